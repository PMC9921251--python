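"""Estimators of the 28 cumulant-model parameters from a signal vector.

Unconstrained
-------------
lls    ordinary least squares on log s
wlls   weighted LS, inverse-variance weights s^2 from the *observed* signal
       (the log-signal error variance is sigma^2 / s~^2, so the weight matrix
       is diag(s)^2; using the noisy signal here is what makes WLLS biased)
iwlls  iteratively reweighted LS: iteration 1 is WLLS, later iterations
       rebuild the weights from the *predicted* signal exp(A theta_hat)
nls    nonlinear LS on the raw signal, damped Gauss-Newton (Levenberg-
       Marquardt) with analytic Jacobian diag(exp(A theta)) A

Constrained
-----------
ciwlls1..3 replace each weighted solve of IWLLS by a convex QP with stacked
linear inequalities realizing physicality constraints (nonnegative
diffusivity, PSD covariance, nonnegative isotropic/anisotropic kurtosis,
monotonic signal decay), discretized over a finite antipodally-symmetric
direction set.  The QP is solved exactly through its dual, a nonnegative
least-squares problem (Lawson-Hanson).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize

from .qti_model import N_PARAMS, forward_signal
from .tensor_algebra import e_bulk, e_shear, voigt6, voigt21_outer


@dataclass
class FitResult:
    theta: np.ndarray
    predicted: np.ndarray          # forward_signal(theta) on the full scheme
    estimator: str
    iterations: int = 1
    status: str = "converged"      # converged | max_iter | infeasible-fallback
    active_constraints: np.ndarray | None = None
    n_dropped: int = 0             # nonpositive samples excluded from log fit


@dataclass
class ConstraintSet:
    """Linear inequalities G theta <= h on the (d, c) blocks of theta."""

    G: np.ndarray
    h: np.ndarray
    directions: np.ndarray
    variant: int
    b_max: float

    @property
    def n_rows(self) -> int:
        return self.G.shape[0]

    def violations(self, theta: np.ndarray, tol: float = 1e-7) -> np.ndarray:
        return self.G @ theta - self.h > tol


def _clean_signal(s: np.ndarray):
    """Indices of usable (strictly positive, finite) samples for log fits."""
    s = np.asarray(s, float)
    keep = np.isfinite(s) & (s > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} nonpositive/non-finite samples "
                      "from log-domain fit", RuntimeWarning)
    return s, keep, n_dropped


def _check_rank(A: np.ndarray):
    if A.shape[0] < N_PARAMS:
        raise ValueError(
            f"need at least {N_PARAMS} usable samples, got {A.shape[0]}")
    rank = np.linalg.matrix_rank(A)
    if rank < N_PARAMS:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {N_PARAMS}); "
            "the scheme does not determine all parameters")


def _weighted_solve(A: np.ndarray, y: np.ndarray,
                    w_sqrt: np.ndarray | None) -> np.ndarray:
    """argmin ||W^(1/2) (y - A theta)||, via an orthogonal factorization."""
    if w_sqrt is None:
        return np.linalg.lstsq(A, y, rcond=None)[0]
    return np.linalg.lstsq(A * w_sqrt[:, None], y * w_sqrt, rcond=None)[0]


def _finish(theta, A_full, name, scheme=None, **kw) -> FitResult:
    pred = np.exp(np.clip(A_full @ theta, -700.0, 700.0))
    return FitResult(theta=theta, predicted=pred, estimator=name, **kw)


def lls_fit(s: np.ndarray, A: np.ndarray) -> FitResult:
    """Ordinary least squares on the log-transformed signal."""
    s, keep, nd = _clean_signal(s)
    Ak = A[keep]
    _check_rank(Ak)
    theta = _weighted_solve(Ak, np.log(s[keep]), None)
    return _finish(theta, A, "lls", n_dropped=nd)


def wlls_fit(s: np.ndarray, A: np.ndarray) -> FitResult:
    """Weighted LLS with observed-signal weights (W^(1/2) = diag(s))."""
    s, keep, nd = _clean_signal(s)
    Ak = A[keep]
    _check_rank(Ak)
    theta = _weighted_solve(Ak, np.log(s[keep]), s[keep])
    return _finish(theta, A, "wlls", n_dropped=nd)


def iwlls_fit(s: np.ndarray, A: np.ndarray, nmax: int = 2) -> FitResult:
    """Iteratively reweighted LLS.

    Iteration 1 uses weights from the observed signal (= WLLS); iteration
    n > 1 rebuilds W_n from the previous prediction exp(A theta_{n-1}).
    ``nmax=1`` therefore equals :func:`wlls_fit` exactly.
    """
    s, keep, nd = _clean_signal(s)
    Ak = A[keep]
    _check_rank(Ak)
    y = np.log(s[keep])
    w_sqrt = s[keep]
    theta = _weighted_solve(Ak, y, w_sqrt)
    status = "converged"
    for _ in range(1, nmax):
        pred = np.exp(np.clip(Ak @ theta, -700.0, 700.0))
        if not np.all(np.isfinite(pred)):
            status = "max_iter"
            break
        theta = _weighted_solve(Ak, y, pred)
    return _finish(theta, A, "iwlls", iterations=nmax, status=status,
                   n_dropped=nd)


def nls_fit(s: np.ndarray, A: np.ndarray,
            theta0: np.ndarray | None = None,
            max_iter: int = 200) -> FitResult:
    """Unweighted nonlinear least squares on the raw signal.

    Damped Gauss-Newton (Levenberg-Marquardt) with analytic Jacobian
    ``diag(exp(A theta)) A``; converged when the gradient norm < 1e-8 or
    the step norm < 1e-10.  Initialized with LLS when theta0 is omitted.
    """
    s = np.asarray(s, float)
    if theta0 is None:
        theta0 = lls_fit(s, A).theta
    theta0 = np.asarray(theta0, float)
    if not np.all(np.isfinite(theta0)):
        raise ValueError("theta0 must be finite")

    theta = theta0.copy()
    pred = np.exp(np.clip(A @ theta, -700.0, 700.0))
    r = s - pred
    cost = r @ r
    lam = 1e-3
    status = "max_iter"
    it = 0
    for it in range(1, max_iter + 1):
        J = pred[:, None] * A
        g = J.T @ r                       # negative gradient direction
        if np.linalg.norm(2.0 * g) < 1e-8:
            status = "converged"
            break
        H = J.T @ J
        diagH = np.diag(H).copy()
        step_taken = False
        for _ in range(40):
            try:
                step = np.linalg.solve(H + lam * np.diag(diagH + 1e-12),
                                       g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            new_theta = theta + step
            new_pred = np.exp(np.clip(A @ new_theta, -700.0, 700.0))
            new_r = s - new_pred
            new_cost = new_r @ new_r
            if new_cost <= cost:
                theta, pred, r, cost = new_theta, new_pred, new_r, new_cost
                lam = max(lam / 3.0, 1e-12)
                step_taken = True
                break
            lam *= 10.0
        if not step_taken:
            status = "converged"          # no decreasing step exists locally
            break
        if np.linalg.norm(step) < 1e-10:
            status = "converged"
            break
    return _finish(theta, A, "nls", iterations=it, status=status)


# ---------------------------------------------------------------------------
# constraints


def antipodal_directions(n: int = 60, seed: int = 0) -> np.ndarray:
    """n approximately uniform unit vectors (antipodally symmetric usage)."""
    from .crlb_design import electrostatic_directions
    return electrostatic_directions(n, seed)


def build_constraints(directions: np.ndarray, variant: int,
                      b_max: float) -> ConstraintSet:
    """Stacked linear inequalities G theta <= h realizing a constraint set.

    variant 1: nonnegative diffusivity along every u in U and nonnegative
               covariance projection <u u^T (x) u u^T, C> >= 0 (discretized
               PSD of the covariance tensor);
    variant 2: d-positivity over U plus monotonic signal decay at b_max:
               <(u u^T)(x)2, c> - b_max <voigt6(u u^T), d> <= 0;
    variant 3: variant 2 plus nonnegative isotropic and anisotropic
               kurtosis numerators <E_bulk, c> >= 0, <E_shear, c> >= 0.

    Every row touches only the d and c blocks (column 0 is zero).
    """
    directions = np.asarray(directions, float)
    if directions.ndim != 2 or directions.shape[1] != 3 or len(directions) < 30:
        raise ValueError("need at least 30 unit directions")
    if b_max <= 0:
        raise ValueError("b_max must be positive")
    if variant not in (1, 2, 3):
        raise ValueError(f"unknown constraint variant {variant!r}")

    v6 = np.stack([voigt6(np.outer(u, u)) for u in directions])       # (m, 6)
    v21 = np.stack([voigt21_outer(np.outer(u, u)) for u in directions])

    rows = []

    def row(d_part=None, c_part=None):
        r = np.zeros(N_PARAMS)
        if d_part is not None:
            r[1:7] = d_part
        if c_part is not None:
            r[7:] = c_part
        rows.append(r)

    for v in v6:                          # D : u u^T >= 0  ->  -<v, d> <= 0
        row(d_part=-v)
    if variant == 1:
        for v in v21:                     # C : (u u^T)(x)2 >= 0
            row(c_part=-v)
    if variant in (2, 3):                 # d S / d b <= 0 at b_max
        for v_d, v_c in zip(v6, v21):
            row(d_part=-b_max * v_d, c_part=v_c)
    if variant == 3:                      # MKi >= 0, MKa >= 0 (numerators)
        row(c_part=-e_bulk())
        row(c_part=-e_shear())

    G = np.stack(rows)
    return ConstraintSet(G=G, h=np.zeros(len(rows)), directions=directions,
                         variant=variant, b_max=float(b_max))


def _qp_ineq(P: np.ndarray, q: np.ndarray, G: np.ndarray,
             h: np.ndarray) -> np.ndarray:
    """Solve min (1/2) x^T P x + q^T x  s.t.  G x <= h, P positive definite.

    Exact dual method: with P = L L^T, B = G L^-T and w = L^-1 q, the dual
    is the nonnegative least-squares problem min_{lam>=0} ||B^T lam + w||
    (valid here since h = 0 puts the dual linear term in range(B));
    the primal is recovered from stationarity P x + q + G^T lam = 0.
    """
    L = np.linalg.cholesky(P)
    Bt = scipy.linalg.solve_triangular(L, G.T, lower=True)    # = B^T, (n, m)
    w = scipy.linalg.solve_triangular(L, q, lower=True)
    if np.any(h):
        raise NotImplementedError("dual NNLS route assumes h = 0")
    lam, _ = scipy.optimize.nnls(Bt, -w)
    x = -scipy.linalg.cho_solve((L, True), q + G.T @ lam)
    # polish: exact equality-constrained KKT solve on the active set
    # (guards against early NNLS termination on ill-conditioned duals)
    active = (lam > 0) | (G @ x > h - 1e-12)
    for _ in range(G.shape[0]):
        idx = np.where(active)[0]
        if len(idx) == 0:
            x_eq = -scipy.linalg.cho_solve((L, True), q)
            lam_eq = np.zeros(0)
        else:
            Ga = G[idx]
            K = np.block([[P, Ga.T],
                          [Ga, np.zeros((len(idx), len(idx)))]])
            rhs = np.concatenate([-q, h[idx]])
            try:
                sol = np.linalg.lstsq(K, rhs, rcond=None)[0]
            except np.linalg.LinAlgError:
                break
            x_eq, lam_eq = sol[: len(q)], sol[len(q):]
        if np.any(lam_eq < -1e-10):
            active[idx[np.argmin(lam_eq)]] = False     # drop most negative
            continue
        if np.all(G @ x_eq <= h + 1e-9):
            x = x_eq
        break
    return x


def ciwlls_fit(s: np.ndarray, A: np.ndarray, constraints: ConstraintSet,
               nmax: int = 2) -> FitResult:
    """Constrained IWLLS: each weighted solve becomes a convex QP.

    If the unconstrained iterate is already feasible it is kept unchanged;
    otherwise the QP  min ||W^(1/2)(log s - A theta)||^2  s.t.
    G theta <= h is solved exactly.  On numerical failure of the QP the
    unconstrained iterate is returned with status ``infeasible-fallback``.
    """
    s, keep, nd = _clean_signal(s)
    Ak = A[keep]
    _check_rank(Ak)
    y = np.log(s[keep])
    G, h = constraints.G, constraints.h
    tol = 1e-7

    w_sqrt = s[keep]
    theta = None
    status = "converged"
    for it in range(nmax):
        if it > 0:
            pred = np.exp(np.clip(Ak @ theta, -700.0, 700.0))
            if not np.all(np.isfinite(pred)):
                status = "max_iter"
                break
            w_sqrt = pred
        Aw = Ak * w_sqrt[:, None]
        yw = y * w_sqrt
        theta_u = np.linalg.lstsq(Aw, yw, rcond=None)[0]
        if np.all(G @ theta_u <= h + tol):
            theta = theta_u
            continue
        P = Aw.T @ Aw
        P[np.diag_indices_from(P)] += 1e-12 * np.trace(P) / N_PARAMS
        q = -(Aw.T @ yw)
        try:
            theta = _qp_ineq(P, q, G, h)
        except Exception:
            warnings.warn("constrained QP solve failed; falling back to the "
                          "unconstrained iterate", RuntimeWarning)
            theta = theta_u
            status = "infeasible-fallback"
    active = (np.abs(G @ theta - h) <= 1e-6)
    return _finish(theta, A, f"ciwlls{constraints.variant}",
                   iterations=nmax, status=status,
                   active_constraints=active, n_dropped=nd)


_UNCONSTRAINED = {"lls": lls_fit, "wlls": wlls_fit, "iwlls": iwlls_fit,
                  "nls": nls_fit}


def fit(s: np.ndarray, A: np.ndarray, estimator: str = "iwlls",
        constraints: ConstraintSet | None = None, **kw) -> FitResult:
    """Fit by estimator name: lls | wlls | iwlls | nls | ciwlls1..3.

    Constrained names build a default constraint set from 60 electrostatic
    directions and the largest ``b_max`` implied by the design matrix unless
    an explicit :class:`ConstraintSet` is supplied.
    """
    name = estimator.lower()
    if name in _UNCONSTRAINED:
        return _UNCONSTRAINED[name](s, A, **kw)
    if name.startswith("ciwlls") and name[-1] in "123":
        if constraints is None:
            b_max = float(np.max(np.abs(A[:, 1:4]).sum(axis=1)))
            constraints = build_constraints(antipodal_directions(60, seed=0),
                                            int(name[-1]), b_max)
        return ciwlls_fit(s, A, constraints, **kw)
    raise ValueError(f"unknown estimator {estimator!r}")
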
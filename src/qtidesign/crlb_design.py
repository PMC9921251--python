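"""Fisher information, Cramer-Rao lower bounds, and acquisition design.

For the cumulant model with i.i.d. Gaussian noise of SD sigma, the Fisher
information matrix is

    I(theta) = (1/sigma^2) A^T diag(s(theta))^2 A,

its inverse bounds the covariance of any unbiased estimator (CRLB), and the
delta method propagates the bound to derived scalar metrics through the
gradient matrix M:  J = M^T I^-1 M.

Two design criteria are provided: f2 = log det I^-1 (D-optimality, computed
as -log det I for numerical stability) and f3 = sum_j w_j J_jj, a weighted
trace of the metric CRLB with default weights 1/m_j^2 (equal relative
precision).  The scheme optimizer fixes N electrostatically repelled
directions and pattern-searches the 2N vector (b, b_delta) inside its box,
averaging the criterion over a population of randomly oriented prior voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .qti_model import (
    AcquisitionScheme,
    METRIC_NAMES,
    N_PARAMS,
    design_matrix,
    design_matrix_from_arrays,
    forward_signal,
    metric_vector,
)

#: default metric set the weighted-trace criterion targets
F3_DEFAULT_METRICS = ("md", "ufa", "mki", "mka")

#: default design box: 0.1 < b < 2 ms/um^2, -0.5 <= b_delta <= 1
B_BOUNDS = (0.1, 2.0)
BDELTA_BOUNDS = (-0.5, 1.0)


@dataclass
class FisherInfo:
    matrix: np.ndarray     # 28 x 28 symmetric PSD
    sigma: float


@dataclass
class MetricCRLB:
    cov: np.ndarray        # K x K lower-bound covariance of the metrics
    names: tuple
    gradients: np.ndarray  # 28 x K matrix M

    @property
    def variances(self) -> np.ndarray:
        return np.diag(self.cov)


@dataclass
class DesignProblem:
    """Inputs of a scheme optimization run."""

    priors: np.ndarray                 # (M, 28) prior parameter vectors
    n_samples: int = 120
    criterion: str = "f3"              # 'f2' | 'f3'
    metrics: tuple = F3_DEFAULT_METRICS
    weights: np.ndarray | None = None  # default: per-voxel 1/m_j^2
    sigma: float = 1.0 / 15.0          # noise SD in S0 units (SNR 15)
    b_bounds: tuple = B_BOUNDS
    b_delta_bounds: tuple = BDELTA_BOUNDS
    seed: int = 0
    max_evals: int = 60_000

    def __post_init__(self):
        self.priors = np.atleast_2d(np.asarray(self.priors, float))
        if self.priors.shape[1] != N_PARAMS or len(self.priors) < 1:
            raise ValueError("priors must be an (M, 28) array, M >= 1")
        if self.criterion not in ("f2", "f3"):
            raise ValueError(f"unknown criterion {self.criterion!r}")


def fisher_information(theta: np.ndarray, scheme: AcquisitionScheme,
                       sigma: float, A: np.ndarray | None = None) -> FisherInfo:
    """FIM of the cumulant model under homoscedastic Gaussian noise."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if A is None:
        A = design_matrix(scheme)
    s = forward_signal(theta, scheme, A=A)
    I = (A * (s ** 2)[:, None]).T @ A / sigma ** 2
    return FisherInfo(matrix=0.5 * (I + I.T), sigma=float(sigma))


def _metric_gradients(theta: np.ndarray, names) -> np.ndarray:
    """28 x K central-finite-difference gradients of the scalar metrics.

    Relative step 1e-5 per parameter with absolute floor 1e-8; the metric
    formulas are smooth rational/root functions, so this is accurate to
    ~1e-9 relative.
    """
    theta = np.asarray(theta, float)
    M = np.empty((N_PARAMS, len(names)))
    for i in range(N_PARAMS):
        h = max(1e-5 * abs(theta[i]), 1e-8)
        tp = theta.copy(); tp[i] += h
        tm = theta.copy(); tm[i] -= h
        M[i] = (metric_vector(tp, names) - metric_vector(tm, names)) / (2 * h)
    return M


def metric_crlb(theta: np.ndarray, scheme: AcquisitionScheme, sigma: float,
                metrics=METRIC_NAMES, A: np.ndarray | None = None) -> MetricCRLB:
    """Delta-method CRLB of derived metrics: J = M^T I^-1 M."""
    info = fisher_information(theta, scheme, sigma, A=A)
    M = _metric_gradients(theta, metrics)
    try:
        X = np.linalg.solve(info.matrix, M)
    except np.linalg.LinAlgError:
        warnings.warn("singular Fisher information; using pseudo-inverse",
                      RuntimeWarning)
        X = np.linalg.pinv(info.matrix) @ M
    J = M.T @ X
    return MetricCRLB(cov=0.5 * (J + J.T), names=tuple(metrics), gradients=M)


def criterion_f2(theta: np.ndarray, scheme: AcquisitionScheme, sigma: float,
                 A: np.ndarray | None = None) -> float:
    """D-optimality: log det CRLB = -log det I (monotone transform).

    Returns +inf when the FIM is not positive definite (scheme does not
    determine all 28 parameters).
    """
    info = fisher_information(theta, scheme, sigma, A=A)
    sign, logdet = np.linalg.slogdet(info.matrix)
    if sign <= 0 or not np.isfinite(logdet):
        return float("inf")
    return -logdet


def criterion_f3(theta: np.ndarray, scheme: AcquisitionScheme, sigma: float,
                 metrics=F3_DEFAULT_METRICS, weights=None,
                 A: np.ndarray | None = None) -> float:
    """Weighted trace of the metric CRLB, default weights 1/m_j^2.

    A vanishing metric with default weights has its weight capped at 1e12
    (logged) rather than propagating an infinity.
    """
    crlb = metric_crlb(theta, scheme, sigma, metrics=metrics, A=A)
    if weights is None:
        m = metric_vector(theta, metrics)
        with np.errstate(divide="ignore"):
            weights = 1.0 / m ** 2
        if np.any(~np.isfinite(weights)):
            warnings.warn("zero metric value; capping its f3 weight at 1e12",
                          RuntimeWarning)
            weights = np.minimum(np.nan_to_num(weights, posinf=1e12), 1e12)
    return float(np.asarray(weights) @ crlb.variances)


def population_objective(priors, scheme: AcquisitionScheme, sigma: float,
                         criterion: str = "f2", metrics=F3_DEFAULT_METRICS,
                         weights=None) -> float:
    """Average of a design criterion over a population of prior voxels."""
    priors = np.atleast_2d(np.asarray(priors, float))
    A = design_matrix(scheme)
    if criterion == "f2":
        vals = [criterion_f2(t, scheme, sigma, A=A) for t in priors]
    elif criterion == "f3":
        vals = [criterion_f3(t, scheme, sigma, metrics=metrics,
                             weights=weights, A=A) for t in priors]
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# fast batched objective used inside the pattern search


class _BatchObjective:
    """Population criterion as a function of the (b, b_delta) vector.

    Directions are fixed; per-prior quantities that do not depend on the
    scheme (signals via theta, metric gradients, f3 weights) are precomputed
    once.  All priors are evaluated in one batch of 28x28 problems.
    """

    def __init__(self, priors, directions, sigma, criterion,
                 metrics=F3_DEFAULT_METRICS, weights=None):
        self.priors = np.atleast_2d(np.asarray(priors, float))
        self.G = np.asarray(directions, float)
        self.sigma = float(sigma)
        self.criterion = criterion
        self.n_evals = 0
        if criterion == "f3":
            self.M = np.stack([_metric_gradients(t, metrics)
                               for t in self.priors])        # (V, 28, K)
            if weights is None:
                mv = np.stack([metric_vector(t, metrics) for t in self.priors])
                with np.errstate(divide="ignore"):
                    w = 1.0 / mv ** 2
                self.w = np.minimum(np.nan_to_num(w, posinf=1e12), 1e12)
            else:
                self.w = np.broadcast_to(np.asarray(weights, float),
                                         (len(self.priors), len(metrics)))

    def __call__(self, x: np.ndarray) -> float:
        self.n_evals += 1
        n = len(self.G)
        A = design_matrix_from_arrays(self.G, x[:n], x[n:])
        expo = np.clip(self.priors @ A.T, -700.0, 700.0)     # (V, N)
        S2 = np.exp(2.0 * expo)
        # batched A^T diag(s^2) A via BLAS matmul
        I = np.matmul(A.T[None], S2[:, :, None] * A[None]) / self.sigma ** 2
        if self.criterion == "f2":
            sign, logdet = np.linalg.slogdet(I)
            if np.any(sign <= 0) or not np.all(np.isfinite(logdet)):
                return float("inf")
            return float(np.mean(-logdet))
        try:
            X = np.linalg.solve(I, self.M)                   # (V, 28, K)
        except np.linalg.LinAlgError:
            return float("inf")
        Jdiag = np.einsum("vik,vik->vk", self.M, X)
        if np.any(Jdiag < 0) or not np.all(np.isfinite(Jdiag)):
            return float("inf")
        return float(np.mean(np.sum(self.w * Jdiag, axis=1)))


# ---------------------------------------------------------------------------
# direction sets


def _antipodal_energy_grad(x: np.ndarray):
    """Antipodally symmetric Coulomb energy and gradient on the sphere.

    Points are free 3-vectors normalized inside, E = sum_{i<j}
    1/|u_i - u_j| + 1/|u_i + u_j|; the gradient is pushed through the
    normalization so unconstrained quasi-Newton descent stays on the sphere.
    """
    n = x.shape[0]
    nrm = np.linalg.norm(x, axis=1, keepdims=True)
    u = x / nrm
    dm = u[:, None, :] - u[None, :, :]
    dp = u[:, None, :] + u[None, :, :]
    rm = np.linalg.norm(dm, axis=2)
    rp = np.linalg.norm(dp, axis=2)
    np.fill_diagonal(rm, np.inf)
    np.fill_diagonal(rp, np.inf)
    E = 0.5 * np.sum(1.0 / rm + 1.0 / rp)
    grad_u = -np.einsum("ij,ijk->ik", rm ** -3, dm) \
             - np.einsum("ij,ijk->ik", rp ** -3, dp)
    # chain rule through u = x / |x|
    grad_x = (grad_u - u * np.sum(grad_u * u, axis=1, keepdims=True)) / nrm
    return E, grad_x


def electrostatic_directions(n: int, seed: int = 0,
                             n_restarts: int = 3) -> np.ndarray:
    """n unit vectors minimizing antipodal electrostatic repulsion energy.

    Deterministic given ``seed``; the best of ``n_restarts`` seeded L-BFGS
    descents from random starts is returned, each point normalized to unit
    length and flipped into the upper hemisphere for a canonical sign.
    Results are memoized (packaged schemes and constraint sets rebuild the
    same direction sets repeatedly).
    """
    return _electrostatic_cached(int(n), int(seed), int(n_restarts)).copy()


from functools import lru_cache


@lru_cache(maxsize=256)
def _electrostatic_cached(n: int, seed: int, n_restarts: int) -> np.ndarray:
    if n < 1:
        raise ValueError("need n >= 1 directions")
    if n == 1:
        return np.array([[0.0, 0.0, 1.0]])
    rng = np.random.default_rng(seed)
    best, best_e = None, np.inf
    for _ in range(n_restarts):
        x0 = rng.standard_normal((n, 3))
        x0 /= np.linalg.norm(x0, axis=1, keepdims=True)
        res = scipy.optimize.minimize(
            lambda v: _antipodal_energy_grad(v.reshape(n, 3)),
            x0.ravel(), jac=True, method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
        if res.fun < best_e:
            best_e, best = res.fun, res.x.reshape(n, 3)
    u = best / np.linalg.norm(best, axis=1, keepdims=True)
    flip = u[:, 2] < 0
    u[flip] *= -1.0
    return u


# ---------------------------------------------------------------------------
# scheme optimization


@dataclass
class DesignResult:
    scheme: AcquisitionScheme
    objective: float
    initial_objective: float
    trace: list          # (eval count, objective) milestones
    n_evals: int


def optimize_scheme(problem: DesignProblem) -> DesignResult:
    """Pattern-search optimization of (b, b_delta) with fixed directions.

    Directions are ``electrostatic_directions(N, seed)`` and stay fixed
    (rotational robustness, fewer free parameters).  The 2N vector
    (b, b_delta) starts from a seeded uniform draw inside the box and is
    refined by opportunistic coordinate polling with step halving from 0.4
    down to 1e-3, never leaving the box.  Descent is monotone, so the
    returned objective never exceeds the initial one.
    """
    n = problem.n_samples
    rng = np.random.default_rng(problem.seed)
    G = electrostatic_directions(n, problem.seed)
    lo = np.concatenate([np.full(n, problem.b_bounds[0]),
                         np.full(n, problem.b_delta_bounds[0])])
    hi = np.concatenate([np.full(n, problem.b_bounds[1]),
                         np.full(n, problem.b_delta_bounds[1])])
    x = rng.uniform(lo, hi)
    obj = _BatchObjective(problem.priors, G, problem.sigma, problem.criterion,
                          metrics=problem.metrics, weights=problem.weights)
    f = obj(x)
    if not np.isfinite(f):
        raise RuntimeError(
            "design objective is infinite at the initialization; the scheme "
            "cannot determine all parameters — increase the sample count N")
    f0 = f
    trace = [(obj.n_evals, f)]
    scale = np.concatenate([
        np.full(n, problem.b_bounds[1] - problem.b_bounds[0]),
        np.full(n, problem.b_delta_bounds[1] - problem.b_delta_bounds[0])])
    step = 0.4
    while step >= 1e-3 and obj.n_evals < problem.max_evals:
        improved = False
        for i in range(2 * n):
            if obj.n_evals >= problem.max_evals:
                break
            for sgn in (1.0, -1.0):
                xi = np.clip(x[i] + sgn * step * scale[i], lo[i], hi[i])
                if xi == x[i]:
                    continue
                x_try = x.copy()
                x_try[i] = xi
                f_try = obj(x_try)
                if f_try < f:
                    x, f = x_try, f_try
                    improved = True
                    break
        trace.append((obj.n_evals, f))
        if not improved:
            step *= 0.5
    scheme = AcquisitionScheme(G, x[:n], x[n:])
    return DesignResult(scheme=scheme, objective=f, initial_objective=f0,
                        trace=trace, n_evals=obj.n_evals)


QUINTESSENTIAL_SHAPES = (-0.5, 0.0, 1.0)


def _kmeans_1d(values: np.ndarray, k: int, n_iter: int = 200):
    """Deterministic 1-D Lloyd k-means, farthest-point initialization.

    (Quantile initialization can duplicate centers when many samples pile
    up at a box bound, silently collapsing shells.)
    """
    values = np.asarray(values, float)
    centers = [float(np.median(values))]
    while len(centers) < k:
        dist = np.min(np.abs(values[:, None] - np.array(centers)[None, :]),
                      axis=1)
        centers.append(float(values[np.argmax(dist)]))
    centers = np.array(centers)
    for _ in range(n_iter):
        lab = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
        new = np.array([values[lab == j].mean() if np.any(lab == j)
                        else centers[j] for j in range(k)])
        if np.allclose(new, centers, atol=1e-12):
            break
        centers = new
    lab = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
    wcss = float(np.sum((values - centers[lab]) ** 2))
    return centers, lab, wcss


def cluster_scheme(raw: AcquisitionScheme, b_delta_snap_tol: float = 0.15,
                   n_b_shells: int = 4, seed: int = 0) -> AcquisitionScheme:
    """Snap an optimized scheme onto a shell structure.

    b_delta values within ``b_delta_snap_tol`` of a quintessential shape
    (-0.5 planar, 0 spherical, 1 linear) are snapped to it (others kept and
    reported); b-values are clustered by 1-D k-means with the smallest k
    (k <= n_b_shells) that reproduces the b-values exactly, else the
    minimal-variance k = n_b_shells solution, each sample taking its
    cluster centroid.  Within every resulting (b, b_delta) group the
    directions are regenerated by electrostatic repulsion, so sample counts
    are preserved and an already-shelled scheme returns unchanged up to
    direction regeneration.
    """
    b = raw.b.copy()
    bd = raw.b_delta.copy()
    for q in QUINTESSENTIAL_SHAPES:
        near = np.abs(bd - q) <= b_delta_snap_tol
        bd[near] = q
    kept = ~np.isin(bd, QUINTESSENTIAL_SHAPES)
    if np.any(kept):
        warnings.warn(f"{int(kept.sum())} samples kept a non-quintessential "
                      "b_delta after snapping", RuntimeWarning)

    k_max = min(n_b_shells, len(np.unique(np.round(b, 12))))
    centers, lab = None, None
    for k in range(1, k_max + 1):
        centers, lab, wcss = _kmeans_1d(b, k)
        if wcss <= 1e-12:
            break           # already exactly shelled with k shells
        # otherwise keep growing k: minimal within-cluster variance
        # subject to k <= n_b_shells
    b_snapped = centers[lab]

    directions = np.empty_like(raw.directions)
    groups = sorted(set(zip(np.round(b_snapped, 12), np.round(bd, 12))))
    for gi, (bv, bdv) in enumerate(groups):
        idx = np.where((np.round(b_snapped, 12) == bv)
                       & (np.round(bd, 12) == bdv))[0]
        if len(idx) == 1:
            # a singleton shell has no uniformity to restore; keep its
            # optimized direction (regenerating would pile every singleton
            # onto the canonical axis)
            directions[idx] = raw.directions[idx]
        else:
            directions[idx] = electrostatic_directions(len(idx),
                                                       seed + 1000 + gi)
    return AcquisitionScheme(directions, b_snapped, bd)


def precision_gain(scheme: AcquisitionScheme, scheme_ref: AcquisitionScheme,
                   theta: np.ndarray, sigma: float,
                   which: int | str) -> float:
    """Relative precision of ``scheme`` over ``scheme_ref`` for one quantity.

    Precision is the reciprocal CRLB variance; ``which`` is either a raw
    parameter index (0..27) or a scalar-metric name.  Values > 1 mean the
    scheme estimates the quantity more precisely than the reference; the
    ratio is independent of sigma.
    """
    def crlb_of(sch):
        if isinstance(which, str):
            return float(metric_crlb(theta, sch, sigma,
                                     metrics=(which,)).variances[0])
        info = fisher_information(theta, sch, sigma)
        return float(np.linalg.inv(info.matrix)[which, which])

    c_i, c_ref = crlb_of(scheme), crlb_of(scheme_ref)
    if not (np.isfinite(c_i) and np.isfinite(c_ref)) or c_i <= 0 or c_ref <= 0:
        warnings.warn("degenerate CRLB in precision gain; returning NaN",
                      RuntimeWarning)
        return float("nan")
    return c_ref / c_i


def random_rotations(n: int, seed: int = 0) -> np.ndarray:
    """n uniform random rotation matrices (quaternion sampling, seeded)."""
    rng = np.random.default_rng(seed)
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    R = np.empty((n, 3, 3))
    R[:, 0, 0] = 1 - 2 * (y * y + z * z)
    R[:, 0, 1] = 2 * (x * y - w * z)
    R[:, 0, 2] = 2 * (x * z + w * y)
    R[:, 1, 0] = 2 * (x * y + w * z)
    R[:, 1, 1] = 1 - 2 * (x * x + z * z)
    R[:, 1, 2] = 2 * (y * z - w * x)
    R[:, 2, 0] = 2 * (x * z - w * y)
    R[:, 2, 1] = 2 * (y * z + w * x)
    R[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return R
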
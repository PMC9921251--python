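"""Cumulant signal model for tensor-valued diffusion encoding.

The voxel is modelled by a distribution of microscopic Gaussian diffusion
tensors.  The measured signal for a b-tensor B is, exactly,

    S = S0 <exp(-B : D)>            (multi-Gaussian mixture)

and, to second cumulant order,

    S = S0 exp(-B : <D> + (1/2) B(x)B : C)

with <D> the mean diffusion tensor and C its 4th-order covariance.  In
Voigt notation this is log S = A theta with the 28-parameter vector

    theta = [log S0, d (6), c (21)]

and a design matrix A whose rows depend only on the acquisition scheme.

This module provides the design matrix, the cumulant forward signal, the
exact mixture signal (the oracle against which the cumulant model is a
low-b approximation), the mixture -> (d, c) moment map, and the scalar
metrics (MD, FA, uFA, MKi, MKa, MK, OP, C_c) derived from theta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .tensor_algebra import (
    btensor_from_shape,
    e_bulk,
    e_shear,
    svec21,
    svec21_to_matrix,
    voigt6,
    voigt6_to_matrix,
    voigt21_outer,
)

N_PARAMS = 28
#: exponent bound for the forward signal; |A theta| beyond this is clipped
#: (far outside any physical regime, prevents overflow on wild iterates)
EXP_CLIP = 700.0

_E_BULK = e_bulk()
_E_SHEAR = e_shear()


@dataclass
class AcquisitionScheme:
    """An N-sample axisymmetric b-tensor acquisition.

    Attributes
    ----------
    directions : (N, 3) float array
        Unit principal axes of the b-tensors.
    b : (N,) float array
        b-values in ms/um^2.
    b_delta : (N,) float array
        b-tensor anisotropies in [-0.5, 1].
    """

    directions: np.ndarray
    b: np.ndarray
    b_delta: np.ndarray

    def __post_init__(self):
        self.directions = np.atleast_2d(np.asarray(self.directions, float))
        self.b = np.atleast_1d(np.asarray(self.b, float))
        self.b_delta = np.atleast_1d(np.asarray(self.b_delta, float))
        n = len(self.b)
        if n < 1:
            raise ValueError("scheme must contain at least one sample")
        if self.directions.shape != (n, 3) or self.b_delta.shape != (n,):
            raise ValueError("inconsistent scheme dimensions")
        nrm = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(nrm, 1.0, atol=1e-8):
            raise ValueError("all scheme directions must be unit norm")
        if np.any(self.b < 0):
            raise ValueError("b-values must be nonnegative")
        if np.any((self.b_delta < -0.5) | (self.b_delta > 1.0)):
            raise ValueError("b_delta must lie in [-0.5, 1]")

    def __len__(self) -> int:
        return len(self.b)

    def btensors(self) -> np.ndarray:
        """(N, 3, 3) stack of the b-tensors."""
        return np.stack(
            [btensor_from_shape(g, b, bd)
             for g, b, bd in zip(self.directions, self.b, self.b_delta)]
        )

    def concatenate(self, other: "AcquisitionScheme") -> "AcquisitionScheme":
        return AcquisitionScheme(
            np.vstack([self.directions, other.directions]),
            np.concatenate([self.b, other.b]),
            np.concatenate([self.b_delta, other.b_delta]),
        )


@dataclass
class DiscreteDTD:
    """Finite weighted mixture of microscopic Gaussian diffusion tensors."""

    weights: np.ndarray
    tensors: np.ndarray  # (K, 3, 3)

    def __post_init__(self):
        self.weights = np.atleast_1d(np.asarray(self.weights, float))
        self.tensors = np.asarray(self.tensors, float)
        if self.tensors.ndim == 2:
            self.tensors = self.tensors[None]
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-10:
            raise ValueError("weights must be nonnegative and sum to 1")
        if self.tensors.shape != (len(self.weights), 3, 3):
            raise ValueError("tensors must be a (K, 3, 3) stack")
        ev = np.linalg.eigvalsh(self.tensors)
        if ev.min() < -1e-10:
            raise ValueError(
                f"mixture components must be PSD (min eigenvalue {ev.min():.3e})"
            )

    def rotated(self, R: np.ndarray) -> "DiscreteDTD":
        """Mixture with every component rotated by the 3x3 rotation R."""
        return DiscreteDTD(self.weights.copy(),
                           np.einsum("ab,kbc,dc->kad", R, self.tensors, R))


@dataclass
class ScalarMetrics:
    """Rotation-invariant metrics of the diffusion tensor distribution."""

    md: float       # mean diffusivity, um^2/ms
    fa: float       # fractional anisotropy of the mean tensor
    ufa: float      # microscopic FA (dispersion-insensitive)
    mki: float      # isotropic kurtosis
    mka: float      # anisotropic kurtosis
    mk: float       # total mean kurtosis = mki + mka
    op: float       # order parameter (orientation coherence)
    c_c: float      # FA^2 / uFA^2

    _NAMES = ("md", "fa", "ufa", "mki", "mka", "mk", "op", "c_c")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self._NAMES}


def theta_from_parts(log_s0: float, d: np.ndarray, c: np.ndarray) -> np.ndarray:
    theta = np.empty(N_PARAMS)
    theta[0] = log_s0
    theta[1:7] = d
    theta[7:] = c
    return theta


def design_row(B: np.ndarray) -> np.ndarray:
    """One row of the design matrix for b-tensor B.

    ``design_row(B) @ theta == log S0 - B:<D> + (1/2) B(x)B : C``.
    """
    row = np.empty(N_PARAMS)
    row[0] = 1.0
    row[1:7] = -voigt6(B)
    row[7:] = 0.5 * voigt21_outer(B)
    return row


_PAIR_I, _PAIR_J = np.array(
    [(i, j) for i in range(6) for j in range(i + 1, 6)]).T


def design_matrix_from_arrays(G: np.ndarray, b: np.ndarray,
                              b_delta: np.ndarray) -> np.ndarray:
    """Vectorized N x 28 design matrix from raw scheme arrays.

    Equivalent to stacking :func:`design_row` over the b-tensors; kept
    allocation-light because the design optimizer calls it in its inner loop.
    """
    G = np.asarray(G, float)
    b = np.asarray(b, float)
    bd = np.asarray(b_delta, float)
    b_par = b * (1.0 + 2.0 * bd) / 3.0
    b_perp = b * (1.0 - bd) / 3.0
    dl = b_par - b_perp
    sq2 = np.sqrt(2.0)
    v6 = np.empty((len(b), 6))
    v6[:, 0] = b_perp + dl * G[:, 0] ** 2
    v6[:, 1] = b_perp + dl * G[:, 1] ** 2
    v6[:, 2] = b_perp + dl * G[:, 2] ** 2
    v6[:, 3] = sq2 * dl * G[:, 1] * G[:, 2]
    v6[:, 4] = sq2 * dl * G[:, 0] * G[:, 2]
    v6[:, 5] = sq2 * dl * G[:, 0] * G[:, 1]
    A = np.empty((len(b), N_PARAMS))
    A[:, 0] = 1.0
    A[:, 1:7] = -v6
    A[:, 7:13] = 0.5 * v6 ** 2
    A[:, 13:] = 0.5 * sq2 * v6[:, _PAIR_I] * v6[:, _PAIR_J]
    return A


def design_matrix(scheme: AcquisitionScheme) -> np.ndarray:
    """N x 28 design matrix of a scheme (row i from b-tensor i)."""
    return design_matrix_from_arrays(scheme.directions, scheme.b,
                                     scheme.b_delta)


def forward_signal(theta: np.ndarray, scheme: AcquisitionScheme,
                   A: np.ndarray | None = None) -> np.ndarray:
    """Cumulant-model signal s = exp(A theta), strictly positive.

    The exponent is clipped at +/-EXP_CLIP to guard against overflow on
    unphysical iterates; clip events emit a warning.
    """
    theta = np.asarray(theta, float)
    if theta.shape != (N_PARAMS,):
        raise ValueError(f"theta must have {N_PARAMS} entries")
    if A is None:
        A = design_matrix(scheme)
    x = A @ theta
    if np.any(np.abs(x) > EXP_CLIP):
        warnings.warn("forward-signal exponent clipped at +/-700", RuntimeWarning)
        x = np.clip(x, -EXP_CLIP, EXP_CLIP)
    return np.exp(x)


def mixture_signal(dtd: DiscreteDTD, s0: float,
                   scheme: AcquisitionScheme) -> np.ndarray:
    """Exact multi-Gaussian signal S0 * sum_k w_k exp(-B : D_k).

    The cumulant model is a second-order (low-b) approximation of this.
    """
    Bs = scheme.btensors()                       # (N, 3, 3)
    expo = -np.einsum("nab,kab->nk", Bs, dtd.tensors)
    return s0 * np.exp(expo) @ dtd.weights


def moments_from_mixture(dtd: DiscreteDTD) -> tuple[np.ndarray, np.ndarray]:
    """First and second central moments of a mixture in Voigt space.

    Returns ``d = sum_k w_k voigt6(D_k)`` and the covariance 21-vector
    ``c`` such that its 6x6 Voigt-matrix form is
    ``sum_k w_k v_k v_k^T - d d^T`` (positive semidefinite by construction).
    """
    V = np.stack([voigt6(D) for D in dtd.tensors])       # (K, 6)
    d = dtd.weights @ V
    second = np.einsum("k,ka,kb->ab", dtd.weights, V, V)
    return d, svec21(second - np.outer(d, d))


def theta_from_mixture(dtd: DiscreteDTD, s0: float = 1.0) -> np.ndarray:
    d, c = moments_from_mixture(dtd)
    return theta_from_parts(np.log(s0), d, c)


def scalar_metrics(theta: np.ndarray) -> ScalarMetrics:
    """Derived scalar metrics of theta.

    With V_bulk = <d(x)d, E_bulk> (= MD^2), V_shear = <d(x)d, E_shear>, and
    the second moments <D(x)D> = d(x)d + C:

        FA   = sqrt(3/2) sqrt(V_shear / (V_bulk + V_shear))
        uFA  = same with <D(x)D>-contractions (micro-scale anisotropy)
        MKi  = 3 <C, E_bulk> / MD^2        (variance of isotropic diffusivities)
        MKa  = (6/5) <C, E_shear> / MD^2   (microscopic anisotropy)
        MK   = MKi + MKa
        OP   = sqrt(V_shear / V_shear_2)   (orientation coherence)
        C_c  = FA^2 / uFA^2

    A nonpositive MD (possible for noisy unconstrained fits) yields NaN
    metrics with a warning rather than an exception.
    """
    theta = np.asarray(theta, float)
    d = theta[1:7]
    c = theta[7:]
    md = d[:3].sum() / 3.0
    if md <= 0:
        warnings.warn("MD <= 0: scalar metrics undefined, returning NaN",
                      RuntimeWarning)
        nan = float("nan")
        return ScalarMetrics(*([nan] * 8))
    dd = svec21(np.outer(d, d))
    second = dd + c
    v_bulk_m = float(dd @ _E_BULK)        # == md**2
    v_shear_m = max(float(dd @ _E_SHEAR), 0.0)
    v_bulk_2 = float(second @ _E_BULK)
    v_shear_2 = float(second @ _E_SHEAR)
    fa = float(np.sqrt(1.5 * v_shear_m / (v_bulk_m + v_shear_m)))
    denom2 = v_bulk_2 + v_shear_2
    ufa = float(np.sqrt(1.5 * max(v_shear_2, 0.0) / denom2)) if denom2 > 0 and v_shear_2 > 0 else 0.0
    mki = 3.0 * float(c @ _E_BULK) / v_bulk_m
    mka = 1.2 * float(c @ _E_SHEAR) / v_bulk_m
    op = float(np.sqrt(v_shear_m / v_shear_2)) if v_shear_2 > 1e-30 else 0.0
    c_c = float(fa**2 / ufa**2) if ufa > 0 else 0.0
    return ScalarMetrics(md=float(md), fa=fa, ufa=ufa, mki=mki, mka=mka,
                         mk=mki + mka, op=op, c_c=c_c)


METRIC_NAMES = ScalarMetrics._NAMES


def metric_vector(theta: np.ndarray, names=METRIC_NAMES) -> np.ndarray:
    """Selected scalar metrics of theta as a flat array (order = names)."""
    m = scalar_metrics(theta).as_dict()
    return np.array([m[k] for k in names])
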
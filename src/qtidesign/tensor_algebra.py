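"""Voigt-notation algebra for 2nd- and 4th-order symmetric tensors.

Symmetric 3x3 tensors (diffusion tensors D, b-tensors B) are stored as
6-vectors, and fully symmetric 4th-order tensors (the diffusion covariance
tensor and B outer B) as 21-vectors.  The normalization is fixed by a single
requirement: vector inner products equal full tensor index contractions,

    voigt6(T) . voigt6(U)             == sum_ij T_ij U_ij
    voigt21_outer(P) . voigt21_outer(Q) == (P : Q)^2

which makes every downstream expression (design matrix, constraints, metric
formulas) basis independent.

Component ordering
------------------
6-vector:  (xx, yy, zz, yz, xz, xy), with sqrt(2) on the three cross terms.
21-vector: the symmetric vectorization (svec) of the 6x6 matrix V v v^T:
           first the 6 diagonal entries (i,i), then the 15 upper-triangle
           entries (i,j), i<j, in row-major order, each scaled by sqrt(2).

Units: diffusivities in um^2/ms, b-values in ms/um^2, so b*D is
dimensionless.
"""

from __future__ import annotations

import numpy as np

SQRT2 = np.sqrt(2.0)

# (row, col) index of each voigt6 slot in the 3x3 tensor
_V6_IDX = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]

# upper-triangle (i<j) slots of the 6x6 matrix, in 21-vector order 6..20
_V21_OFFDIAG = [(i, j) for i in range(6) for j in range(i + 1, 6)]


def voigt6(T: np.ndarray) -> np.ndarray:
    """Map a symmetric 3x3 tensor to its Voigt 6-vector.

    Order (xx, yy, zz, yz, xz, xy) with sqrt(2) on the cross terms, so that
    ``voigt6(T) @ voigt6(U)`` equals the double contraction T:U.

    Raises
    ------
    ValueError
        If ``T`` is not symmetric within 1e-10.
    """
    T = np.asarray(T, dtype=float)
    if T.shape != (3, 3):
        raise ValueError(f"expected a 3x3 tensor, got shape {T.shape}")
    if not np.allclose(T, T.T, atol=1e-10):
        raise ValueError("input tensor is not symmetric within 1e-10")
    return np.array(
        [T[0, 0], T[1, 1], T[2, 2],
         SQRT2 * T[1, 2], SQRT2 * T[0, 2], SQRT2 * T[0, 1]]
    )


def voigt6_to_matrix(v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`voigt6`: rebuild the symmetric 3x3 tensor."""
    v = np.asarray(v, dtype=float)
    if v.shape != (6,):
        raise ValueError(f"expected a 6-vector, got shape {v.shape}")
    T = np.empty((3, 3))
    for k, (i, j) in enumerate(_V6_IDX):
        val = v[k] if i == j else v[k] / SQRT2
        T[i, j] = T[j, i] = val
    return T


def svec21(M: np.ndarray) -> np.ndarray:
    """Symmetric vectorization of a 6x6 symmetric matrix into a 21-vector.

    Diagonal entries first, then sqrt(2)-scaled upper-triangle entries, so
    that ``svec21(A) @ svec21(B)`` equals the Frobenius inner product <A, B>.
    """
    M = np.asarray(M, dtype=float)
    if M.shape != (6, 6):
        raise ValueError(f"expected a 6x6 matrix, got shape {M.shape}")
    out = np.empty(21)
    out[:6] = np.diag(M)
    for k, (i, j) in enumerate(_V21_OFFDIAG):
        out[6 + k] = SQRT2 * M[i, j]
    return out


def svec21_to_matrix(c: np.ndarray) -> np.ndarray:
    """Inverse of :func:`svec21`: rebuild the symmetric 6x6 matrix."""
    c = np.asarray(c, dtype=float)
    if c.shape != (21,):
        raise ValueError(f"expected a 21-vector, got shape {c.shape}")
    M = np.diag(c[:6]).astype(float)
    for k, (i, j) in enumerate(_V21_OFFDIAG):
        M[i, j] = M[j, i] = c[6 + k] / SQRT2
    return M


def voigt21_outer(T: np.ndarray) -> np.ndarray:
    """21-vector of the symmetric outer product T (x) T.

    Normalized so that for any symmetric P, Q

        voigt21_outer(P) @ voigt21_outer(Q) == (P : Q)^2,

    i.e. 21-space inner products equal the full 4-index contraction of the
    corresponding 4th-order tensors.
    """
    v = voigt6(T)
    return svec21(np.outer(v, v))


def e_bulk() -> np.ndarray:
    """Isotropic 'bulk' 4th-order basis tensor as a 21-vector.

    In the 6x6 Voigt-matrix picture it is (1/9) * ones on the upper-left
    3x3 block; its contraction with <D (x) D> extracts the squared bulk
    (mean-diffusivity) part: <e_bulk, voigt21_outer(D)> = (tr D / 3)^2.
    """
    E = np.zeros((6, 6))
    E[:3, :3] = 1.0 / 9.0
    return svec21(E)


def e_shear() -> np.ndarray:
    """Isotropic 'shear' 4th-order basis tensor as a 21-vector.

    Complements :func:`e_bulk`: for a single tensor D with eigenvalues l_i,
    <e_shear, voigt21_outer(D)> = (1/9) * sum_{i<j} (l_i - l_j)^2, the
    variance-of-eigenvalues (anisotropy) part of D (x) D.
    """
    E = np.zeros((6, 6))
    E[:3, :3] = -1.0 / 9.0
    np.fill_diagonal(E[:3, :3], 2.0 / 9.0)
    E[3:, 3:] = np.diag([3.0 / 9.0] * 3)
    return svec21(E)


def btensor_from_shape(g: np.ndarray, b: float, b_delta: float) -> np.ndarray:
    """Construct an axisymmetric b-tensor from (direction, b-value, shape).

    Parameters
    ----------
    g
        Unit 3-vector, the principal symmetry axis.
    b
        b-value in ms/um^2 (the trace of the returned tensor), >= 0.
    b_delta
        Tensor-shape anisotropy in [-0.5, 1]: 1 = linear (LTE),
        0 = spherical (STE), -0.5 = planar (PTE) encoding.

    Returns
    -------
    3x3 symmetric tensor with eigenvalues (b_perp, b_perp, b_par),
    b_par = b (1 + 2 b_delta) / 3 along g, b_perp = b (1 - b_delta) / 3.
    """
    g = np.asarray(g, dtype=float)
    if g.shape != (3,):
        raise ValueError(f"direction must be a 3-vector, got shape {g.shape}")
    nrm = np.linalg.norm(g)
    if abs(nrm - 1.0) > 1e-8:
        raise ValueError(f"direction must be unit norm (|g| = {nrm:.3e})")
    if b < 0:
        raise ValueError(f"b-value must be nonnegative, got {b}")
    if not -0.5 <= b_delta <= 1.0:
        raise ValueError(f"b_delta must lie in [-0.5, 1], got {b_delta}")
    b_par = b * (1.0 + 2.0 * b_delta) / 3.0
    b_perp = b * (1.0 - b_delta) / 3.0
    return b_perp * np.eye(3) + (b_par - b_perp) * np.outer(g, g)


def btensor_shape(B: np.ndarray, axis_hint: np.ndarray | None = None):
    """Recover (g, b, b_delta) from an axisymmetric b-tensor.

    ``b`` is the trace; ``b_delta = (b_par - b_perp) / b``.  The axial
    eigenvalue is the one whose eigenvector is most aligned with
    ``axis_hint`` when given, else the eigenvalue farthest from the mean of
    the other two (ties, i.e. the fully isotropic case, give b_delta = 0 and
    the stored/default axis).
    """
    B = np.asarray(B, dtype=float)
    b = float(np.trace(B))
    w, V = np.linalg.eigh(B)
    if b <= 0 or np.ptp(w) < 1e-12 * max(1.0, abs(b)):
        g = np.array([0.0, 0.0, 1.0]) if axis_hint is None else np.asarray(axis_hint, float)
        return g, b, 0.0
    if axis_hint is not None:
        k = int(np.argmax(np.abs(V.T @ np.asarray(axis_hint, float))))
    else:
        # isolated eigenvalue = farthest from the mean of the other two
        dev = [abs(w[i] - 0.5 * (w[(i + 1) % 3] + w[(i + 2) % 3])) for i in range(3)]
        k = int(np.argmax(dev))
    b_par = w[k]
    b_perp = 0.5 * (w.sum() - b_par)
    g = V[:, k]
    return g, b, float((b_par - b_perp) / b)
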
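import numpy as np
import pytest

import qtidesign as q


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_symmetric(rng, scale=1.0):
    T = rng.standard_normal((3, 3)) * scale
    return T + T.T


def random_spd(rng, scale=1.0):
    T = rng.standard_normal((3, 3)) * scale
    return T @ T.T + 0.01 * np.eye(3)


def dual_projected_gradient_gap(P, qv, G, x, n_iter=30000):
    """Weak-duality certificate for min 1/2 x'Px + q'x s.t. Gx <= 0.

    Runs accelerated projected gradient (FISTA) on the dual; returns
    f(x) - g(lam), which upper-bounds the primal suboptimality of x for
    any dual-feasible lam.
    """
    Pinv = np.linalg.inv(P)
    M = G @ Pinv @ G.T
    c = G @ Pinv @ qv
    lr = 1.0 / np.linalg.eigvalsh(M).max()
    lam = np.zeros(G.shape[0])
    y, t = lam.copy(), 1.0
    for _ in range(n_iter):
        lam_new = np.maximum(y - lr * (M @ y + c), 0.0)
        t_new = 0.5 * (1 + np.sqrt(1 + 4 * t * t))
        y = lam_new + (t - 1) / t_new * (lam_new - lam)
        lam, t = lam_new, t_new
    v = qv + G.T @ lam
    dual_value = -0.5 * v @ Pinv @ v
    return (0.5 * x @ P @ x + qv @ x) - dual_value


@pytest.fixture(scope="session")
def q3_scheme():
    return q.packaged_scheme("q3")


@pytest.fixture(scope="session")
def q1_scheme():
    return q.packaged_scheme("q1")


@pytest.fixture(scope="session")
def small_population():
    """20 synthetic WM/GM voxels used across estimator tests."""
    return q.synth_population(20, seed=42)


@pytest.fixture(scope="session")
def wm_theta(small_population):
    """A single coherent-ish anisotropic voxel's parameter vector."""
    return small_population[0][0]
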
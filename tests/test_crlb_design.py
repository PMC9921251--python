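"""Fisher information, CRLB propagation, design criteria and optimizer."""

import numpy as np
import pytest

import qtidesign as q
from qtidesign.crlb_design import (
    _BatchObjective,
    _kmeans_1d,
    _metric_gradients,
    electrostatic_directions,
)
from qtidesign.qti_model import theta_from_parts
from qtidesign.tensor_algebra import voigt6


class TestFisherInformation:
    def test_sigma_scaling_and_symmetry(self, wm_theta, q3_scheme):
        i1 = q.fisher_information(wm_theta, q3_scheme, sigma=0.05).matrix
        i2 = q.fisher_information(wm_theta, q3_scheme, sigma=0.10).matrix
        assert np.allclose(i1, 4.0 * i2, rtol=1e-12)
        assert np.allclose(i1, i1.T)
        assert np.linalg.eigvalsh(i1).min() >= -1e-8 * np.abs(i1).max()

    def test_matches_finite_difference_jacobian(self, wm_theta, q3_scheme):
        """FIM equals (1/sigma^2) J^T J with J the numeric signal Jacobian."""
        sigma = 1.0 / 25.0
        A = q.design_matrix(q3_scheme)
        J = np.empty((len(q3_scheme), 28))
        for i in range(28):
            h = max(1e-6 * abs(wm_theta[i]), 1e-9)
            tp = wm_theta.copy(); tp[i] += h
            tm = wm_theta.copy(); tm[i] -= h
            J[:, i] = (q.forward_signal(tp, q3_scheme, A=A)
                       - q.forward_signal(tm, q3_scheme, A=A)) / (2 * h)
        ref = J.T @ J / sigma ** 2
        fim = q.fisher_information(wm_theta, q3_scheme, sigma).matrix
        assert (np.linalg.norm(fim - ref) / np.linalg.norm(ref)) < 1e-6

    def test_additive_over_concatenated_schemes(self, wm_theta, q3_scheme,
                                                q1_scheme):
        sigma = 0.04
        both = q3_scheme.concatenate(q1_scheme)
        i_both = q.fisher_information(wm_theta, both, sigma).matrix
        i_sum = (q.fisher_information(wm_theta, q3_scheme, sigma).matrix
                 + q.fisher_information(wm_theta, q1_scheme, sigma).matrix)
        assert np.allclose(i_both, i_sum, rtol=1e-12)


class TestMetricCRLB:
    def test_md_gradient_is_linear(self, q3_scheme):
        theta = theta_from_parts(0.0, 1.2 * voigt6(np.eye(3)), np.zeros(21))
        M = _metric_gradients(theta, ("md",))
        expect = np.zeros(28)
        expect[1:4] = 1.0 / 3.0
        assert np.allclose(M[:, 0], expect, atol=1e-7)

    def test_md_crlb_matches_analytic_delta_method(self, wm_theta,
                                                   q3_scheme):
        sigma = 1 / 25
        crlb = q.metric_crlb(wm_theta, q3_scheme, sigma, metrics=("md",))
        m = np.zeros(28)
        m[1:4] = 1.0 / 3.0
        I = q.fisher_information(wm_theta, q3_scheme, sigma).matrix
        ref = m @ np.linalg.solve(I, m)
        assert crlb.variances[0] == pytest.approx(ref, rel=1e-6)

    def test_information_monotonicity(self, wm_theta, q3_scheme, rng):
        """Appending any sample never increases a metric variance bound."""
        sigma = 1 / 20
        base = q.metric_crlb(wm_theta, q3_scheme, sigma).variances
        for _ in range(10):
            g = rng.standard_normal(3)
            g /= np.linalg.norm(g)
            extra = q.AcquisitionScheme(
                g[None], [rng.uniform(0.1, 2)], [rng.uniform(-0.5, 1)])
            grown = q.metric_crlb(wm_theta, q3_scheme.concatenate(extra),
                                  sigma).variances
            assert np.all(grown <= base * (1 + 1e-9))


class TestCriteria:
    def test_f2_duplication_identity(self, wm_theta, q3_scheme):
        """Doubling every sample lowers log det CRLB by exactly 28 log 2."""
        sigma = 1 / 15
        f = q.criterion_f2(wm_theta, q3_scheme, sigma)
        doubled = q3_scheme.concatenate(q3_scheme)
        f2x = q.criterion_f2(wm_theta, doubled, sigma)
        assert f2x == pytest.approx(f - 28 * np.log(2.0), abs=1e-6)

    def test_f2_row_order_invariance_and_singular_sentinel(self, wm_theta,
                                                           q3_scheme, rng):
        sigma = 1 / 15
        perm = rng.permutation(len(q3_scheme))
        shuffled = q.AcquisitionScheme(q3_scheme.directions[perm],
                                       q3_scheme.b[perm],
                                       q3_scheme.b_delta[perm])
        assert q.criterion_f2(wm_theta, shuffled, sigma) == pytest.approx(
            q.criterion_f2(wm_theta, q3_scheme, sigma), abs=1e-8)
        tiny = q.AcquisitionScheme(q3_scheme.directions[:10],
                                   q3_scheme.b[:10], q3_scheme.b_delta[:10])
        assert q.criterion_f2(wm_theta, tiny, sigma) == float("inf")

    def test_f3_weighting_behaviour(self, wm_theta, q3_scheme):
        sigma = 1 / 15
        crlb = q.metric_crlb(wm_theta, q3_scheme, sigma, metrics=("ufa",))
        f_single = q.criterion_f3(wm_theta, q3_scheme, sigma,
                                  metrics=("ufa",), weights=[1.0])
        assert f_single == pytest.approx(crlb.variances[0], rel=1e-9)
        f_scaled = q.criterion_f3(wm_theta, q3_scheme, sigma,
                                  metrics=("ufa",), weights=[3.0])
        assert f_scaled == pytest.approx(3 * f_single, rel=1e-12)

    def test_f3_never_increases_with_more_samples(self, wm_theta, q3_scheme,
                                                  q1_scheme):
        sigma = 1 / 15
        f_base = q.criterion_f3(wm_theta, q3_scheme, sigma)
        f_more = q.criterion_f3(wm_theta, q3_scheme.concatenate(q1_scheme),
                                sigma)
        assert f_more <= f_base + 1e-12

    def test_joint_rotation_invariance(self, small_population, q3_scheme,
                                       rng):
        """Rotating the scheme and the voxel together leaves f2/f3 fixed."""
        theta, dtd = small_population[3]
        sigma = 1 / 15
        R = np.linalg.qr(rng.standard_normal((3, 3)))[0]
        if np.linalg.det(R) < 0:
            R[:, 0] *= -1
        rot_scheme = q.AcquisitionScheme(q3_scheme.directions @ R.T,
                                         q3_scheme.b, q3_scheme.b_delta)
        theta_rot = q.theta_from_mixture(dtd.rotated(R))
        assert q.criterion_f2(theta_rot, rot_scheme, sigma) == pytest.approx(
            q.criterion_f2(theta, q3_scheme, sigma), abs=1e-8)
        assert q.criterion_f3(theta_rot, rot_scheme, sigma) == pytest.approx(
            q.criterion_f3(theta, q3_scheme, sigma), rel=1e-6)


class TestPopulationObjective:
    def test_single_prior_and_permutation_invariance(self, small_population,
                                                     q3_scheme):
        sigma = 1 / 15
        thetas = np.stack([t for t, _ in small_population[:6]])
        f1 = q.population_objective(thetas[:1], q3_scheme, sigma, "f2")
        assert f1 == pytest.approx(
            q.criterion_f2(thetas[0], q3_scheme, sigma), rel=1e-12)
        fwd = q.population_objective(thetas, q3_scheme, sigma, "f2")
        rev = q.population_objective(thetas[::-1], q3_scheme, sigma, "f2")
        assert fwd == pytest.approx(rev, rel=1e-12)

    def test_batch_objective_matches_reference(self, small_population):
        """The optimizer's vectorized objective equals the public one."""
        sigma = 1 / 15
        thetas = np.stack([t for t, _ in small_population[:5]])
        G = electrostatic_directions(40, seed=3)
        rng = np.random.default_rng(0)
        b = rng.uniform(0.1, 2.0, 40)
        bd = rng.uniform(-0.5, 1.0, 40)
        scheme = q.AcquisitionScheme(G, b, bd)
        x = np.concatenate([b, bd])
        for crit in ("f2", "f3"):
            fast = _BatchObjective(thetas, G, sigma, crit)(x)
            ref = q.population_objective(thetas, scheme, sigma, crit)
            assert fast == pytest.approx(ref, rel=1e-9)


class TestElectrostaticDirections:
    def test_unit_norm_and_determinism(self):
        u1 = electrostatic_directions(30, seed=9)
        u2 = electrostatic_directions(30, seed=9)
        assert np.array_equal(u1, u2)
        assert np.allclose(np.linalg.norm(u1, axis=1), 1.0, atol=1e-10)

    def test_two_points_are_orthogonal(self):
        u = electrostatic_directions(2, seed=4)
        angle = np.degrees(np.arccos(abs(u[0] @ u[1])))
        assert angle == pytest.approx(90.0, abs=0.5)

    def test_six_points_reach_icosahedral_energy(self):
        """n=6 antipodal optimum: icosahedron vertices (upper half)."""
        from qtidesign.crlb_design import _antipodal_energy_grad
        phi = (1 + np.sqrt(5)) / 2
        ico = np.array([[0, 1, phi], [0, -1, phi], [1, phi, 0],
                        [-1, phi, 0], [phi, 0, 1], [-phi, 0, 1]], float)
        ico /= np.linalg.norm(ico, axis=1, keepdims=True)
        e_ref, _ = _antipodal_energy_grad(ico)
        u = electrostatic_directions(6, seed=0)
        e, _ = _antipodal_energy_grad(u)
        assert e <= e_ref * 1.005


class TestOptimizerAndClustering:
    @pytest.fixture(scope="class")
    def small_problem(self, small_population):
        thetas = np.stack([t for t, _ in small_population[:5]])
        return q.DesignProblem(priors=thetas, n_samples=40, criterion="f2",
                               sigma=1 / 15, seed=11, max_evals=1500)

    def test_descent_and_reproducibility(self, small_problem):
        r1 = q.optimize_scheme(small_problem)
        assert r1.objective <= r1.initial_objective
        r2 = q.optimize_scheme(small_problem)
        assert np.array_equal(r1.scheme.b, r2.scheme.b)
        assert np.array_equal(r1.scheme.b_delta, r2.scheme.b_delta)
        assert np.array_equal(r1.scheme.directions, r2.scheme.directions)

    def test_cluster_preserves_counts_and_shelled_schemes(self, q3_scheme):
        cl = q.cluster_scheme(q3_scheme, seed=3)
        assert len(cl) == len(q3_scheme)
        assert np.allclose(np.sort(cl.b), np.sort(q3_scheme.b))
        assert np.allclose(np.sort(cl.b_delta), np.sort(q3_scheme.b_delta))

    def test_kmeans_recovers_exact_shells(self):
        vals = np.array([0.1] * 5 + [0.8] * 7 + [2.0] * 8)
        centers, lab, wcss = _kmeans_1d(vals, 3)
        assert wcss == pytest.approx(0.0, abs=1e-20)
        assert np.allclose(np.sort(centers), [0.1, 0.8, 2.0])


class TestPrecisionGain:
    def test_self_comparison_and_sigma_invariance(self, wm_theta, q3_scheme,
                                                  q1_scheme):
        g_self = q.precision_gain(q3_scheme, q3_scheme, wm_theta, 0.04, "md")
        assert g_self == pytest.approx(1.0, rel=1e-12)
        g1 = q.precision_gain(q3_scheme, q1_scheme, wm_theta, 0.04, "ufa")
        g2 = q.precision_gain(q3_scheme, q1_scheme, wm_theta, 0.08, "ufa")
        assert g1 == pytest.approx(g2, rel=1e-9)

    def test_duplication_doubles_precision(self, wm_theta, q1_scheme):
        doubled = q1_scheme.concatenate(q1_scheme)
        for which in (0, 5, "md", "mki"):
            gain = q.precision_gain(doubled, q1_scheme, wm_theta, 0.05, which)
            assert gain == pytest.approx(2.0, rel=1e-6)
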
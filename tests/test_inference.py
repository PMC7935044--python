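"""Variational Laplace GLM, Bayesian model reduction, pruning, search."""

import numpy as np
import pytest

from blanketrg.inference import (EstimationConfig, PriorSpec, RowPosterior,
                                 bmr, build_glm_problem, build_operators,
                                 distance_model_search, estimate_jacobian,
                                 fit_glm_vl, prune_reciprocal, _assemble)
from blanketrg.synthgen import (GridGeometry, TimeSeriesMatrix,
                                make_geometry, sample_jacobian)


class TestOperators:
    def test_derivative_annihilates_constants(self):
        ops = build_operators(64, 2.0)
        assert np.abs(ops.derivative @ np.ones(64)).max() < 1e-12

    def test_derivative_of_ramp_is_one(self):
        tr = 2.0
        ops = build_operators(64, tr)
        ramp = np.arange(64.0) * tr
        interior = (ops.derivative @ ramp)[1:-1]
        np.testing.assert_allclose(interior, 1.0)

    def test_kernel_and_derivative_commute_exactly(self):
        ops = build_operators(128, 1.0)
        s = np.sin(2 * np.pi * np.arange(128) / 16)
        k, d = ops.kernels[0], ops.derivative
        resid = np.linalg.norm((k @ d - d @ k) @ s) / np.linalg.norm(s)
        assert resid < 1e-12

    def test_component_spectra_are_nonnegative(self):
        ops = build_operators(64, 1.0, basis_count=2)
        assert np.all(ops.component_spectra >= 0)
        assert len(ops.component_names) == 5   # k1, k2, sum, deriv, identity

    def test_basis_count_validated(self):
        with pytest.raises(ValueError):
            build_operators(64, 1.0, basis_count=0)


class TestFitGlmVl:
    def _noiseless_problem(self, t=2000, n=10, seed=0):
        rng = np.random.default_rng(seed)
        jac = -0.5 * np.eye(n) + 0.1 * rng.standard_normal((n, n))
        y = rng.standard_normal((t, n))
        series = TimeSeriesMatrix(values=y, sampling_interval=1.0)
        problem = build_glm_problem(series)
        problem.response[:] = (y - y.mean(0)) @ jac.T
        return problem, jac

    def test_noiseless_fit_matches_least_squares_oracle(self):
        problem, jac = self._noiseless_problem()
        gls, *_ = np.linalg.lstsq(problem.design, problem.response,
                                  rcond=None)
        row = fit_glm_vl(problem, PriorSpec(), 0)
        assert np.abs(row.mean - gls.T[0]).max() < 0.05
        assert np.abs(row.mean - jac[0]).max() < 0.05

    def test_free_energy_nondecreasing(self):
        problem, _ = self._noiseless_problem(t=256, n=6, seed=1)
        row = fit_glm_vl(problem, PriorSpec(), 2)
        assert np.all(np.diff(row.free_energy_trace) >= -1e-6)

    def test_null_data_gives_null_posterior(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal((200, 4))
        series = TimeSeriesMatrix(values=y, sampling_interval=1.0)
        problem = build_glm_problem(series)
        problem.response[:] = 0.0
        row = fit_glm_vl(problem, PriorSpec(diagonal_mean=0.0), 0)
        assert np.abs(row.mean).max() < 0.05
        assert np.isfinite(row.free_energy)

    def test_ill_conditioned_design_rejected(self):
        rng = np.random.default_rng(3)
        col = rng.standard_normal(100)
        y = np.column_stack([col, col, rng.standard_normal(100)])
        series = TimeSeriesMatrix(values=y, sampling_interval=1.0)
        problem = build_glm_problem(series)
        with pytest.raises(np.linalg.LinAlgError):
            fit_glm_vl(problem, PriorSpec(), 0)


class TestBmr:
    def test_identity_reduction_is_exact_zero(self):
        m = np.array([0.3, -0.1])
        s = np.array([[0.04, 0.01], [0.01, 0.09]])
        m0 = np.zeros(2)
        s0 = np.eye(2)
        delta, mr, sr = bmr(m, s, m0, s0, m0, s0)
        assert delta == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(mr, m)
        np.testing.assert_allclose(sr, s)

    def test_redundant_parameter_removal_gains_evidence(self):
        # posterior ~ prior: shrinking the parameter is (mildly) favored
        delta, _, _ = bmr([0.01], [[0.9]], [0.0], [[1.0]],
                          [0.0], [[1e-8]])
        assert delta > 0

    def test_supported_parameter_removal_loses_evidence(self):
        delta, _, _ = bmr([0.5], [[0.01]], [0.0], [[1.0]],
                          [0.0], [[1e-8]])
        assert delta < -3

    def test_delta_matches_conjugate_evidence_difference(self):
        """BMR equals the direct log-evidence difference of a refit on a
        two-parameter conjugate linear-Gaussian problem."""
        rng = np.random.default_rng(4)
        x = rng.standard_normal((50, 2))
        beta = np.array([0.8, 0.0])
        noise = 0.5
        y = x @ beta + rng.normal(0, np.sqrt(noise), 50)

        def log_evidence(prior_cov):
            cov = x @ prior_cov @ x.T + noise * np.eye(50)
            sign, logdet = np.linalg.slogdet(2 * np.pi * cov)
            return -0.5 * (logdet + y @ np.linalg.solve(cov, y))

        s0 = np.eye(2)
        s0r = np.diag([1.0, 1e-6])
        prec = x.T @ x / noise + np.linalg.inv(s0)
        s_post = np.linalg.inv(prec)
        m_post = s_post @ (x.T @ y / noise)
        delta, _, _ = bmr(m_post, s_post, np.zeros(2), s0, np.zeros(2), s0r)
        direct = log_evidence(s0r) - log_evidence(s0)
        assert delta == pytest.approx(direct, abs=0.1)

    def test_singular_reduced_precision_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            bmr([0.0], [[1.0]], [0.0], [[1e-9]], [0.0], [[1.0]])


def _synthetic_posterior(mean_matrix, sd, prior_var=4.0):
    """Assemble a JacobianPosterior from a dense coupling matrix."""
    n = mean_matrix.shape[0]
    rows = []
    for i in range(n):
        cols = np.arange(n)
        m0 = np.zeros(n)
        m0[i] = -0.5
        rows.append(RowPosterior(
            row_index=i, columns=cols, mean=mean_matrix[i].copy(),
            cov=np.eye(n) * sd ** 2, prior_mean=m0,
            prior_cov=np.eye(n) * prior_var, free_energy=0.0,
            free_energy_trace=np.zeros(1), hyper_mean=np.zeros(1),
            hyper_cov=np.eye(1), input_mean=np.zeros(0), converged=True))
    return _assemble(rows, n, [])


class TestPruneReciprocal:
    def test_infinite_threshold_removes_nothing(self):
        mat = np.full((4, 4), 0.001)
        np.fill_diagonal(mat, -0.5)
        post = _synthetic_posterior(mat, sd=0.05)
        pruned = prune_reciprocal(post, threshold_nats=np.inf)
        np.testing.assert_array_equal(pruned.support, post.support)

    def test_null_pair_removed_strong_pair_kept(self):
        mat = np.zeros((4, 4))
        np.fill_diagonal(mat, -0.5)
        mat[0, 1] = mat[1, 0] = 0.5       # strong reciprocal pair
        mat[2, 3] = mat[3, 2] = 0.002     # planted-null pair
        post = _synthetic_posterior(mat, sd=0.04)
        pruned = prune_reciprocal(post)
        assert pruned.support[0, 1] and pruned.support[1, 0]
        assert not pruned.support[2, 3] and not pruned.support[3, 2]
        assert pruned.mean[2, 3] == 0.0

    def test_retained_means_keep_their_sign(self):
        rng = np.random.default_rng(5)
        mat = rng.normal(0, 0.2, (6, 6))
        np.fill_diagonal(mat, -0.5)
        post = _synthetic_posterior(mat, sd=0.04)
        pruned = prune_reciprocal(post)
        kept = pruned.support & ~np.eye(6, dtype=bool)
        assert np.all(np.sign(pruned.mean[kept]) == np.sign(mat[kept]))


class TestDistanceModelSearch:
    def _posterior_with_range(self, geometry, max_range):
        dist = geometry.mirrored_distances()
        mat = np.where(dist <= max_range, 0.3, 0.0)
        np.fill_diagonal(mat, -0.5)
        return _synthetic_posterior(mat, sd=0.03)

    def test_planted_range_detected(self):
        geometry = make_geometry(32, 6.0, "grid", seed=0)
        post = self._posterior_with_range(geometry, 18.0)
        radii, profile, best = distance_model_search(
            post, geometry, (8.0, 12.0, 16.0, 20.0, 24.0, 28.0, 32.0),
            homologous_exempt=False)
        assert best >= 18.0
        assert best == min(r for r in radii if r >= 18.0)

    def test_single_radius_profile(self):
        geometry = make_geometry(8, 4.0, "grid", seed=0)
        post = self._posterior_with_range(geometry, 8.0)
        radii, profile, best = distance_model_search(post, geometry, [32.0])
        assert len(profile) == 1 and best == 32.0

    def test_zero_couplings_give_flat_profile(self):
        geometry = make_geometry(8, 4.0, "grid", seed=0)
        mat = np.diag(np.full(16, -0.5))
        post = _synthetic_posterior(mat, sd=0.03)
        # masked-out (zero) couplings contribute nothing at any radius
        post.support[:] = np.eye(16, dtype=bool)
        radii, profile, _ = distance_model_search(
            post, geometry, (8.0, 16.0, 32.0))
        assert profile.max() < 1e-6

    def test_empty_radii_rejected(self):
        geometry = make_geometry(8, 4.0, "grid", seed=0)
        post = self._posterior_with_range(geometry, 8.0)
        with pytest.raises(ValueError):
            distance_model_search(post, geometry, [])


class TestEstimateJacobian:
    def test_single_channel_rejected(self):
        geo = GridGeometry(positions=np.array([[0.0, 0, 0], [4.0, 0, 0]]))
        series = TimeSeriesMatrix(values=np.random.default_rng(0)
                                  .standard_normal((100, 1)),
                                  sampling_interval=1.0)
        with pytest.raises(ValueError):
            estimate_jacobian(series, geo)

    def test_inputs_enter_bookkeeping_not_jacobian(self, small_geometry,
                                                   default_system):
        from tests.conftest import noisy_observation
        series = noisy_observation(default_system, seed=0, n_samples=300)
        u = np.sin(np.arange(300) / 20.0)[:, None]
        post = estimate_jacobian(series, small_geometry, inputs=u)
        assert post.input_effects is not None
        assert post.input_effects.shape == (small_geometry.n_states, 1)
        assert post.mean.shape == (20, 20)

    def test_provenance_records_every_stage(self, small_geometry,
                                            default_system):
        from tests.conftest import noisy_observation
        series = noisy_observation(default_system, seed=1, n_samples=300)
        post = estimate_jacobian(series, small_geometry)
        text = "\n".join(post.provenance)
        assert "hard bound" in text
        assert "prune_reciprocal" in text
        assert "distance search" in text

    def test_masked_entries_are_exactly_zero(self, small_geometry,
                                             default_system):
        from tests.conftest import noisy_observation
        series = noisy_observation(default_system, seed=2, n_samples=300)
        post = estimate_jacobian(series, small_geometry)
        assert np.all(post.mean[~post.support] == 0.0)
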
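"""Renormalization group: seeding, adiabatic reduction, scaling fits."""

import numpy as np
import pytest

from blanketrg.renorm import (RGConfig, adiabatic_reduce, coarse_grain,
                              extrapolate_scales, fit_scaling,
                              mirrored_center_distances, particle_centers,
                              run_rg, scale_summaries,
                              seed_particles_from_voxels)
from blanketrg.partition import particular_partition
from blanketrg.synthgen import (make_hierarchical_system,
                                make_scale_free_system)


class TestSeedParticles:
    def test_radius_covering_field_gives_single_particle(self):
        rng = np.random.default_rng(0)
        series = rng.standard_normal((50, 12))
        positions = rng.uniform(0, 5, (12, 3))
        eigv, loads, groups = seed_particles_from_voxels(series, positions,
                                                         radius=100.0)
        assert len(groups) == 1
        # eigenvariate equals the first principal component series
        centered = series - series.mean(0)
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        pc1 = u[:, 0] * s[0]
        match = abs(np.corrcoef(eigv[:, 0], pc1)[0, 1])
        assert match == pytest.approx(1.0, abs=1e-10)

    def test_duplicate_voxels_fully_explained(self):
        rng = np.random.default_rng(1)
        col = rng.standard_normal(40)
        series = np.column_stack([col, col, col])
        positions = np.zeros((3, 3))
        eigv, loads, groups = seed_particles_from_voxels(series, positions,
                                                         radius=10.0)
        centered = series - series.mean(0)
        explained = np.var(eigv[:, 0]) * np.sum(loads[:, 0] ** 2)
        assert explained == pytest.approx(centered.var(axis=0).sum() * 1.0,
                                          rel=1e-8)

    def test_eigenvariate_variance_bounded_by_voxel_variance(self):
        rng = np.random.default_rng(2)
        series = rng.standard_normal((80, 200)) * \
            rng.uniform(0.5, 2.0, 200)
        positions = rng.uniform(0, 30, (200, 3))
        eigv, _, _ = seed_particles_from_voxels(series, positions,
                                                radius=6.0)
        total_eig = np.var(eigv, axis=0).sum()
        total_vox = np.var(series - series.mean(0), axis=0).sum()
        assert total_eig <= total_vox * (1 + 1e-9)

    def test_sign_fixed_on_seed_voxel(self):
        rng = np.random.default_rng(3)
        series = rng.standard_normal((60, 5))
        positions = rng.uniform(0, 2, (5, 3))
        _, loads, groups = seed_particles_from_voxels(series, positions,
                                                      radius=50.0)
        variances = series.var(axis=0)
        seed_voxel = int(np.argmax(variances))
        assert loads[seed_voxel, 0] > 0

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            seed_particles_from_voxels(np.empty((0, 0)), np.empty((0, 3)))


class TestAdiabaticReduce:
    def test_diagonal_eigenvalues_thresholded(self):
        pe = adiabatic_reduce(np.diag([-0.5, -2.0, -10.0]),
                              dissipation_threshold=1.0)
        assert pe.n_retained == 1
        assert pe.eigenvalues[0] == pytest.approx(-0.5)

    def test_conjugate_pair_never_split_at_cap(self):
        block = np.array([[-0.2, -1.3], [1.3, -0.2]])
        pe = adiabatic_reduce(block, dissipation_threshold=1.0, max_modes=1)
        assert pe.n_retained == 2
        assert pe.eigenvalues[0] == pytest.approx(
            np.conj(pe.eigenvalues[1]))

    def test_all_fast_keeps_single_slowest(self):
        pe = adiabatic_reduce(np.diag([-3.0, -5.0, -9.0]),
                              dissipation_threshold=1.0)
        assert pe.n_retained == 1
        assert pe.eigenvalues[0] == pytest.approx(-3.0)

    def test_left_inverse_property(self):
        rng = np.random.default_rng(4)
        jac = -np.eye(5) + 0.3 * rng.standard_normal((5, 5))
        pe = adiabatic_reduce(jac, dissipation_threshold=10.0, max_modes=5)
        resid = pe.left_inverse @ pe.eigenvectors - np.eye(pe.n_retained)
        assert np.abs(resid).max() < 1e-8


class TestCoarseGrain:
    def test_single_particle_gives_diagonal_jacobian(self):
        jac = np.array([[-1.0, 0.4, 0.0],
                        [0.4, -1.0, 0.5],
                        [0.0, 0.5, -2.0]])
        part = particular_partition(jac, n_internal=1)
        assert part.n_particles == 1
        nxt, eigens, blankets, _ = coarse_grain(jac, part,
                                                RGConfig(max_modes=3))
        off = nxt - np.diag(np.diag(nxt))
        assert np.abs(off).max() < 1e-12

    def test_uncoupled_particles_have_zero_extrinsic_blocks(self):
        system, truth = make_hierarchical_system([4, 4],
                                                 between_strength=0.0,
                                                 seed=0)
        nxt, eigens, _, pos = coarse_grain(system.jacobian, truth,
                                           RGConfig(max_modes=2))
        for i in range(nxt.shape[0]):
            for j in range(nxt.shape[0]):
                if pos[i] != pos[j]:
                    assert nxt[i, j] == 0.0

    def test_intrinsic_block_identity(self):
        """xi^- J(b,b) xi equals diag(lambda) on retained modes."""
        system, truth = make_hierarchical_system([5, 5, 5], seed=3)
        jac = system.jacobian
        cfg = RGConfig(max_modes=2, dissipation_threshold=1e6)
        _, eigens, blankets, _ = coarse_grain(jac, truth, cfg)
        for pe, b in zip(eigens, blankets):
            block = jac[np.ix_(b, b)]
            resid = pe.left_inverse @ block @ pe.eigenvectors \
                - np.diag(pe.eigenvalues)
            assert np.abs(resid).max() < 1e-8


class TestRunRg:
    def test_dimension_strictly_decreasing(self):
        system, info = make_scale_free_system(n_levels=3, seed=0)
        model = run_rg(system, n_scales=4,
                       config=RGConfig(**info["rg_config"]))
        dims = [s.n_states for s in model.scales]
        assert dims == [64, 16, 4, 1]
        assert all(a > b for a, b in zip(dims, dims[1:]))

    def test_mean_decay_rate_nondecreasing(self):
        system, info = make_scale_free_system(n_levels=2, seed=1)
        model = run_rg(system, n_scales=3,
                       config=RGConfig(**info["rg_config"]))
        rates = model.mean_decay_rates()
        assert np.all(np.diff(rates) >= -1e-10)
        assert model.provenance["progressive_slowing"]

    def test_rerun_is_bit_identical(self):
        system, info = make_scale_free_system(n_levels=2, seed=2)
        cfg = RGConfig(**info["rg_config"])
        a = run_rg(system, n_scales=3, config=cfg)
        b = run_rg(system, n_scales=3, config=cfg)
        for sa, sb in zip(a.scales, b.scales):
            np.testing.assert_array_equal(sa.jacobian, sb.jacobian)
            np.testing.assert_array_equal(sa.eigenmodes, sb.eigenmodes)


class TestEigenmodesAndCenters:
    def test_identity_chain_preserves_base_modes(self):
        # diagonal (uncoupled) blanket Jacobians give identity eigenvectors
        jac = np.diag([-0.5, -0.5, -0.6, -0.6])
        jac[0, 1] = jac[1, 0] = 0.3
        jac[2, 3] = jac[3, 2] = 0.3
        model = run_rg(jac, None, n_scales=2,
                       config=RGConfig(n_internal=1, max_modes=2,
                                       dissipation_threshold=1e6))
        modes = model.scales[-1].eigenmodes
        # every top-scale mode is supported on exactly one particle's states
        for k in range(modes.shape[1]):
            support = np.abs(modes[:, k]) > 1e-10
            assert support.sum() <= 2

    def test_center_of_equal_two_voxel_mode_is_midpoint(self):
        positions = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        modes = np.array([[1.0], [1.0]])
        centers = particle_centers(modes, positions)
        np.testing.assert_allclose(centers[0], [1.0, 0, 0])

    def test_zero_temperature_limit_is_argmax(self):
        positions = np.array([[0.0, 0, 0], [2.0, 0, 0], [4.0, 0, 0]])
        modes = np.array([[0.1], [0.9], [0.3]])
        centers = particle_centers(modes, positions, temperature=1e-9)
        np.testing.assert_allclose(centers[0], [2.0, 0, 0], atol=1e-6)

    def test_homologous_modes_have_zero_mirrored_distance(self):
        positions = np.array([[-3.0, 1, 0], [3.0, 1, 0]])
        modes = np.array([[1.0, 0.0], [0.0, 1.0]])
        centers = particle_centers(modes, positions, temperature=1e-9)
        dist = mirrored_center_distances(centers, positions,
                                         hemisphere_axis=0)
        assert dist[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_zero_mode_rejected(self):
        with pytest.raises(ValueError):
            particle_centers(np.zeros((4, 1)), np.zeros((4, 3)))


class TestScaleSummaries:
    def test_time_constant_is_reciprocal_rate(self):
        jac = np.diag([-2.0, -2.0])
        jac[0, 1] = jac[1, 0] = 1e-8
        model = run_rg(jac, None, n_scales=1)
        tau, ell, excluded = scale_summaries(model)
        assert tau[0] == pytest.approx(0.5)
        assert excluded == [0]

    def test_uniform_mode_extent_is_cube_root_of_volume(self):
        system, info = make_scale_free_system(n_levels=1, seed=0,
                                              spacing=1.0)
        model = run_rg(system, n_scales=2,
                       config=RGConfig(**info["rg_config"]))
        tau, ell, _ = scale_summaries(model)
        # scale-2 modes spread uniformly over two 1-mm^3 voxels
        assert ell[1] == pytest.approx(2.0 ** (1 / 3), rel=1e-2)

    def test_planted_two_scale_slowing(self):
        system, info = make_scale_free_system(n_levels=1, seed=3)
        model = run_rg(system, n_scales=2,
                       config=RGConfig(**info["rg_config"]))
        tau, _, _ = scale_summaries(model)
        assert tau[1] > tau[0]


class TestScalingFit:
    def test_printed_geometric_series_reproduced(self):
        i = np.arange(4)
        tau = 0.374 * 2.37 ** i
        ell = 1.82 * 2.13 ** i
        fit = fit_scaling(tau, ell)
        assert round(fit.alpha, 2) == 1.14
        assert fit.factor_tau == pytest.approx(2.37)
        assert fit.factor_ell == pytest.approx(2.13)

    def test_constant_time_scale_gives_zero_exponent(self):
        fit = fit_scaling(np.full(4, 0.5), 1.82 * 2.13 ** np.arange(4))
        assert fit.alpha == pytest.approx(0.0, abs=1e-12)

    def test_two_points_interpolate_exactly(self):
        fit = fit_scaling([0.5, 1.0], [2.0, 5.0])
        assert np.abs(fit.residuals).max() < 1e-12

    def test_nonpositive_summaries_rejected(self):
        with pytest.raises(ValueError):
            fit_scaling([0.5, -1.0], [2.0, 5.0])


class TestExtrapolation:
    @pytest.fixture()
    def printed_fit(self):
        i = np.arange(4)
        return fit_scaling(0.374 * 2.37 ** i, 1.82 * 2.13 ** i)

    def test_identity_at_scale_zero(self, printed_fit):
        ell, tau = extrapolate_scales(printed_fit, 0)
        assert tau[0] == pytest.approx(0.374)
        assert ell[0] == pytest.approx(1.82)

    def test_four_scales_up_is_about_twelve_seconds(self, printed_fit):
        ell, tau = extrapolate_scales(printed_fit, 4)
        assert tau[0] == pytest.approx(11.8, abs=0.05)
        assert ell[0] == pytest.approx(37.2, rel=0.01)

    def test_four_scales_down_is_about_twelve_milliseconds(self,
                                                           printed_fit):
        _, tau = extrapolate_scales(printed_fit, -4)
        assert tau[0] * 1e3 == pytest.approx(11.9, abs=0.05)
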
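"""Monte Carlo bootstrap inversion."""

import itertools

import numpy as np
import pytest

from mdrc.encoding import delta_spectra, protocol_frequency_band
from mdrc.forward import VoxelDistribution, signal_matrix
from mdrc.inversion import (
    InversionConfig,
    InversionLimits,
    MonteCarloInverter,
    bootstrap_ensemble,
    fit_weights,
    invert_voxel,
    sample_component,
    sample_components,
    voxel_rng,
)
from mdrc.metrics import weighted_moments

LIGHT = InversionConfig(n_candidates=150, n_refine=12, n_children=3, n_fresh=20)


class TestInversionLimits:
    def test_defaults_are_the_stated_box(self, limits):
        assert limits.d_min == 5e-12 and limits.d_max == 5e-9
        assert limits.gamma_min == 0.1 and limits.gamma_max == 1e5
        assert limits.r1_min == 0.1 and limits.r1_max == 4.0
        assert limits.r2_min == 4.0 and limits.r2_max == 100.0

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            InversionLimits(d_min=1e-9, d_max=1e-10)
        with pytest.raises(ValueError):
            InversionLimits(r1_min=-1.0)


class TestSampling:
    def test_draws_respect_limits(self, limits):
        dist = sample_components(limits, 10_000, np.random.default_rng(0))
        assert limits.contains(dist)
        assert np.all(dist.d_par <= dist.d0)
        assert np.all(dist.d_perp <= dist.d0)
        assert np.all(dist.w == 1.0)

    def test_orientations_uniform_on_sphere(self, limits):
        """Mean outer product of the principal axes approaches I/3."""
        dist = sample_components(limits, 40_000, np.random.default_rng(1))
        u = dist.principal_axes()
        outer = np.einsum("ia,ib->ab", u, u) / len(u)
        np.testing.assert_allclose(outer, np.eye(3) / 3, atol=0.01)

    def test_deterministic_under_seed(self, limits):
        a = sample_components(limits, 50, np.random.default_rng(7))
        b = sample_components(limits, 50, np.random.default_rng(7))
        np.testing.assert_array_equal(a.d0, b.d0)
        np.testing.assert_array_equal(a.theta, b.theta)
        c = sample_component(limits, np.random.default_rng(7))
        assert c.d0 == a.d0[0]


def _nnls_by_enumeration(A, y):
    """Independent NNLS oracle: exhaustive active-set search (small problems)."""
    n = A.shape[1]
    best_w, best_res = np.zeros(n), np.linalg.norm(y)
    for size in range(1, n + 1):
        for support in itertools.combinations(range(n), size):
            sol, *_ = np.linalg.lstsq(A[:, support], y, rcond=None)
            if np.any(sol < -1e-12):
                continue
            w = np.zeros(n)
            w[list(support)] = np.clip(sol, 0, None)
            res = np.linalg.norm(A @ w - y)
            if res < best_res - 1e-15:
                best_w, best_res = w, res
    return best_w, best_res


class TestFitWeights:
    def test_exactly_representable_signal(self, desk_protocol, desk_spectra, limits):
        rng = np.random.default_rng(3)
        basis = sample_components(limits, 8, rng)
        truth = basis.select(np.arange(8) == 2).with_weights([0.7])
        y = signal_matrix(truth, desk_protocol, desk_spectra) @ truth.w
        w, res = fit_weights(basis, y, desk_protocol, desk_spectra)
        assert w[2] == pytest.approx(0.7, rel=1e-8)
        assert np.sum(np.delete(w, 2)) == pytest.approx(0.0, abs=1e-10)
        assert res == pytest.approx(0.0, abs=1e-10)

    def test_zero_signals_give_zero_weights(self, desk_protocol, desk_spectra, limits):
        basis = sample_components(limits, 5, np.random.default_rng(4))
        w, res = fit_weights(basis, np.zeros(len(desk_protocol)),
                             desk_protocol, desk_spectra)
        assert np.all(w == 0.0) and res == 0.0

    def test_empty_basis_rejected(self, desk_protocol, desk_spectra):
        with pytest.raises(ValueError):
            fit_weights(VoxelDistribution.empty(), np.zeros(len(desk_protocol)),
                        desk_protocol, desk_spectra)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_against_enumeration_oracle(self, desk_protocol, desk_spectra, limits, seed):
        """5-component NNLS equals the exhaustive active-set optimum."""
        rng = np.random.default_rng(seed)
        basis = sample_components(limits, 5, rng)
        rows = list(range(0, len(desk_protocol), 7))
        proto = desk_protocol.subset(rows)
        spectra = [desk_spectra[i] for i in rows]
        y = rng.uniform(0, 1, len(rows))
        w, res = fit_weights(basis, y, proto, spectra)
        A = signal_matrix(basis, proto, spectra)
        w_ref, res_ref = _nnls_by_enumeration(A, y)
        assert res == pytest.approx(res_ref, abs=1e-8)


class TestInvertVoxel:
    def test_noiseless_isotropic_recovery(self, desk_protocol, desk_spectra,
                                          iso_component, omega_band):
        dist = VoxelDistribution.from_components([iso_component])
        y = signal_matrix(dist, desk_protocol, desk_spectra) @ dist.w
        fit = invert_voxel(y, desk_protocol, desk_spectra,
                           rng=np.random.default_rng(11))
        e_diso = weighted_moments(fit.distribution, "diso", omega_band[0]).e_x
        e_r2 = weighted_moments(fit.distribution, "r2", 0.0).e_x
        assert e_diso == pytest.approx(1e-9, rel=0.05)
        assert e_r2 == pytest.approx(20.0, rel=0.05)

    def test_residual_never_worse_than_initial(self, desk_protocol, desk_spectra,
                                               dispersive_component):
        dist = VoxelDistribution.from_components([dispersive_component])
        y = signal_matrix(dist, desk_protocol, desk_spectra) @ dist.w
        fit = invert_voxel(y, desk_protocol, desk_spectra, config=LIGHT,
                           rng=np.random.default_rng(5))
        assert fit.residual <= fit.residual_initial

    def test_solution_respects_limits_and_cap(self, desk_protocol, desk_spectra,
                                              limits, wm_component, fluid_component):
        dist = VoxelDistribution.from_components(
            [wm_component.with_weight(0.6), fluid_component.with_weight(0.4)])
        y = signal_matrix(dist, desk_protocol, desk_spectra) @ dist.w
        config = InversionConfig(n_candidates=150, n_refine=8, n_children=3,
                                 n_fresh=20, max_components=6)
        fit = invert_voxel(y, desk_protocol, desk_spectra, limits, config,
                           np.random.default_rng(6))
        assert limits.contains(fit.distribution)
        assert 0 < len(fit.distribution) <= 6
        assert np.all(fit.distribution.w >= 0)

    def test_pure_noise_voxel_has_small_weight(self, desk_protocol, desk_spectra):
        rng = np.random.default_rng(3)
        sigma = 0.02
        noise = np.hypot(rng.normal(0, sigma, len(desk_protocol)),
                         rng.normal(0, sigma, len(desk_protocol)))
        fit = invert_voxel(noise, desk_protocol, desk_spectra, config=LIGHT,
                           rng=np.random.default_rng(9))
        assert fit.distribution.total_weight < 0.1

    def test_nonfinite_signals_rejected(self, desk_protocol, desk_spectra):
        y = np.zeros(len(desk_protocol))
        y[0] = np.nan
        with pytest.raises(ValueError):
            invert_voxel(y, desk_protocol, desk_spectra)

    def test_deterministic_under_seed(self, desk_protocol, desk_spectra,
                                      dispersive_component):
        dist = VoxelDistribution.from_components([dispersive_component])
        y = signal_matrix(dist, desk_protocol, desk_spectra) @ dist.w
        fits = [
            invert_voxel(y, desk_protocol, desk_spectra, config=LIGHT,
                         rng=np.random.default_rng(21))
            for _ in range(2)
        ]
        np.testing.assert_array_equal(fits[0].distribution.w, fits[1].distribution.w)
        np.testing.assert_array_equal(fits[0].distribution.d0, fits[1].distribution.d0)
        assert fits[0].residual == fits[1].residual


class TestBootstrap:
    def test_single_replicate_rejected(self, desk_protocol, desk_spectra):
        with pytest.raises(ValueError):
            bootstrap_ensemble(
                np.zeros(len(desk_protocol)), desk_protocol, desk_spectra,
                config=InversionConfig(n_bootstrap=1))

    def test_bitwise_reproducible(self, desk_protocol, desk_spectra, iso_component):
        dist = VoxelDistribution.from_components([iso_component])
        y = signal_matrix(dist, desk_protocol, desk_spectra) @ dist.w
        config = InversionConfig(n_candidates=80, n_refine=4, n_children=2,
                                 n_fresh=10, n_bootstrap=3)
        runs = [
            bootstrap_ensemble(y, desk_protocol, desk_spectra, config=config,
                               rng=np.random.default_rng(13))
            for _ in range(2)
        ]
        for a, b in zip(runs[0].solutions, runs[1].solutions):
            np.testing.assert_array_equal(a.w, b.w)
            np.testing.assert_array_equal(a.r2, b.r2)

    def test_noise_widens_bootstrap_dispersion(self, desk_protocol, desk_spectra,
                                               iso_component, omega_band):
        """Across-bootstrap spread of E[Diso] grows with measurement noise."""
        from mdrc.synthetic import add_rician_noise

        dist = VoxelDistribution.from_components([iso_component])
        y = signal_matrix(dist, desk_protocol, desk_spectra) @ dist.w
        y_noisy = add_rician_noise(y, y.max() / 20.0, np.random.default_rng(2))
        config = InversionConfig(n_candidates=120, n_refine=8, n_children=3,
                                 n_fresh=20, n_bootstrap=8)

        def spread(signals, seed):
            ens = bootstrap_ensemble(signals, desk_protocol, desk_spectra,
                                     config=config, rng=np.random.default_rng(seed))
            vals = [weighted_moments(s, "diso", omega_band[0]).e_x
                    for s in ens.solutions if len(s)]
            return np.std(vals)

        assert spread(y, 31) < 0.3 * spread(y_noisy, 31)


class TestMonteCarloInverter:
    def test_sklearn_params_round_trip(self, desk_protocol):
        from sklearn.base import clone

        est = MonteCarloInverter(protocol=desk_protocol, n_candidates=50,
                                 random_state=3)
        cloned = clone(est)
        assert cloned.get_params()["n_candidates"] == 50
        cloned.set_params(n_refine=5)
        assert cloned.n_refine == 5

    def test_fit_and_predict(self, desk_protocol, desk_spectra, iso_component,
                             dispersive_component):
        X = np.stack([
            signal_matrix(VoxelDistribution.from_components([c]),
                          desk_protocol, desk_spectra).sum(axis=1)
            for c in (iso_component, dispersive_component)
        ])
        est = MonteCarloInverter(protocol=desk_protocol, n_candidates=120,
                                 n_refine=8, random_state=0)
        est.fit(X)
        assert len(est.distributions_) == 2
        assert est.residuals_.shape == (2,)
        recon = est.predict()
        assert recon.shape == X.shape
        # reconstruction should be close to the noiseless input
        assert np.abs(recon - X).max() < 0.05

    def test_shape_mismatch_rejected(self, desk_protocol):
        est = MonteCarloInverter(protocol=desk_protocol)
        with pytest.raises(ValueError):
            est.fit(np.zeros((2, 3)))

    def test_voxel_substreams_order_independent(self):
        a = voxel_rng(5, 3).integers(0, 1000, 4)
        b = voxel_rng(5, 3).integers(0, 1000, 4)
        c = voxel_rng(5, 4).integers(0, 1000, 4)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)
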
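"""Frequency-dependent diffusion-relaxation forward model."""

import numpy as np
import pytest

from mdrc.encoding import AcquisitionPoint, EncodingSpectrum, delta_spectrum
from mdrc.forward import (
    DiffusionComponent,
    InconsistentEncodingError,
    VoxelDistribution,
    axial_diffusivity,
    iso_and_anisotropy,
    lab_frame_tensor,
    radial_diffusivity,
    signal,
    signal_matrix,
)


class TestLorentzianDispersion:
    def test_zero_frequency_limits(self, dispersive_component):
        c = dispersive_component
        assert axial_diffusivity(c, 0.0) == pytest.approx(c.d_par, rel=1e-15)
        assert radial_diffusivity(c, 0.0) == pytest.approx(c.d_perp, rel=1e-15)

    def test_high_frequency_limit_is_d0(self, dispersive_component):
        c = dispersive_component
        assert axial_diffusivity(c, 1e9) == pytest.approx(c.d0, rel=1e-6)
        assert radial_diffusivity(c, 1e9) == pytest.approx(c.d0, rel=1e-6)

    def test_half_transition_at_gamma(self):
        c = DiffusionComponent(d0=2e-9, d_par=1e-9, d_perp=1e-9,
                               gamma_par=100.0, gamma_perp=250.0)
        assert axial_diffusivity(c, 100.0) == pytest.approx(1.5e-9)
        assert radial_diffusivity(c, 250.0) == pytest.approx(1.5e-9)

    def test_even_and_monotone_in_frequency(self, dispersive_component):
        c = dispersive_component
        om = np.linspace(0, 1e4, 100)
        d = axial_diffusivity(c, om)
        np.testing.assert_array_equal(d, axial_diffusivity(c, -om))
        assert np.all(np.diff(d) >= 0)
        assert np.all((d >= c.d_par) & (d <= c.d0))

    def test_no_dispersion_when_dperp_equals_d0(self):
        c = DiffusionComponent(d0=1e-9, d_par=1e-9, d_perp=1e-9,
                               gamma_par=50.0, gamma_perp=50.0)
        om = np.array([0.0, 10.0, 1e3, 1e6])
        np.testing.assert_allclose(radial_diffusivity(c, om), 1e-9)

    def test_component_validation(self):
        with pytest.raises(ValueError):
            DiffusionComponent(d0=1e-9, d_par=2e-9, d_perp=1e-10,
                               gamma_par=1.0, gamma_perp=1.0)
        with pytest.raises(ValueError):
            DiffusionComponent(d0=1e-9, d_par=1e-10, d_perp=1e-10,
                               gamma_par=-1.0, gamma_perp=1.0)
        with pytest.raises(ValueError):
            DiffusionComponent(d0=1e-9, d_par=1e-10, d_perp=1e-10,
                               gamma_par=1.0, gamma_perp=1.0, w=-0.5)


class TestLabFrameTensor:
    def test_aligned_component_is_diagonal(self, dispersive_component):
        from dataclasses import replace

        c = replace(dispersive_component, theta=0.0, phi=0.0)
        om = 500.0
        D = lab_frame_tensor(c, om)
        np.testing.assert_allclose(
            D, np.diag([radial_diffusivity(c, om)] * 2 + [axial_diffusivity(c, om)]),
            atol=1e-25,
        )

    @pytest.mark.parametrize("theta,phi", [(0.3, 1.0), (1.2, 4.0), (2.8, 0.1)])
    def test_trace_is_rotation_invariant(self, dispersive_component, theta, phi):
        from dataclasses import replace

        c = replace(dispersive_component, theta=theta, phi=phi)
        om = 700.0
        expected = axial_diffusivity(c, om) + 2 * radial_diffusivity(c, om)
        assert np.trace(lab_frame_tensor(c, om)) == pytest.approx(expected, rel=1e-12)

    def test_principal_axis_via_eigendecomposition(self, dispersive_component):
        from dataclasses import replace

        c = replace(dispersive_component, theta=np.pi / 2, phi=0.0)
        D = lab_frame_tensor(c, 0.0)
        lam, v = np.linalg.eigh(D)
        assert lam[-1] == pytest.approx(c.d_par)
        assert lam[0] == pytest.approx(c.d_perp)
        assert abs(v[:, -1] @ np.array([1.0, 0.0, 0.0])) == pytest.approx(1.0)


class TestIsoAnisotropy:
    def test_isotropic_case(self, iso_component):
        d_iso, d_delta = iso_and_anisotropy(iso_component, 0.0)
        assert d_iso == pytest.approx(1e-9)
        assert d_delta == pytest.approx(0.0, abs=1e-15)

    def test_stick_limit(self):
        c = DiffusionComponent(d0=2e-9, d_par=2e-9, d_perp=1e-30,
                               gamma_par=1.0, gamma_perp=1.0)
        _, d_delta = iso_and_anisotropy(c, 0.0)
        assert d_delta == pytest.approx(1.0)

    def test_arithmetic_example(self):
        c = DiffusionComponent(d0=2e-9, d_par=2e-9, d_perp=0.5e-9,
                               gamma_par=1.0, gamma_perp=1.0)
        d_iso, d_delta = iso_and_anisotropy(c, 0.0)
        assert d_iso == pytest.approx(1e-9)
        assert d_delta == pytest.approx(0.5)
        assert -0.5 <= d_delta <= 1.0


class TestSignal:
    def test_no_attenuation_limit(self, iso_component):
        pt = AcquisitionPoint(b=0.0, omega_cent=0.0, tau_R=1e9, tau_E=1e-12)
        s = signal([iso_component.with_weight(0.8)], pt, delta_spectrum(pt))
        assert s == pytest.approx(0.8, rel=1e-9)

    def test_closed_form_single_component(self, iso_component):
        """w·e^{-bD}·e^{-τE R2}·(1-e^{-τR R1}) for a flat isotropic component."""
        pt = AcquisitionPoint(b=1e9, b_delta=0.0, omega_cent=50.0,
                              tau_R=3.5, tau_E=0.01)
        s = signal([iso_component], pt, delta_spectrum(pt))
        expected = np.exp(-1.0) * np.exp(-0.2) * (1 - np.exp(-3.5))
        assert s == pytest.approx(expected, rel=1e-12)
        assert s == pytest.approx(0.2921, abs=5e-5)

    def test_mismatched_spectrum_rejected(self, iso_component):
        pt = AcquisitionPoint(b=1e9, omega_cent=50.0)
        wrong = delta_spectrum(AcquisitionPoint(b=2e9, omega_cent=50.0))
        with pytest.raises(InconsistentEncodingError):
            signal([iso_component], pt, wrong)

    def test_monotonicity_contracts(self, dispersive_component):
        """S decreases in b and τE, increases in τR."""
        def s(b=2e9, tau_E=0.02, tau_R=2.0):
            pt = AcquisitionPoint(b=b, b_delta=1.0, omega_cent=100.0,
                                  tau_R=tau_R, tau_E=tau_E)
            return signal([dispersive_component], pt, delta_spectrum(pt))

        assert s(b=1e9) > s(b=2e9) > s(b=4e9)
        assert s(tau_E=0.01) > s(tau_E=0.03)
        assert s(tau_R=3.5) > s(tau_R=1.0)

    def test_weaker_attenuation_at_high_frequency(self, dispersive_component):
        """Dispersive components attenuate less at high ωcent (restriction)."""
        def s(f):
            pt = AcquisitionPoint(b=4e9, b_delta=0.0, omega_cent=f)
            return signal([dispersive_component], pt, delta_spectrum(pt))

        assert s(36.6) > 0  # sanity
        assert s(247.0) < s(36.6)  # higher apparent D at high frequency

    def test_superposition(self, dispersive_component, iso_component):
        pt = AcquisitionPoint(b=3e9, b_delta=0.5, theta=0.4, phi=2.0,
                              omega_cent=130.0, tau_R=1.5, tau_E=0.02)
        sp = delta_spectrum(pt)
        s_both = signal(
            [dispersive_component.with_weight(0.6), iso_component.with_weight(0.4)],
            pt, sp)
        s_a = signal([dispersive_component.with_weight(0.6)], pt, sp)
        s_b = signal([iso_component.with_weight(0.4)], pt, sp)
        assert s_both == pytest.approx(s_a + s_b, rel=1e-12)

    def test_flat_component_reduces_to_btensor_contraction(self, rng):
        """For ω-independent D the spectral integral is the plain b:D product."""
        from conftest import random_components

        for _ in range(10):
            comp = random_components(1, rng)
            # flatten the dispersion: transition far above the probed band
            flat = VoxelDistribution(
                d0=comp.d0, d_par=comp.d_par, d_perp=comp.d_perp,
                gamma_par=np.array([1e12]), gamma_perp=np.array([1e12]),
                theta=comp.theta, phi=comp.phi, r1=comp.r1, r2=comp.r2,
                w=np.array([1.0]),
            )
            pt = AcquisitionPoint(
                b=float(rng.uniform(1e8, 8e9)), b_delta=float(rng.uniform(-0.5, 1)),
                theta=float(rng.uniform(0, np.pi)), phi=float(rng.uniform(0, 2 * np.pi)),
                omega_cent=float(rng.uniform(30, 250)), tau_R=2.0, tau_E=0.02,
            )
            sp = delta_spectrum(pt)
            got = signal(flat, pt, sp)
            D = flat.lab_tensors(0.0)[0]
            expected = (
                np.exp(-np.sum(sp.btensor * D))
                * (1 - np.exp(-2.0 * flat.r1[0])) * np.exp(-0.02 * flat.r2[0])
            )
            assert got == pytest.approx(expected, rel=1e-9)

    def test_delta_vs_dense_quadrature(self, dispersive_component):
        """A delta spectrum equals brute-force quadrature of a narrow band."""
        pt = AcquisitionPoint(b=3e9, b_delta=1.0, theta=0.9, phi=0.3,
                              omega_cent=150.0, tau_R=2.0, tau_E=0.015)
        sp_delta = delta_spectrum(pt)
        # narrow top-hat of total weight b around ±ωcent on a dense grid
        w0 = 2 * np.pi * 150.0
        half = 1e-3  # rad/s half-width: D(ω) constant over it to ~1e-12
        grid = w0 + np.linspace(-half, half, 2001)
        density = np.repeat(sp_delta.density, len(grid), axis=0) / (2 * half)
        h = 2 * half / (len(grid) - 1)  # analytic step avoids cancellation
        widths = np.full(len(grid), h)
        widths[0] = widths[-1] = h / 2  # trapezoid end weights
        sp_dense = EncodingSpectrum(omega=grid, density=density, weights=widths)
        s1 = signal([dispersive_component], pt, sp_delta)
        s2 = signal([dispersive_component], pt, sp_dense)
        assert s2 == pytest.approx(s1, rel=1e-9)


class TestVoxelDistribution:
    def test_component_round_trip(self, dispersive_component, iso_component):
        dist = VoxelDistribution.from_components(
            [dispersive_component, iso_component])
        back = dist.components
        assert back[0] == dispersive_component
        assert back[1] == iso_component
        assert len(dist) == 2
        assert dist.total_weight == pytest.approx(2.0)

    def test_signal_matrix_matches_scalar_signal(self, desk_protocol, desk_spectra,
                                                 dispersive_component):
        dist = VoxelDistribution.from_components([dispersive_component])
        kernel = signal_matrix(dist, desk_protocol, desk_spectra)
        for i in (0, 10, 50):
            s = signal(dist, desk_protocol[i], desk_spectra[i])
            assert kernel[i] @ dist.w == pytest.approx(s, rel=1e-12)

    def test_invalid_arrays_rejected(self):
        with pytest.raises(ValueError):
            VoxelDistribution(
                d0=np.array([1e-9]), d_par=np.array([2e-9]), d_perp=np.array([1e-10]),
                gamma_par=np.array([1.0]), gamma_perp=np.array([1.0]),
                theta=np.array([0.0]), phi=np.array([0.0]),
                r1=np.array([1.0]), r2=np.array([20.0]), w=np.array([1.0]),
            )
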
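"""Beam synthesis and the three reflectometry quantities."""

import numpy as np
import pytest

from fluolut import OpticalMedium, farrell_reflectance
from fluolut.diffusion import farrell_profile
from fluolut.mc.transport import RadialProfile
from fluolut.reflectometry import (
    LARGE_DISK,
    SMALL_DISK,
    BeamSpec,
    CoverageError,
    compute_RT,
    compute_srr,
    convolve_beam,
    fit_slope_logsrr,
    measure_triplet,
    roi_mean_map,
)


@pytest.fixture(scope="module")
def farrell_imp():
    """Noise-free diffusion-model impulse profile (mu_a=0.1, mu_s'=10)."""
    m = OpticalMedium(mu_a=0.1, mu_s_prime=10.0, n=1.37)
    r, v = farrell_profile(m, r_max=10.0, n_bins=400)
    return RadialProfile(r, v)


class TestConvolveBeam:
    def test_delta_beam_is_identity(self, farrell_imp):
        """A beam one bin wide reproduces the impulse response."""
        beam = BeamSpec(diameter=0.025)
        out = convolve_beam(farrell_imp, beam, analysis_radius=5.0)
        prof = out.radial_profile()
        expected = np.interp(
            prof.r_centers, farrell_imp.r_centers, farrell_imp.values
        )
        interior = prof.r_centers < 4.0
        np.testing.assert_allclose(
            prof.values[interior], expected[interior], rtol=1e-6
        )

    def test_constant_input_preserved(self):
        """Convolution with a unit-energy kernel preserves constants."""
        r = np.linspace(0.025, 12.0, 480)
        flat = RadialProfile(r, np.full_like(r, 3.7))
        out = convolve_beam(flat, LARGE_DISK, analysis_radius=4.0)
        prof = out.radial_profile()
        inner = prof.r_centers < 3.0
        np.testing.assert_allclose(prof.values[inner], 3.7, rtol=1e-6)

    def test_center_matches_direct_quadrature(self, farrell_imp):
        """Flat-top 4.16 mm disk center value vs brute-force 2D
        integration of the Farrell model on a 10 um grid."""
        out = convolve_beam(farrell_imp, LARGE_DISK, analysis_radius=3.0)
        c = out.center_index
        center_val = out.pixels[c, c]

        m = OpticalMedium(mu_a=0.1, mu_s_prime=10.0, n=1.37)
        a = 0.5 * LARGE_DISK.diameter
        h = 0.01
        ax = np.arange(-a, a + h, h)
        xx, yy = np.meshgrid(ax, ax)
        rr = np.hypot(xx, yy)
        inside = rr <= a
        r_safe = np.clip(rr[inside], 1e-6, None)
        vals = farrell_reflectance(m, r_safe)
        # beam irradiance 1/(pi a^2); integral over the disk
        oracle = vals.sum() * h * h / (np.pi * a**2)
        assert center_val == pytest.approx(oracle, rel=5e-3)

    def test_insufficient_coverage_raises(self, farrell_imp):
        with pytest.raises(CoverageError):
            convolve_beam(farrell_imp, LARGE_DISK, analysis_radius=9.0)


class TestComputeRT:
    def test_self_normalization(self, farrell_imp):
        out = convolve_beam(farrell_imp, LARGE_DISK, analysis_radius=2.0)
        v = roi_mean_map(out, 1.40)
        assert compute_RT(out, 1.40, reference_scale=v) == pytest.approx(1.0)

    def test_zero_map(self, farrell_imp):
        out = convolve_beam(farrell_imp, LARGE_DISK, analysis_radius=2.0)
        out.pixels[:] = 0.0
        assert compute_RT(out, 1.40, reference_scale=0.5) == 0.0

    def test_roi_mean_matches_quadrature(self, farrell_imp):
        """ROI mean equals the explicit pixel-enumeration average."""
        out = convolve_beam(farrell_imp, LARGE_DISK, analysis_radius=2.0)
        c = out.center_index
        n = out.pixels.shape[0]
        acc = []
        for iy in range(n):
            for ix in range(n):
                r = out.pitch * np.hypot(ix - c, iy - c)
                if r <= 0.70:
                    acc.append(out.pixels[iy, ix])
        assert roi_mean_map(out, 1.40) == pytest.approx(
            np.mean(acc), rel=1e-12
        )

    def test_oversized_roi_rejected(self, farrell_imp):
        out = convolve_beam(farrell_imp, LARGE_DISK, analysis_radius=2.0)
        with pytest.raises(CoverageError):
            roi_mean_map(out, 10.0)


class TestComputeSrr:
    def test_scale_invariance(self, farrell_imp):
        out = convolve_beam(farrell_imp, SMALL_DISK, analysis_radius=5.2)
        srr1 = compute_srr(out, 5.0)
        out.pixels *= 123.4
        srr2 = compute_srr(out, 5.0)
        np.testing.assert_allclose(srr1.values, srr2.values, rtol=1e-12)

    def test_normalization_closes(self, farrell_imp):
        """Sum(values * annulus area) * disk area over r <= 5 mm is 1."""
        out = convolve_beam(farrell_imp, SMALL_DISK, analysis_radius=5.2)
        srr = compute_srr(out, 5.0)
        edges = np.concatenate(
            [[0.0], 0.5 * (srr.r_centers[:-1] + srr.r_centers[1:]),
             [srr.r_centers[-1] + 0.5 * out.pitch]]
        )
        areas = np.pi * np.diff(edges**2)
        inside = srr.r_centers <= 5.0
        total = (srr.values[inside] * areas[inside]).sum()
        assert total * np.pi * 5.0**2 == pytest.approx(1.0, abs=1e-10)

    def test_radially_symmetric_input_reproduced(self, farrell_imp):
        """Up to normalization, the SRR of a symmetric map is the map's
        own radial function."""
        out = convolve_beam(farrell_imp, SMALL_DISK, analysis_radius=5.2)
        srr = compute_srr(out, 5.0)
        raw = out.radial_profile()
        ratio = srr.values / raw.values
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)


class TestSlopeFit:
    def test_pure_exponential_recovered_exactly(self):
        r = np.linspace(0.5, 3.0, 101)
        s = 0.8
        prof = RadialProfile(r, 2.5 * 10 ** (-s * r))
        fit = fit_slope_logsrr(prof)
        assert fit.slope == pytest.approx(-s, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_scaling_changes_intercept_not_slope(self):
        r = np.linspace(0.5, 3.0, 101)
        prof = RadialProfile(r, 2.5 * 10 ** (-0.8 * r))
        scaled = RadialProfile(r, 7.0 * prof.values)
        f1, f2 = fit_slope_logsrr(prof), fit_slope_logsrr(scaled)
        assert f2.slope == pytest.approx(f1.slope, abs=1e-12)
        assert f2.intercept != pytest.approx(f1.intercept, abs=1e-6)

    def test_window_membership_is_closed_interval(self):
        r = np.array([1.0, 1.1, 1.6, 2.1, 2.2])
        prof = RadialProfile(r, np.ones_like(r))
        fit = fit_slope_logsrr(prof)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        # exactly the three bins at 1.1, 1.6, 2.1 are used
        with pytest.raises(ValueError):
            fit_slope_logsrr(RadialProfile(r[:2], np.ones(2)))

    def test_nonpositive_value_names_radius(self):
        r = np.linspace(1.0, 2.5, 16)
        v = np.ones_like(r)
        v[5] = 0.0
        with pytest.raises(ValueError, match=f"{r[5]:.4g}"):
            fit_slope_logsrr(RadialProfile(r, v))

    def test_farrell_slope_tracks_mu_eff(self):
        """In the 1.1-2.1 mm window the log-decay rate of the dipole
        model is mu_eff plus the geometric ~2/r term of its 1/r^2
        prefactor (the window is pre-asymptotic), and it increases
        monotonically with mu_eff at fixed mu_s'."""
        m = OpticalMedium(mu_a=0.05, mu_s_prime=5.0, n=1.37)
        r, v = farrell_profile(m, r_max=10.0, n_bins=400)
        fit = fit_slope_logsrr(RadialProfile(r, v))
        r_mid = 1.6
        assert abs(fit.slope) * np.log(10) == pytest.approx(
            m.mu_eff + 2.0 / r_mid, rel=0.25
        )
        decays = []
        for mu_a in (0.01, 0.03, 0.1, 0.3):
            mm = OpticalMedium(mu_a=mu_a, mu_s_prime=5.0, n=1.37)
            rr, vv = farrell_profile(mm, r_max=10.0, n_bins=400)
            decays.append(abs(fit_slope_logsrr(RadialProfile(rr, vv)).slope))
        assert all(a < b for a, b in zip(decays, decays[1:]))


class TestMeasureTriplet:
    def test_chain_runs_on_model_profiles(self, farrell_imp):
        """The full chain produces a sane triplet from model inputs."""
        fluo = RadialProfile(
            farrell_imp.r_centers, 1e-3 * farrell_imp.values
        )
        trip, fit = measure_triplet(
            RadialProfile(farrell_imp.r_centers, farrell_imp.values), fluo
        )
        assert 0.0 < trip.R_T <= 1.0
        assert trip.slope_log_srr < 0.0
        assert trip.F == pytest.approx(1e-3 * trip.R_T, rel=1e-9)
        assert fit.r_squared > 0.99
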
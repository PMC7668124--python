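"""Spectral estimators: oracles, exact identities, planted-truth recovery."""

import math

import numpy as np
import pytest

from qusdr.synthetic import AcquisitionGeometry, ReferencePhantom, RFFrame
from qusdr.spectral import (
    PowerSpectrum,
    WindowSpec,
    burg_coefficients,
    compensate_attenuation,
    compute_power_spectrum,
    estimate_bsc,
    estimate_sas,
    fit_gaussian_form_factor,
    fit_linear_spectral_params,
    grid_count,
    mean_map_value,
    normalize_spectrum,
)


def _spectrum(freqs, power, in_db=False):
    return PowerSpectrum(frequencies=np.asarray(freqs, float),
                         power=np.asarray(power, float), in_db=in_db)


class TestComputePowerSpectrum:
    def test_sinusoid_peak_at_8mhz(self, small_geometry):
        t = np.arange(small_geometry.n_samples) / small_geometry.sampling_rate
        samples = np.tile(np.sin(2 * np.pi * 8e6 * t)[:, None],
                          (1, small_geometry.n_lines))
        frame = RFFrame(samples=samples, geometry=small_geometry)
        spec = compute_power_spectrum(frame, (0.1, 1.4, 0.0, 0.72))
        assert spec.frequencies[np.argmax(spec.power)] == pytest.approx(
            8.0, abs=0.1)

    def test_all_zero_window(self, small_geometry):
        frame = RFFrame(samples=np.zeros((small_geometry.n_samples,
                                          small_geometry.n_lines)),
                        geometry=small_geometry)
        spec = compute_power_spectrum(frame, (0.1, 1.0, 0.0, 0.72))
        assert np.all(spec.power == 0)

    def test_line_averaging_reduces_variance(self, small_geometry):
        """Periodogram variance scales as 1/L for white noise."""
        rng = np.random.default_rng(0)
        n_rep = 150
        var_by_l = {}
        for n_lines in (4, 16):
            vals = []
            for _ in range(n_rep):
                x = rng.standard_normal((400, n_lines))
                geom = AcquisitionGeometry(n_lines=n_lines,
                                           lateral_width=n_lines * 0.015,
                                           depth=400 * 1540 / 2 / 40e6 * 100)
                frame = RFFrame(samples=x, geometry=geom)
                spec = compute_power_spectrum(
                    frame, (0, geom.depth, 0, geom.lateral_width))
                vals.append(spec.power[40])  # one in-band bin
            var_by_l[n_lines] = np.var(vals)
        ratio = var_by_l[4] / var_by_l[16]
        assert ratio == pytest.approx(4.0, rel=0.45)

    def test_too_small_window_rejected(self, small_geometry):
        frame = RFFrame(samples=np.zeros((small_geometry.n_samples,
                                          small_geometry.n_lines)),
                        geometry=small_geometry)
        with pytest.raises(ValueError, match="window too small"):
            compute_power_spectrum(frame, (0.1, 0.102, 0.0, 0.72))


class TestNormalizeSpectrum:
    freqs = np.linspace(2.0, 14.0, 49)

    def test_identical_gives_zero_db(self):
        s = _spectrum(self.freqs, np.ones(49))
        out = normalize_spectrum(s, s)
        assert np.allclose(out.power, 0.0)
        assert out.in_db

    def test_tenfold_gives_ten_db(self):
        r = _spectrum(self.freqs, np.ones(49))
        s = _spectrum(self.freqs, 10.0 * np.ones(49))
        assert np.allclose(normalize_spectrum(s, r).power, 10.0)

    def test_planted_tilt_recovered(self):
        r = _spectrum(self.freqs, np.full(49, 2.0))
        tilt = 0.7  # dB/MHz
        s = _spectrum(self.freqs, 2.0 * 10 ** (tilt * self.freqs / 10.0))
        nps = normalize_spectrum(s, r)
        slope = np.polyfit(nps.frequencies, nps.power, 1)[0]
        assert slope == pytest.approx(tilt, rel=1e-9)

    def test_grid_mismatch_rejected(self):
        r = _spectrum(self.freqs, np.ones(49))
        s = _spectrum(self.freqs + 0.1, np.ones(49))
        with pytest.raises(ValueError, match="grid mismatch"):
            normalize_spectrum(s, r)

    def test_zero_reference_rejected(self):
        power = np.ones(49)
        power[3] = 0.0
        r = _spectrum(self.freqs, power)
        s = _spectrum(self.freqs, np.ones(49))
        with pytest.raises(ValueError, match="reference"):
            normalize_spectrum(s, r)


class TestCompensation:
    freqs = np.linspace(4.0, 12.0, 65)

    def test_matched_attenuation_is_identity(self):
        nps = _spectrum(self.freqs, np.random.default_rng(0).normal(size=65),
                        in_db=True)
        out = compensate_attenuation(nps, 0.576, 0.576, depth=3.0)
        assert np.allclose(out.power, nps.power)

    def test_zero_depth_is_identity(self):
        nps = _spectrum(self.freqs, np.ones(65), in_db=True)
        out = compensate_attenuation(nps, 1.3, 0.576, depth=0.0)
        assert np.allclose(out.power, nps.power)

    def test_roundtrip_removes_depth_trend(self):
        """Compensating with the correct ACE flattens the planted trend."""
        ace, ref, z = 1.1, 0.576, 2.4
        planted = -2.0 * (ace - ref) * self.freqs * z
        nps = _spectrum(self.freqs, planted, in_db=True)
        out = compensate_attenuation(nps, ace, ref, depth=z)
        assert np.allclose(out.power, 0.0, atol=1e-12)


class TestLinearFit:
    def test_exact_line(self):
        f = np.linspace(4.0, 12.0, 33)
        nps = _spectrum(f, 2.0 + 0.5 * f, in_db=True)
        fit = fit_linear_spectral_params(nps, (4.0, 12.0))
        assert fit.si == pytest.approx(2.0)
        assert fit.ss == pytest.approx(0.5)
        assert fit.mbf == pytest.approx(2.0 + 0.5 * 8.0)

    def test_flat_zero(self):
        f = np.linspace(4.0, 12.0, 33)
        fit = fit_linear_spectral_params(_spectrum(f, np.zeros(33), in_db=True),
                                         (4.0, 12.0))
        assert fit.mbf == fit.ss == fit.si == 0.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        f = np.linspace(5.0, 11.0, 64)
        y = 1.5 - 0.8 * f + rng.normal(0, 0.5, 64)
        fit = fit_linear_spectral_params(_spectrum(f, y, in_db=True),
                                         (5.0, 11.0))
        # closed-form normal equations
        A = np.column_stack([np.ones(64), f])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert fit.si == pytest.approx(beta[0], rel=1e-12)
        assert fit.ss == pytest.approx(beta[1], rel=1e-12)

    def test_mbf_identity(self):
        """MBF = SI + SS * f_c is exact by construction for any input."""
        rng = np.random.default_rng(2)
        f = np.linspace(4.0, 12.0, 40)
        for _ in range(10):
            fit = fit_linear_spectral_params(
                _spectrum(f, rng.normal(size=40), in_db=True), (4.0, 12.0))
            assert fit.mbf == pytest.approx(fit.si + fit.ss * 8.0, abs=1e-12)

    def test_degenerate_band_rejected(self):
        f = np.linspace(4.0, 12.0, 33)
        with pytest.raises(ValueError, match="degenerate band"):
            fit_linear_spectral_params(_spectrum(f, f, in_db=True),
                                       (4.0, 4.1))


class TestBSC:
    freqs = np.linspace(4.0, 12.0, 33)

    def test_zero_nps_flat_reference(self):
        phantom = ReferencePhantom(backscatter_law=("flat", 3.5))
        nps = _spectrum(self.freqs, np.zeros(33), in_db=True)
        bsc = estimate_bsc(nps, phantom)
        assert np.allclose(bsc.power, 3.5)

    def test_three_db_doubles(self):
        phantom = ReferencePhantom(backscatter_law=("flat", 1.0))
        nps = _spectrum(self.freqs, np.full(33, 3.0), in_db=True)
        bsc = estimate_bsc(nps, phantom)
        assert np.allclose(bsc.power, 10 ** 0.3)

    def test_unknown_law_rejected(self):
        with pytest.raises(ValueError, match="unknown backscatter law"):
            ReferencePhantom(backscatter_law=("cubic", 1.0))


class TestGaussianFormFactor:
    def _bsc_exact(self, a_um, scale=1.0):
        f = np.linspace(4.0, 12.0, 65)
        k = 2 * np.pi * f * 1e6 / 1540.0
        a = a_um * 1e-6
        return _spectrum(f, scale * f**4 * np.exp(-0.827 * k**2 * a**2))

    def test_analytic_inversion_machine_precision(self):
        bsc = self._bsc_exact(12.5)
        asd, aac = fit_gaussian_form_factor(bsc, (4.0, 12.0))
        assert asd == pytest.approx(25.0, rel=1e-9)

    def test_scale_shifts_aac_only(self):
        asd1, aac1 = fit_gaussian_form_factor(self._bsc_exact(12.5),
                                              (4.0, 12.0))
        asd2, aac2 = fit_gaussian_form_factor(self._bsc_exact(12.5, 10.0),
                                              (4.0, 12.0))
        assert asd2 == pytest.approx(asd1, rel=1e-9)
        assert aac2 - aac1 == pytest.approx(10.0, abs=1e-9)

    def test_nonphysical_slope_flagged_zero(self):
        f = np.linspace(4.0, 12.0, 65)
        bsc = _spectrum(f, f**4 * np.exp(+1e-10 * (2 * np.pi * f * 1e6
                                                   / 1540.0) ** 2))
        with pytest.warns(RuntimeWarning, match="nonphysical"):
            asd, _ = fit_gaussian_form_factor(bsc, (4.0, 12.0))
        assert asd == 0.0


class TestBurgSAS:
    def test_burg_matches_statsmodels(self):
        from statsmodels.regression.linear_model import burg as sm_burg
        rng = np.random.default_rng(3)
        x = rng.standard_normal(200)
        x = np.convolve(x, [1, 0.7, 0.2], mode="same")
        order = 6
        a = burg_coefficients(x - x.mean(), order)[0]
        rho, _ = sm_burg(x - x.mean(), order=order, demean=False)
        assert np.allclose(a[1:], -rho, atol=1e-8)

    def test_cosine_ripple_inverts_formula(self):
        """Ripple of period 2.567 MHz at c = 1540 m/s -> SAS = 0.30 mm."""
        f = np.arange(4.0, 12.0, 0.078125)
        spec = _spectrum(f, 3.0 * np.cos(2 * np.pi * f / 2.567), in_db=True)
        sas = estimate_sas(spec, ar_order=14, speed_of_sound=1540.0)
        assert sas == pytest.approx(1540.0 / (2 * 2.567e6) * 1e3, rel=0.02)

    def test_unreliable_featureless_spectrum_warns(self):
        """A spectrum with no ripple at all has no dominant AR peak."""
        f = np.arange(4.0, 12.0, 0.078125)
        spec = _spectrum(f, np.full(len(f), 2.0), in_db=True)
        with pytest.warns(RuntimeWarning, match="unreliable"):
            estimate_sas(spec, ar_order=14)

    def test_order_bounds(self):
        f = np.arange(4.0, 12.0, 0.078125)
        spec = _spectrum(f, np.cos(f), in_db=True)
        with pytest.raises(ValueError):
            estimate_sas(spec, ar_order=1)
        with pytest.raises(ValueError, match="4 x ar_order"):
            estimate_sas(spec, ar_order=40)


class TestGridAndMeans:
    def test_closed_form_window_count(self):
        # 10 mm span, 2 mm window, 94% overlap -> step 0.12 mm -> 67
        assert grid_count(10.0, 2.0, 0.94) == 67

    def test_zero_overlap_tiles_exactly(self):
        # windows tile without gap or overlap: span/w windows
        assert grid_count(10.0, 2.0, 0.0) == 5

    def test_mean_map_value(self):
        m = np.array([[1.0, 3.0], [np.nan, 5.0]])
        roi = np.array([[True, True], [True, False]])
        assert mean_map_value(m, roi) == pytest.approx(2.0)

    def test_mean_map_random_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        m = rng.normal(size=(30, 20))
        roi = rng.random((30, 20)) > 0.4
        expected = m[roi].sum() / roi.sum()
        assert mean_map_value(m, roi) == pytest.approx(expected, rel=1e-12)

    def test_all_invalid_rejected(self):
        m = np.full((4, 4), np.nan)
        with pytest.raises(ValueError):
            mean_map_value(m, np.ones((4, 4), bool))
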
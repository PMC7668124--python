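"""Synthetic RF generator: determinism, geometry, planted physics."""

import numpy as np
import pytest
from scipy.signal import hilbert

from qusdr.synthetic import (
    AcquisitionGeometry,
    EffectSpec,
    ReferencePhantom,
    ScattererField,
    SurvivalSpec,
    TIMEPOINTS,
    generate_cohort,
    make_scatterer_field,
    simulate_reference_frame,
    simulate_rf_frame,
)
from qusdr.spectral import compute_power_spectrum

from conftest import single_scatterer_frame


class TestGeometry:
    def test_clinical_acquisition_defaults(self, geometry):
        # 5 cm depth at 40 MHz / 1540 m/s -> 2597 samples per line
        assert geometry.n_samples == round(2 * 0.05 / 1540 * 40e6)
        assert geometry.n_lines == 256

    def test_nyquist_guard(self):
        with pytest.raises(ValueError, match="Nyquist"):
            AcquisitionGeometry(sampling_rate=20e6)

    def test_invalid_lines(self):
        with pytest.raises(ValueError):
            AcquisitionGeometry(n_lines=1)


class TestScattererField:
    def test_zero_jitter_lattice_spacing(self, small_geometry):
        field = make_scatterer_field(
            "quasi_periodic", 500.0, geometry=small_geometry,
            mean_spacing=0.30, jitter=0.0, n_columns=1, seed=3)
        z = np.sort(field.positions[:, 0])
        diffs = np.diff(z) * 10.0  # cm -> mm
        assert np.allclose(diffs, 0.30, atol=1e-9)

    def test_poisson_count(self, small_geometry):
        # mean count over 200 seeds within 3 SE of density * area
        density = 300.0
        area = small_geometry.depth * small_geometry.lateral_width
        counts = [
            make_scatterer_field("random", density,
                                 geometry=small_geometry,
                                 seed=s).n_scatterers
            for s in range(200)
        ]
        lam = density * area
        se = np.sqrt(lam / 200)
        assert abs(np.mean(counts) - lam) < 3 * se

    def test_seed_determinism(self, small_geometry):
        a = make_scatterer_field("random", 1000, geometry=small_geometry,
                                 seed=5)
        b = make_scatterer_field("random", 1000, geometry=small_geometry,
                                 seed=5)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.amplitudes, b.amplitudes)

    def test_empty_mask_rejected(self, small_geometry):
        mask = np.zeros((16, 16), dtype=bool)
        with pytest.raises(ValueError, match="empty region"):
            make_scatterer_field("random", 100, geometry=small_geometry,
                                 mask=mask, seed=0)

    def test_mask_confines_positions(self, small_geometry):
        mask = np.zeros((100, 48), dtype=bool)
        mask[:50] = True  # upper half in depth
        field = make_scatterer_field("random", 5000,
                                     geometry=small_geometry, mask=mask,
                                     seed=1)
        assert field.positions[:, 0].max() < small_geometry.depth / 2 + 0.02


class TestSimulateRF:
    def test_single_scatterer_arrival(self, small_geometry):
        z = 0.8
        frame = single_scatterer_frame(small_geometry, z, 0.36)
        line = frame.samples[:, int(0.36 / small_geometry.line_pitch)]
        env = np.abs(hilbert(line))
        expected = round(2 * (z / 100) / 1540 * small_geometry.sampling_rate)
        assert abs(int(np.argmax(env)) - expected) <= 1

    def test_power_scales_with_concentration(self, small_geometry):
        rng = np.random.default_rng(0)
        pos = np.column_stack([rng.uniform(0.2, 1.3, 200),
                               rng.uniform(0.05, 0.67, 200)])
        amps = rng.standard_normal(200)
        frames = {}
        for conc in (1.0, 10.0):
            field = ScattererField(positions=pos, amplitudes=amps,
                                   mode="random",
                                   acoustic_concentration=conc)
            frames[conc] = simulate_rf_frame(field, small_geometry, 0.5,
                                             noise_floor=None, seed=0)
        ratio = np.mean(frames[10.0].samples**2) / np.mean(
            frames[1.0].samples**2)
        assert ratio == pytest.approx(10.0, rel=1e-6)

    def test_point_scatterers_flat_backscatter(self, small_geometry):
        """With zero diameter and the bare (non-Rayleigh) echo model, the
        backscatter spectrum inside the band is the pulse spectrum alone
        (form factor = 1): its residual in-band tilt is near zero, while a
        60 um scatterer population shows the expected downward tilt."""
        rng = np.random.default_rng(1)
        n = 3000
        pos = np.column_stack([rng.uniform(0.1, 1.4, n),
                               rng.uniform(0.0, 0.72, n)])
        amps = rng.standard_normal(n)

        def band_slope(diameter):
            field = ScattererField(positions=pos, amplitudes=amps,
                                   mode="random",
                                   effective_diameter=diameter)
            frame = simulate_rf_frame(field, small_geometry, 0.0,
                                      noise_floor=None, seed=1,
                                      rayleigh=False)
            spec = compute_power_spectrum(frame, (0.2, 1.3, 0.0, 0.72))
            sel = (spec.frequencies >= 6.0) & (spec.frequencies <= 10.0)
            pulse = small_geometry.pulse_spectrum(spec.frequencies[sel] * 1e6)
            shape_db = 10 * np.log10(spec.power[sel] / pulse**2)
            return np.polyfit(spec.frequencies[sel], shape_db, 1)[0]

        flat_slope = band_slope(0.0)
        sized_slope = band_slope(60.0)
        assert abs(flat_slope) < 0.5          # dB/MHz, ~flat
        assert sized_slope < flat_slope - 0.5  # clear form-factor decay

    def test_czt_matches_direct_on_grid(self, small_geometry):
        dz = small_geometry.axial_sample_spacing
        rng = np.random.default_rng(2)
        idx = rng.integers(50, small_geometry.n_samples - 50, 20)
        pos = np.column_stack([idx * dz, rng.uniform(0.0, 0.7, 20)])
        field = ScattererField(positions=pos,
                               amplitudes=rng.standard_normal(20),
                               mode="random", effective_diameter=25.0)
        a = simulate_rf_frame(field, small_geometry, 0.9, noise_floor=None,
                              method="czt")
        b = simulate_rf_frame(field, small_geometry, 0.9, noise_floor=None,
                              method="direct")
        assert np.allclose(a.samples, b.samples, atol=1e-8 *
                           np.abs(b.samples).max())

    def test_negative_attenuation_rejected(self, small_geometry):
        field = make_scatterer_field("random", 100,
                                     geometry=small_geometry, seed=0)
        with pytest.raises(ValueError):
            simulate_rf_frame(field, small_geometry, -0.1)

    def test_frame_determinism(self, small_geometry):
        field = make_scatterer_field("random", 2000,
                                     geometry=small_geometry, seed=4)
        a = simulate_rf_frame(field, small_geometry, 0.7, seed=4)
        b = simulate_rf_frame(field, small_geometry, 0.7, seed=4)
        assert np.array_equal(a.samples, b.samples)


class TestReferenceFrame:
    def test_attenuation_depth_law(self, geometry, reference_frame):
        """Mean log-spectral difference between two depths follows
        2 * alpha * f * (z2 - z1) dB for the phantom's 0.576 dB/MHz/cm."""
        s1 = compute_power_spectrum(reference_frame, (1.0, 1.4, 0.0, 3.8))
        s2 = compute_power_spectrum(reference_frame, (3.0, 3.4, 0.0, 3.8))
        sel = (s1.frequencies >= 6.0) & (s1.frequencies <= 10.0)
        diff_db = 10 * np.log10(s1.power[sel] / s2.power[sel])
        slope = np.polyfit(s1.frequencies[sel], diff_db, 1)[0]
        expected = 2 * 0.576 * 2.0  # dz = 2 cm
        assert slope == pytest.approx(expected, rel=0.10)

    def test_zero_attenuation_depth_independent(self, small_geometry):
        phantom = ReferencePhantom(attenuation=0.0)
        frame = simulate_reference_frame(phantom, small_geometry, seed=5,
                                         density=40000)
        s1 = compute_power_spectrum(frame, (0.2, 0.5, 0.0, 0.72))
        s2 = compute_power_spectrum(frame, (1.0, 1.3, 0.0, 0.72))
        sel = (s1.frequencies >= 6.5) & (s1.frequencies <= 9.5)
        diff_db = 10 * np.log10(s1.power[sel] / s2.power[sel])
        slope = np.polyfit(s1.frequencies[sel], diff_db, 1)[0]
        assert abs(slope) < 0.35  # dB/MHz, ~0 vs 0.92 for the 0.576 phantom

    def test_reference_determinism(self, small_geometry, phantom):
        a = simulate_reference_frame(phantom, small_geometry, seed=9)
        b = simulate_reference_frame(phantom, small_geometry, seed=9)
        assert np.array_equal(a.samples, b.samples)


class TestCohort:
    def test_label_split_matches_clinical_cohort(self):
        cohort = generate_cohort(n_patients=36, cr_fraction=14 / 36, seed=0,
                                 density=300.0, noise_floor=None)
        labels = cohort.labels
        assert labels.count("CR") == 14
        assert labels.count("PR") == 22

    def test_every_patient_has_four_timepoints(self):
        cohort = generate_cohort(n_patients=6, cr_fraction=0.5, seed=1,
                                 density=300.0)
        for p in cohort.patients:
            assert set(p.frames) == set(TIMEPOINTS)
            assert p.followup_months > 0
            assert p.event in (0, 1)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError, match="cross-validate"):
            generate_cohort(n_patients=3, seed=0)

    def test_cohort_determinism(self):
        a = generate_cohort(n_patients=4, cr_fraction=0.5, seed=11,
                            density=300.0)
        b = generate_cohort(n_patients=4, cr_fraction=0.5, seed=11,
                            density=300.0)
        for pa, pb in zip(a.patients, b.patients):
            assert pa.label == pb.label
            assert pa.followup_months == pb.followup_months
            for tp in TIMEPOINTS:
                assert np.array_equal(pa.frames[tp].samples,
                                      pb.frames[tp].samples)

    def test_planted_trajectories_follow_groups(self):
        spec = EffectSpec()
        cohort = generate_cohort(n_patients=8, cr_fraction=0.5, seed=2,
                                 effect_spec=spec, density=300.0)
        cr_conc = [p.truth["week4"].concentration
                   for p in cohort.patients if p.label == "CR"]
        pr_conc = [p.truth["week4"].concentration
                   for p in cohort.patients if p.label == "PR"]
        assert np.mean(cr_conc) > np.mean(pr_conc)

    def test_survival_spec_rates(self):
        spec = SurvivalSpec()
        rng = np.random.default_rng(0)
        draws = [spec.draw("CR", rng) for _ in range(4000)]
        # with uniform 12-57 mo censoring the event fraction is modest
        events = np.mean([e for _, e in draws])
        assert 0.05 < events < 0.35
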
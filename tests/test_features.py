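"""Feature extraction: PTT oracle, spectrum, morphology, assembly."""
from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq

from wristbp.features import (
    FEATURE_COLUMNS,
    InvalidBeatError,
    assemble_features,
    compute_ptt,
    morphological_features,
    ppg_spectrum_features,
)
from wristbp.sim import PULSE_DERIV_PEAK_FRAC, pulse_template, simulate_recording
from wristbp.types import Beat, NoiseConfig, SubjectProfile

from conftest import preprocess_chain

FS = 250.0


def _beat(seg, fs=FS):
    return Beat(index=0, r_peak_time=0.0, ecg_segment=np.zeros(len(seg)),
                ppg_segment=np.asarray(seg, dtype=float))


class TestPTT:
    def test_matches_simulator_truth_within_two_samples(self, clean_recording):
        _, _, _, beats = preprocess_chain(clean_recording)
        for b in beats:
            ptt = compute_ptt(b, clean_recording.fs)
            assert ptt == pytest.approx(
                clean_recording.truth.ptt[b.index], abs=2.0 / clean_recording.fs
            )

    def test_bias_below_one_sample_over_500_beats(self, default_profile):
        errs = []
        for seed in range(25):
            rec = simulate_recording(
                default_profile, noise=NoiseConfig.clean(), seed=100 + seed
            )
            _, _, _, beats = preprocess_chain(rec)
            for b in beats:
                errs.append(compute_ptt(b, rec.fs) - rec.truth.ptt[b.index])
        assert len(errs) >= 500
        assert abs(np.mean(errs)) * FS < 1.0

    def test_pure_ramp_flagged_invalid(self):
        seg = np.linspace(0.0, 1.0, 100)
        with pytest.raises(InvalidBeatError):
            compute_ptt(_beat(seg), FS)

    def test_subject_mean_ptt_decreases_with_sbp(self):
        means = []
        for i, sbp in enumerate([100.0, 115.0, 130.0, 145.0, 160.0]):
            prof = SubjectProfile(f"p{i}", 50, "M", 165, 70, sbp, 70.0, 65.0)
            rec = simulate_recording(prof, noise=NoiseConfig.clean(), seed=i)
            _, _, _, beats = preprocess_chain(rec)
            means.append(np.mean([compute_ptt(b, rec.fs) for b in beats]))
        assert all(a > b for a, b in zip(means, means[1:]))


class TestSpectrum:
    def test_pure_tone_mass_in_its_band(self):
        t = np.arange(0, 4.0, 1 / FS)
        seg = np.sin(2 * np.pi * 2.0 * t)
        out = ppg_spectrum_features(seg, FS, n_bands=8)
        # Band edges span 0.8-11 Hz; 2 Hz falls in the first band.
        assert out[0] >= 0.90

    def test_normalization_sums_to_one(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            seg = rng.standard_normal(rng.integers(64, 400))
            assert ppg_spectrum_features(seg, FS).sum() == pytest.approx(1.0)

    def test_gain_invariance(self):
        rng = np.random.default_rng(6)
        seg = rng.standard_normal(200)
        a = ppg_spectrum_features(seg, FS)
        b = ppg_spectrum_features(7.3 * seg, FS)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ppg_spectrum_features(np.zeros(100), FS)
        with pytest.raises(ValueError):
            ppg_spectrum_features(np.ones(8), FS)


class TestMorphology:
    def test_symmetric_triangle_rise_equals_decay(self):
        seg = np.concatenate([np.linspace(0, 1, 50), np.linspace(1, 0, 50)[1:]])
        f = dict(zip(
            ["sys_amp", "width_half", "rise_time", "decay_time", "area_norm",
             "max_upslope", "downslope_ratio"],
            morphological_features(seg, FS),
        ))
        assert f["rise_time"] == pytest.approx(f["decay_time"], rel=1e-6)
        assert f["downslope_ratio"] == pytest.approx(1.0, rel=1e-6)

    def test_gain_homogeneity(self):
        t = np.arange(200) / FS
        seg = pulse_template(t - 0.1, 0.12)
        a = morphological_features(seg, FS)
        b = morphological_features(2.0 * seg, FS)
        names = ["sys_amp", "width_half", "rise_time", "decay_time",
                 "area_norm", "max_upslope", "downslope_ratio"]
        fa, fb = dict(zip(names, a)), dict(zip(names, b))
        assert fb["sys_amp"] == pytest.approx(2 * fa["sys_amp"])
        assert fb["max_upslope"] == pytest.approx(2 * fa["max_upslope"])
        for k in ("width_half", "rise_time", "decay_time", "area_norm",
                  "downslope_ratio"):
            assert fb[k] == pytest.approx(fa[k], rel=1e-9)

    def test_template_matches_closed_form_oracle(self):
        # Analytic oracle for w(t) = (t/2tau)^2 exp(2 - t/tau): unit peak at
        # t=2tau; crossings and extrema solved on the analytic curve.
        tau = 0.12
        fs_dense = 4000.0
        t = np.arange(int(1.2 * fs_dense)) / fs_dense  # 1.2 s window
        seg = pulse_template(t, tau)

        w = lambda x: (x / (2 * tau)) ** 2 * math.exp(2 - x / tau)
        t_peak = 2 * tau
        t_rise10 = brentq(lambda x: w(x) - 0.1, 1e-9, t_peak)
        t_decay10 = brentq(lambda x: w(x) - 0.1, t_peak, 1.2)
        t_half_l = brentq(lambda x: w(x) - 0.5, 1e-9, t_peak)
        t_half_r = brentq(lambda x: w(x) - 0.5, t_peak, 1.2)
        dw = lambda x: math.exp(2 - x / tau) * x * (2 * tau - x) / (4 * tau**3)
        t_up = PULSE_DERIV_PEAK_FRAC * tau
        # Steepest downslope of w: minimize dw on (t_peak, end).
        from scipy.optimize import minimize_scalar

        t_down = minimize_scalar(dw, bounds=(t_peak, 1.0), method="bounded").x
        area = quad(w, 0, t[-1])[0]

        got = dict(zip(
            ["sys_amp", "width_half", "rise_time", "decay_time", "area_norm",
             "max_upslope", "downslope_ratio"],
            morphological_features(seg, fs_dense),
        ))
        assert got["sys_amp"] == pytest.approx(1.0, rel=0.02)
        assert got["width_half"] == pytest.approx(t_half_r - t_half_l, rel=0.02)
        assert got["rise_time"] == pytest.approx(t_peak - t_rise10, rel=0.02)
        assert got["decay_time"] == pytest.approx(t_decay10 - t_peak, rel=0.02)
        assert got["area_norm"] == pytest.approx(area, rel=0.02)
        assert got["max_upslope"] == pytest.approx(dw(t_up), rel=0.02)
        assert got["downslope_ratio"] == pytest.approx(
            -dw(t_down) / dw(t_up), rel=0.02
        )

    def test_nonfinite_input_rejected(self):
        seg = np.ones(100)
        seg[3] = np.nan
        with pytest.raises(ValueError):
            morphological_features(seg, FS)


@pytest.fixture(scope="module")
def selected_beats(clean_recording):
    from wristbp.preprocess import score_and_select_beats

    _, _, _, beats = preprocess_chain(clean_recording)
    selected, _ = score_and_select_beats(beats)
    return selected


class TestAssembly:
    def test_ten_beats_in_ten_vectors_out(self, selected_beats, default_profile):
        table = assemble_features(selected_beats, default_profile, 60.0, FS)
        assert table.shape == (10, len(FEATURE_COLUMNS))
        assert list(table.columns) == FEATURE_COLUMNS

    def test_demographics_isolated(self, selected_beats, default_profile):
        a = assemble_features(selected_beats, default_profile, 60.0, FS)
        demo = {"age": 80.0, "sex_code": 1, "height": 165.0, "weight": 70.0}
        b = assemble_features(selected_beats, demo, 60.0, FS)
        diff_cols = [
            c for c in FEATURE_COLUMNS if not np.allclose(a[c], b[c])
        ]
        assert diff_cols == ["age"]

    def test_missing_demographic_rejected(self, selected_beats):
        with pytest.raises(ValueError, match="missing demographic"):
            assemble_features(
                selected_beats, {"age": 50, "sex_code": 1, "height": 165}, 60.0, FS
            )

    def test_dimensionality_constant_across_cohort(self):
        from wristbp.sim import simulate_cohort
        from wristbp.types import CohortSpec

        dims = set()
        for i, prof in enumerate(simulate_cohort(CohortSpec(n_subjects=5, seed=2))):
            rec = simulate_recording(prof, seed=i)
            from wristbp.model import extract_measurement_features

            table, _ = extract_measurement_features(rec, prof)
            assert table is not None
            assert np.all(np.isfinite(table.to_numpy()))
            dims.add(table.shape[1])
        assert dims == {len(FEATURE_COLUMNS)}
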
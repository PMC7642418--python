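"""Validation statistics: pairing, Bland-Altman, bins, RMSE, concordance."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wristbp.reference_data import (
    HYPERTENSION_TABLE,
    STUDY_N_SUBJECTS,
    printed_classifications,
)
from wristbp.types import ProtocolEvent
from wristbp.validation import (
    PairedReading,
    PairingError,
    accuracy_bins,
    bland_altman,
    build_report,
    classify_hypertension,
    correlation_and_ttest,
    count_threshold_discordance,
    diagnostic_concordance,
    pair_readings,
    rmse,
    rmse_from_bias_sd,
)

diff_vectors = st.lists(
    st.floats(min_value=-50, max_value=50, allow_nan=False), min_size=2, max_size=40
)


def _session(watch_times, manual_times, manual_sbp=120.0):
    events = [
        ProtocolEvent("manual", t, sbp=manual_sbp + i, dbp=80.0 + i)
        for i, t in enumerate(manual_times)
    ]
    events += [
        ProtocolEvent("watch", t, sbp=118.0, dbp=79.0) for t in watch_times
    ]
    return events


class TestPairing:
    def test_closest_previous_manual_chosen(self):
        events = _session(watch_times=[120.0], manual_times=[60.0, 300.0])
        (pair,) = pair_readings(events)
        assert pair.manual_source == "previous"
        assert pair.manual_sbp == 120.0

    def test_closest_next_manual_chosen(self):
        events = _session(watch_times=[250.0], manual_times=[60.0, 300.0])
        (pair,) = pair_readings(events)
        assert pair.manual_source == "next"
        assert pair.manual_sbp == 121.0

    def test_exact_tie_resolves_to_previous(self):
        events = _session(watch_times=[180.0], manual_times=[60.0, 300.0])
        (pair,) = pair_readings(events)
        assert pair.manual_source == "previous"

    def test_unbracketed_watch_rejected(self):
        events = _session(watch_times=[30.0], manual_times=[60.0, 300.0])
        with pytest.raises(PairingError, match="bracketing"):
            pair_readings(events)

    def test_35_sessions_yield_105_pairs(self):
        from wristbp.sim import simulate_cohort, simulate_protocol_session
        from wristbp.types import CohortSpec, NoiseConfig

        profiles = simulate_cohort(CohortSpec(n_subjects=35, seed=0))
        pairs = []
        for i, prof in enumerate(profiles):
            events = simulate_protocol_session(
                prof, seed=i, noise=NoiseConfig.clean(), duration=6.0
            )
            for e in events:
                if e.kind == "watch":
                    e.sbp, e.dbp = 120.0, 80.0
            pairs.extend(pair_readings(events, subject_id=prof.subject_id))
        assert len(pairs) == 105

    def test_every_watch_event_pairs_exactly_once(self):
        events = _session(
            watch_times=[90.0, 200.0, 310.0],
            manual_times=[60.0, 150.0, 260.0, 370.0],
        )
        assert len(pair_readings(events)) == 3


class TestBlandAltman:
    def test_zero_differences(self):
        ba = bland_altman(np.zeros(5))
        assert ba.bias == 0 and ba.sd == 0
        assert ba.loa_lower == 0 and ba.loa_upper == 0

    def test_hand_computed_example(self):
        ba = bland_altman(np.array([-2.0, 0.0, 2.0]))
        assert ba.bias == pytest.approx(0.0)
        assert ba.sd == pytest.approx(2.0)
        assert ba.loa_upper == pytest.approx(3.92)
        assert ba.loa_lower == pytest.approx(-3.92)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(np.array([1.0]))

    def test_recovers_injected_device_bias(self):
        rng = np.random.default_rng(0)
        diffs = rng.normal(3.0, 6.0, size=105)
        ba = bland_altman(diffs)
        assert ba.bias == pytest.approx(3.0, abs=3 * 6.0 / np.sqrt(105))
        assert ba.sd == pytest.approx(6.0, rel=0.25)


class TestAccuracyBins:
    def test_counted_example(self):
        assert accuracy_bins(np.array([0.0, 4.0, 9.0, 16.0])) == (50.0, 75.0, 75.0)

    def test_all_zero(self):
        assert accuracy_bins(np.zeros(7)) == (100.0, 100.0, 100.0)

    def test_boundary_inclusive(self):
        assert accuracy_bins(np.array([5.0, -10.0, 15.0])) == (
            pytest.approx(100 / 3),
            pytest.approx(200 / 3),
            pytest.approx(100.0),
        )

    @settings(deadline=None, derandomize=True)
    @given(diff_vectors)
    def test_nesting_property(self, diffs):
        p5, p10, p15 = accuracy_bins(np.array(diffs))
        assert p5 <= p10 <= p15 <= 100.0


class TestRMSE:
    def test_symmetric_pair(self):
        assert rmse(np.array([3.0, -3.0])) == pytest.approx(3.0)

    def test_printed_sbp_summary_consistent(self):
        # bias 2.2, SD 6.1 -> RMSE 6.5 at one decimal.
        assert round(rmse_from_bias_sd(2.2, 6.1), 1) == 6.5

    def test_printed_dbp_summary_consistent(self):
        assert round(rmse_from_bias_sd(-0.2, 4.2), 1) == 4.2

    @settings(deadline=None, derandomize=True)
    @given(diff_vectors)
    def test_decomposition_identity(self, diffs):
        d = np.array(diffs)
        n = len(d)
        ba = bland_altman(d)
        assert rmse(d) ** 2 == pytest.approx(
            ba.bias**2 + (n - 1) / n * ba.sd**2, abs=1e-8
        )

    def test_rmse_bounds_mean_diff(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            d = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 8), size=30)
            assert rmse(d) >= abs(d.mean()) - 1e-12


class TestCorrelation:
    def test_identical_series(self):
        dev = np.array([120.0, 130.0, 140.0, 125.0])
        r, t, p, high = correlation_and_ttest(dev, dev.copy())
        assert r == pytest.approx(1.0)
        assert t == 0.0 and p == 1.0
        assert high

    def test_constant_offset_degenerate_t(self):
        dev = np.array([121.0, 131.0, 141.0])
        man = dev - 1.0
        r, t, p, _ = correlation_and_ttest(dev, man)
        assert r == pytest.approx(1.0)
        assert np.isnan(t) and np.isnan(p)

    def test_zero_variance_r_undefined(self):
        dev = np.full(5, 120.0)
        man = np.array([118.0, 122.0, 119.0, 121.0, 120.0])
        r, _, _, high = correlation_and_ttest(dev, man)
        assert np.isnan(r) and not high

    def test_attenuation_matches_closed_form(self):
        # device = manual + noise attenuates r to s/sqrt(s^2+n^2).
        rng = np.random.default_rng(2)
        s_sd, n_sd = 20.0, 6.0
        manual = 125 + s_sd * rng.standard_normal(5000)
        device = manual + n_sd * rng.standard_normal(5000)
        r, _, _, _ = correlation_and_ttest(device, manual)
        expected = s_sd / np.hypot(s_sd, n_sd)
        assert r == pytest.approx(expected, abs=0.02)


class TestHypertension:
    def test_published_first_row_device_vs_manual(self):
        row = HYPERTENSION_TABLE[0]
        assert classify_hypertension(row["device_sbp"], row["device_dbp"]) is False
        assert classify_hypertension(row["manual_sbp"], row["manual_dbp"]) is True

    def test_two_of_three_rule(self):
        assert classify_hypertension((136, 120, 120), (60, 60, 86)) is True
        assert classify_hypertension((136, 120, 120), (60, 60, 85)) is False

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError):
            classify_hypertension((140, 140), (90, 90))

    def test_printed_table_concordance_971(self):
        dev, man = printed_classifications()
        acc, n_disc = diagnostic_concordance(dev, man, STUDY_N_SUBJECTS)
        assert n_disc == 1
        assert acc == pytest.approx(97.1, abs=0.05)

    def test_all_concordant_is_100(self):
        acc, n = diagnostic_concordance({"a": True}, {"a": True}, 35)
        assert acc == 100.0 and n == 0

    def test_total_below_listed_rejected(self):
        with pytest.raises(ValueError):
            diagnostic_concordance({"a": True, "b": False}, {"a": True, "b": False}, 1)

    def test_measurement_discordance_counter(self):
        assert count_threshold_discordance([140.0], [130.0], 135.0) == 1
        assert count_threshold_discordance([140.0, 120.0], [140.0, 120.0], 135.0) == 0


class TestFullStudyRecovery:
    def test_unbiased_device_noise_recovered(self):
        # 35 subjects x 3 device readings = truth + N(0, 6); manual = truth.
        # The report's mean difference sits within 3 SE of zero and the
        # within-10 percentage within 3 binomial SE of 2*Phi(10/6)-1.
        from scipy.stats import norm

        rng = np.random.default_rng(7)
        pairs = []
        for s in range(35):
            truth = rng.normal(130, 20)
            for _ in range(3):
                pairs.append(
                    PairedReading(
                        subject_id=f"s{s}",
                        device_sbp=truth + rng.normal(0, 6.0),
                        device_dbp=80.0 + rng.normal(0, 4.0),
                        manual_sbp=truth,
                        manual_dbp=80.0,
                        manual_source="previous",
                    )
                )
        rep = build_report(pairs, n_total_subjects=35)
        se_mean = 6.0 / np.sqrt(105)
        assert abs(rep.sbp["mean_diff"]) < 3 * se_mean
        p_expect = 100 * (2 * norm.cdf(10 / 6.0) - 1)
        se_p = 100 * np.sqrt(p_expect / 100 * (1 - p_expect / 100) / 105)
        assert abs(rep.sbp["pct_within_10"] - p_expect) < 3 * se_p
        assert rep.sbp["pct_within_5"] <= rep.sbp["pct_within_10"] <= rep.sbp["pct_within_15"]
        assert rep.sbp["rmse"] >= abs(rep.sbp["mean_diff"])

    def test_report_serialization_roundtrip(self):
        rng = np.random.default_rng(8)
        pairs = [
            PairedReading("s", 120 + rng.normal(), 80.0, 120.0, 80.0, "previous")
            for _ in range(10)
        ]
        rep = build_report(pairs)
        import json

        d = json.loads(rep.to_json())
        assert d["n_pairs"] == 10
        assert "mean_diff" in d["sbp"]
        assert "Paired readings" in rep.summary()
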
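"""BP network: recovery, determinism, read-out identity, aggregation."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wristbp.features import FEATURE_COLUMNS
from wristbp.model import (
    BPNetwork,
    GeneralModel,
    TrainConfig,
    estimate_measurement,
    predict,
)
from wristbp.sim import simulate_feature_table
from wristbp.types import CohortSpec, NoiseConfig, SubjectProfile

COMPACT = TrainConfig(
    layer_options=(1,), node_options=(16,), activation_options=("relu",),
    cv_folds=3, max_epochs=300, seed=0,
)


def _linear_ptt_cohort(rng, n_subjects=40, beats_per_subject=10, noise_sd=3.0):
    """Feature table with SBP = (0.40 - ptt)/0.001 + noise; nuisance features
    are uninformative."""
    rows, y, groups = [], [], []
    for s in range(n_subjects):
        ptt = rng.uniform(0.23, 0.31)
        sbp_true = (0.40 - ptt) / 0.001
        for _ in range(beats_per_subject):
            fv = dict.fromkeys(FEATURE_COLUMNS, 0.0)
            fv["ptt"] = ptt + 0.001 * rng.standard_normal()
            for i in range(8):
                fv[f"spec_{i}"] = 0.125 + 0.01 * rng.standard_normal()
            fv["sys_amp"] = 1.0 + 0.05 * rng.standard_normal()
            fv["heart_rate"] = 70.0
            fv["age"] = 50.0
            fv["height"] = 165.0
            fv["weight"] = 70.0
            rows.append([fv[c] for c in FEATURE_COLUMNS])
            y.append(
                (sbp_true + noise_sd * rng.standard_normal(),
                 0.5 * sbp_true + noise_sd * rng.standard_normal())
            )
            groups.append(f"s{s}")
    X = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    return X, pd.DataFrame(y, columns=["sbp", "dbp"]), np.array(groups)


@pytest.fixture(scope="module")
def ptt_fit():
    rng = np.random.default_rng(0)
    X, y, groups = _linear_ptt_cohort(rng)
    train_sel = np.isin(groups, [f"s{i}" for i in range(30)])
    res = BPNetwork(X[train_sel], y[train_sel], groups[train_sel]).fit(COMPACT)
    return res, X[~train_sel], y[~train_sel]


class TestTraining:
    def test_linear_ptt_recovery_on_heldout_subjects(self, ptt_fit):
        # Targets carry 3 mmHg of noise; held-out RMSE must stay within
        # twice that floor.
        res, X_test, y_test = ptt_fit
        preds, _ = res.predict(X_test)
        rmse = np.sqrt(np.mean((preds[:, 0] - y_test["sbp"].to_numpy()) ** 2))
        assert rmse <= 6.0

    def test_heldout_correlation_exceeds_09(self, ptt_fit):
        res, X_test, y_test = ptt_fit
        preds, _ = res.predict(X_test)
        r = np.corrcoef(preds[:, 0], y_test["sbp"])[0, 1]
        assert r >= 0.9

    def test_constant_targets_learned_exactly(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(
            rng.standard_normal((120, len(FEATURE_COLUMNS))), columns=FEATURE_COLUMNS
        )
        y = pd.DataFrame({"sbp": [120.0] * 120, "dbp": [80.0] * 120})
        groups = np.repeat(np.arange(12), 10)
        res = BPNetwork(X, y, groups).fit(COMPACT)
        preds, _ = res.predict(X)
        assert np.all(np.abs(preds[:, 0] - 120.0) < 1.0)
        assert np.all(np.abs(preds[:, 1] - 80.0) < 1.0)

    def test_determinism(self):
        rng = np.random.default_rng(2)
        X, y, groups = _linear_ptt_cohort(rng, n_subjects=10, beats_per_subject=5)
        a = BPNetwork(X, y, groups).fit(COMPACT)
        b = BPNetwork(X, y, groups).fit(COMPACT)
        assert a.model.params.hidden_sizes == b.model.params.hidden_sizes
        for wa, wb in zip(a.model.params.W, b.model.params.W):
            np.testing.assert_array_equal(wa, wb)
        np.testing.assert_array_equal(a.model.params.W_out, b.model.params.W_out)

    def test_search_log_covers_space_and_selects_argmin(self):
        rng = np.random.default_rng(3)
        X, y, groups = _linear_ptt_cohort(rng, n_subjects=12, beats_per_subject=5)
        cfg = TrainConfig(
            layer_options=(1, 2), node_options=(8,), activation_options=("relu",),
            cv_folds=3, max_epochs=150, seed=1,
        )
        res = BPNetwork(X, y, groups).fit(cfg)
        assert len(res.search_log) == 2
        best = res.search_log.loc[res.search_log.cv_mse.idxmin()]
        assert len(res.model.params.hidden_sizes) == int(best.n_layers)
        assert res.cv_mse == pytest.approx(best.cv_mse)

    def test_subject_grouped_folds_are_disjoint(self):
        # Structural check of the fold construction the fit uses: all beats
        # of a subject share a fold, so validation subjects never appear in
        # their fold's training rows.
        from sklearn.model_selection import GroupKFold

        rng = np.random.default_rng(4)
        X, y, groups = _linear_ptt_cohort(rng, n_subjects=10, beats_per_subject=5)
        for tr, va in GroupKFold(n_splits=3).split(X, y, groups):
            assert set(groups[tr]) & set(groups[va]) == set()

    def test_empty_search_space_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(layer_options=())

    def test_noise_degradation_monotonic_on_average(self):
        # Mean held-out RMSE over 5 seeds must not decrease as the
        # generator's PTT noise rises through 2/6/12 mmHg equivalents.
        from wristbp.sim import simulate_cohort

        cfg = TrainConfig(
            layer_options=(1,), node_options=(16,), activation_options=("relu",),
            cv_folds=2, max_epochs=200, seed=0,
        )
        mean_rmse = []
        for ptt_noise in (0.002, 0.006, 0.012):
            rmses = []
            for seed in range(5):
                profiles = simulate_cohort(CohortSpec(n_subjects=16, seed=seed))
                X, y, groups = simulate_feature_table(
                    profiles, n_measurements=2, beats_per_measurement=5,
                    seed=seed, ptt_noise_sd=ptt_noise,
                )
                hold = np.isin(groups, [p.subject_id for p in profiles[12:]])
                res = BPNetwork(X[~hold], y[~hold], groups[~hold]).fit(cfg)
                preds, _ = res.predict(X[hold])
                rmses.append(
                    np.sqrt(np.mean((preds[:, 0] - y["sbp"][hold]) ** 2))
                )
            mean_rmse.append(np.mean(rmses))
        assert mean_rmse[0] <= mean_rmse[1] <= mean_rmse[2]


class TestPrediction:
    def test_output_is_affine_readout_of_hidden(self, ptt_fit):
        res, X_test, _ = ptt_fit
        m = res.model
        fv = X_test.iloc[[0]]
        sbp, dbp, hidden = predict(m, fv)
        assert sbp == pytest.approx(
            float(m.params.W_out[0] @ hidden + m.params.b_out[0]), abs=1e-9
        )
        assert dbp == pytest.approx(
            float(m.params.W_out[1] @ hidden + m.params.b_out[1]), abs=1e-9
        )

    def test_zeroed_output_weights_force_constant(self, ptt_fit):
        res, X_test, _ = ptt_fit
        m = GeneralModel.from_json(res.model.to_json())
        m.params.W_out[:] = 0.0
        m.params.b_out[:] = (120.0, 80.0)
        preds, _ = m.predict(X_test)
        assert np.all(preds[:, 0] == 120.0) and np.all(preds[:, 1] == 80.0)

    def test_schema_mismatch_rejected(self, ptt_fit):
        res, _, _ = ptt_fit
        with pytest.raises(ValueError):
            res.model.predict(np.zeros((1, 3)))

    def test_json_roundtrip_preserves_predictions(self, ptt_fit):
        res, X_test, _ = ptt_fit
        m2 = GeneralModel.from_json(res.model.to_json())
        a, _ = res.model.predict(X_test)
        b, _ = m2.predict(X_test)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_summary_mentions_architecture(self, ptt_fit):
        res, _, _ = ptt_fit
        s = res.summary()
        assert "16" in s and "relu" in s and "cross-validated" in s.lower()


def build_oracle_model() -> GeneralModel:
    """A network whose weights implement the generator's exact law
    SBP = (0.40 - ptt)/0.001, DBP = SBP - 55: one hidden layer of two relu
    nodes encoding +/-ptt, so the affine read-out reproduces the linear map
    exactly.  Serves as the oracle-matched model for end-to-end checks of
    the measurement chain."""
    from wristbp._mlp import MLPParams

    d = len(FEATURE_COLUMNS)
    ptt_idx = FEATURE_COLUMNS.index("ptt")
    w1 = np.zeros((2, d))
    w1[0, ptt_idx] = 1.0
    w1[1, ptt_idx] = -1.0
    params = MLPParams(
        hidden_sizes=(2,),
        activation="relu",
        W=[w1],
        gamma=[np.ones(2)],
        beta=[np.zeros(2)],
        # BN in inference mode with these stats is the identity map.
        bn_mean=[np.zeros(2)],
        bn_var=[np.full(2, 1.0 - 1e-5)],
        W_out=np.array([[-1000.0, 1000.0], [-1000.0, 1000.0]]),
        b_out=np.array([400.0, 345.0]),
    )
    return GeneralModel(
        columns=list(FEATURE_COLUMNS),
        x_mean=np.zeros(d),
        x_scale=np.ones(d),
        params=params,
    )


class TestMeasurementEstimation:
    def test_clean_measurement_estimated_close_to_truth(self):
        # Oracle-matched model: the full signal chain (filter, segment,
        # QC, PTT, median aggregation) must land within 5 mmHg of truth.
        from wristbp.sim import simulate_recording

        model = build_oracle_model()
        for seed, sbp in [(77, 135.0), (78, 112.0), (79, 158.0)]:
            prof = SubjectProfile("e1", 55, "F", 160, 62, sbp, 75.0, 68.0,
                                  ptt_intercept=0.40, ptt_slope=0.001)
            rec = simulate_recording(prof, noise=NoiseConfig.clean(), seed=seed)
            est = estimate_measurement(model, rec, prof)
            assert est.ok
            assert est.per_beat.shape[0] == 10
            assert abs(est.sbp - np.median(est.per_beat[:, 0])) < 1e-9
            assert abs(est.sbp - prof.true_sbp) <= 5.0

    def test_oracle_model_readout_is_exact_on_features(self):
        model = build_oracle_model()
        fv = pd.DataFrame([dict.fromkeys(FEATURE_COLUMNS, 0.0)])
        fv["ptt"] = 0.27
        sbp, dbp, _ = predict(model, fv)
        assert sbp == pytest.approx(130.0, abs=0.01)
        assert dbp == pytest.approx(75.0, abs=0.01)

    def test_corrupted_measurement_gives_no_estimate(self):
        from wristbp.sim import simulate_recording

        model = build_oracle_model()
        prof = SubjectProfile("e2", 55, "F", 160, 62, 135.0, 75.0, 68.0)
        rec = simulate_recording(
            prof, noise=NoiseConfig(bad_contact=True), seed=78
        )
        est = estimate_measurement(model, rec, prof)
        assert not est.ok
        assert est.sbp is None and est.dbp is None

    def test_median_is_beat_order_invariant(self, ptt_fit):
        res, X_test, _ = ptt_fit
        block = X_test.iloc[:10]
        preds, _ = res.predict(block)
        shuffled, _ = res.predict(block.iloc[::-1])
        assert np.median(preds[:, 0]) == np.median(shuffled[:, 0])
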
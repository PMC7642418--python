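"""General BP estimation network: training, architecture search, inference.

The estimator is a fully connected network with batch-normalized hidden
layers and a two-node linear output (SBP, DBP).  Because the output layer
is affine in the final hidden activations, the SBP and DBP heads are two
linear regressions sharing learned features — which is what makes the
per-subject affine calibration (see :mod:`wristbp.calibration`) equivalent
to adjusting the output layer.

Exposed statsmodels-style: build a :class:`BPNetwork` from a feature table
and targets, call ``fit`` with a :class:`TrainConfig`, and get a
:class:`BPNetworkResults` carrying the fitted :class:`GeneralModel`, the
cross-validation search log and ``predict``/``summary`` methods.

Architecture search: every combination of layer count, layer width and
activation in the config is scored by subject-grouped K-fold
cross-validated MSE (summed over the two outputs); the argmin architecture
is refit on all rows.  Grouping all beats of a subject into the same fold
prevents leakage between folds.
"""
from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.model_selection import GroupKFold

from ._mlp import MLPParams, fit_mlp, init_mlp, predict_with_hidden
from .features import FEATURE_COLUMNS, assemble_features
from .preprocess import (
    DEFAULT_QUALITY_THRESHOLD,
    ECG_BAND,
    PPG_BAND,
    bandpass,
    detect_r_peaks,
    gate_measurement,
    score_and_select_beats,
    segment_beats,
)
from .types import Recording, SubjectProfile

__all__ = [
    "TrainConfig",
    "GeneralModel",
    "BPNetwork",
    "BPNetworkResults",
    "MeasurementEstimate",
    "train_general_model",
    "predict",
    "extract_measurement_features",
    "estimate_measurement",
]


@dataclass(frozen=True)
class TrainConfig:
    """Architecture search space and optimization settings.

    The default space (1-3 hidden layers, 8-32 nodes, relu/tanh, 5-fold CV)
    is desk-scale; studies in the tests and the acceptance script shrink it
    where a full sweep would add nothing.
    """

    layer_options: tuple[int, ...] = (1, 2, 3)
    node_options: tuple[int, ...] = (8, 16, 32)
    activation_options: tuple[str, ...] = ("relu", "tanh")
    cv_folds: int = 5
    max_epochs: int = 500
    learning_rate: float = 0.01
    tol: float = 1e-6
    patience: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not (self.layer_options and self.node_options and self.activation_options):
            raise ValueError("search space must be non-empty")

    def candidates(self) -> list[tuple[tuple[int, ...], str]]:
        out = []
        for n_layers, nodes, act in itertools.product(
            self.layer_options, self.node_options, self.activation_options
        ):
            out.append(((nodes,) * n_layers, act))
        return out


def _schema_hash(columns: Sequence[str]) -> str:
    return hashlib.sha1("|".join(columns).encode()).hexdigest()[:12]


@dataclass
class GeneralModel:
    """A fitted, self-contained BP estimation network.

    Carries input standardization, all network parameters with frozen
    batch-norm statistics, and the feature schema it was trained on.
    Serializes losslessly to JSON.
    """

    columns: list[str]
    x_mean: np.ndarray
    x_scale: np.ndarray
    params: MLPParams

    @property
    def schema_hash(self) -> str:
        return _schema_hash(self.columns)

    @property
    def final_hidden_dim(self) -> int:
        return self.params.hidden_sizes[-1]

    @property
    def model_hash(self) -> str:
        h = hashlib.sha1()
        h.update(self.schema_hash.encode())
        for w in (*self.params.W, self.params.W_out, self.params.b_out):
            h.update(np.ascontiguousarray(w).tobytes())
        return h.hexdigest()[:12]

    def _design(self, X: Union[pd.DataFrame, np.ndarray]) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.columns if c not in X.columns]
            if missing:
                raise ValueError(f"feature table missing columns {missing}")
            x = X[self.columns].to_numpy(dtype=float)
        else:
            x = np.atleast_2d(np.asarray(X, dtype=float))
            if x.shape[1] != len(self.columns):
                raise ValueError(
                    f"schema mismatch: expected {len(self.columns)} features, got {x.shape[1]}"
                )
        return (x - self.x_mean) / self.x_scale

    def predict(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Return (predictions (m, 2), final hidden activations (m, k))."""
        out, hidden = predict_with_hidden(self.params, self._design(X))
        return out, hidden

    def to_json(self) -> str:
        p = self.params
        return json.dumps(
            {
                "schema_version": 1,
                "columns": self.columns,
                "x_mean": self.x_mean.tolist(),
                "x_scale": self.x_scale.tolist(),
                "hidden_sizes": list(p.hidden_sizes),
                "activation": p.activation,
                "W": [w.tolist() for w in p.W],
                "gamma": [g.tolist() for g in p.gamma],
                "beta": [b.tolist() for b in p.beta],
                "bn_mean": [m.tolist() for m in p.bn_mean],
                "bn_var": [v.tolist() for v in p.bn_var],
                "W_out": p.W_out.tolist(),
                "b_out": p.b_out.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GeneralModel":
        d = json.loads(text)
        params = MLPParams(
            hidden_sizes=tuple(d["hidden_sizes"]),
            activation=d["activation"],
            W=[np.array(w) for w in d["W"]],
            gamma=[np.array(g) for g in d["gamma"]],
            beta=[np.array(b) for b in d["beta"]],
            bn_mean=[np.array(m) for m in d["bn_mean"]],
            bn_var=[np.array(v) for v in d["bn_var"]],
            W_out=np.array(d["W_out"]),
            b_out=np.array(d["b_out"]),
        )
        return cls(
            columns=list(d["columns"]),
            x_mean=np.array(d["x_mean"]),
            x_scale=np.array(d["x_scale"]),
            params=params,
        )


class BPNetwork:
    """Model object: per-beat features, paired reference SBP/DBP, subject ids.

    ``groups`` ties all beats of one subject together for leakage-safe
    cross-validation; if omitted, rows are treated as independent subjects.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y: Union[pd.DataFrame, np.ndarray],
        groups: Optional[Sequence] = None,
    ):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float), columns=FEATURE_COLUMNS)
        y_arr = y.to_numpy(dtype=float) if isinstance(y, pd.DataFrame) else np.asarray(y, dtype=float)
        if y_arr.ndim != 2 or y_arr.shape[1] != 2:
            raise ValueError("y must have exactly two columns: SBP, DBP")
        if len(X) != len(y_arr):
            raise ValueError("X and y length mismatch")
        if not np.all(np.isfinite(X.to_numpy(dtype=float))) or not np.all(np.isfinite(y_arr)):
            raise ValueError("non-finite values in training data")
        self.X = X.reset_index(drop=True)
        self.y = y_arr
        self.groups = (
            np.asarray(groups) if groups is not None else np.arange(len(X))
        )
        if len(self.groups) != len(X):
            raise ValueError("groups length mismatch")

    @classmethod
    def from_feature_table(
        cls, table: pd.DataFrame, target_cols: tuple[str, str] = ("sbp", "dbp"),
        group_col: str = "subject_id",
    ) -> "BPNetwork":
        feats = [c for c in table.columns if c in FEATURE_COLUMNS]
        groups = table[group_col] if group_col in table.columns else None
        return cls(table[feats], table[list(target_cols)], groups)

    def fit(self, config: Optional[TrainConfig] = None) -> "BPNetworkResults":
        cfg = config if config is not None else TrainConfig()
        X = self.X.to_numpy(dtype=float)
        x_mean = X.mean(axis=0)
        x_scale = X.std(axis=0)
        x_scale[x_scale == 0] = 1.0
        Xs = (X - x_mean) / x_scale
        y = self.y

        n_groups = len(np.unique(self.groups))
        folds = min(cfg.cv_folds, n_groups)
        if folds < 2:
            raise ValueError("need at least 2 distinct subject groups for CV")
        splitter = GroupKFold(n_splits=folds)
        splits = list(splitter.split(Xs, y, groups=self.groups))

        root = np.random.SeedSequence(cfg.seed)
        log_rows = []
        best = None
        for ci, (arch, act) in enumerate(cfg.candidates()):
            fold_losses = []
            for fi, (tr, va) in enumerate(splits):
                params = init_mlp(
                    Xs.shape[1], arch, act,
                    seed=np.random.SeedSequence((cfg.seed, ci, fi)),
                    y_mean=y[tr].mean(axis=0),
                )
                params, _ = fit_mlp(
                    params, Xs[tr], y[tr],
                    lr=cfg.learning_rate, max_epochs=cfg.max_epochs, tol=cfg.tol,
                    X_val=Xs[va], y_val=y[va], patience=cfg.patience,
                )
                out, _ = predict_with_hidden(params, Xs[va])
                fold_losses.append(float(((out - y[va]) ** 2).sum(axis=1).mean()))
            mean_loss = float(np.mean(fold_losses))
            if not np.isfinite(mean_loss):
                raise FloatingPointError(
                    f"non-finite CV loss for architecture {arch}/{act}"
                )
            log_rows.append(
                {
                    "n_layers": len(arch),
                    "nodes": arch[0],
                    "activation": act,
                    **{f"fold{j}_mse": fl for j, fl in enumerate(fold_losses)},
                    "cv_mse": mean_loss,
                }
            )
            if best is None or mean_loss < best[0]:
                best = (mean_loss, ci, arch, act)

        _, ci, arch, act = best
        params = init_mlp(
            Xs.shape[1], arch, act,
            seed=np.random.SeedSequence((cfg.seed, ci, folds)),
            y_mean=y.mean(axis=0),
        )
        params, history = fit_mlp(
            params, Xs, y,
            lr=cfg.learning_rate, max_epochs=cfg.max_epochs, tol=cfg.tol,
        )
        model = GeneralModel(
            columns=list(self.X.columns), x_mean=x_mean, x_scale=x_scale, params=params
        )
        return BPNetworkResults(
            model=model,
            search_log=pd.DataFrame(log_rows),
            cv_mse=best[0],
            config=cfg,
            history=history,
            train_y=y,
        )


@dataclass
class BPNetworkResults:
    """Fit artifacts: the serializable model, search log, diagnostics."""

    model: GeneralModel
    search_log: pd.DataFrame
    cv_mse: float
    config: TrainConfig
    history: dict = field(default_factory=dict)
    train_y: Optional[np.ndarray] = None

    def predict(self, X) -> tuple[np.ndarray, np.ndarray]:
        return self.model.predict(X)

    def summary(self) -> str:
        m = self.model
        lines = [
            "BP estimation network",
            "=" * 52,
            f"features:            {len(m.columns)} ({m.schema_hash})",
            f"architecture:        {' -> '.join(map(str, m.params.hidden_sizes))} -> 2",
            f"activation:          {m.params.activation}",
            f"cross-validated MSE: {self.cv_mse:.2f} mmHg^2 (SBP+DBP)",
            f"candidates searched: {len(self.search_log)}",
            "",
            "search log (best 5 by CV MSE):",
        ]
        top = self.search_log.nsmallest(5, "cv_mse")
        for _, r in top.iterrows():
            lines.append(
                f"  layers={int(r.n_layers)} nodes={int(r.nodes)} "
                f"act={r.activation:<5} cv_mse={r.cv_mse:8.2f}"
            )
        return "\n".join(lines)


def train_general_model(
    X: pd.DataFrame,
    y,
    groups: Optional[Sequence] = None,
    config: Optional[TrainConfig] = None,
) -> tuple[GeneralModel, pd.DataFrame]:
    """Functional wrapper: returns (fitted model, architecture search log)."""
    res = BPNetwork(X, y, groups).fit(config)
    return res.model, res.search_log


def predict(model: GeneralModel, fv) -> tuple[float, float, np.ndarray]:
    """Single feature vector -> (sbp_hat, dbp_hat, final hidden activations).

    The outputs are exactly the affine read-out of the returned hidden
    activations through the model's output layer.
    """
    out, hidden = model.predict(fv)
    return float(out[0, 0]), float(out[0, 1]), hidden[0]


@dataclass
class MeasurementEstimate:
    """Outcome of estimating one 24-s measurement.

    ``ok=False`` means the quality gate refused the measurement; there is
    deliberately no fallback number in that case.
    """

    ok: bool
    sbp: Optional[float]
    dbp: Optional[float]
    qc: object
    reason: str = "none"
    per_beat: Optional[np.ndarray] = None      # (10, 2) per-beat predictions
    hidden_mean: Optional[np.ndarray] = None   # mean final-hidden activations


def extract_measurement_features(
    recording: Recording,
    demographics: Union[SubjectProfile, Mapping[str, float]],
    quality_threshold: float = DEFAULT_QUALITY_THRESHOLD,
    n_beats: int = 10,
):
    """Front half of the estimation chain: denoise, segment, gate, extract.

    Returns ``(feature_table | None, qc)`` — the table is ``None`` whenever
    the quality gate refuses the measurement.
    """
    from .types import MeasurementQC

    ecg_f = bandpass(recording.ecg, recording.fs, *ECG_BAND)
    ppg_f = bandpass(recording.ppg, recording.fs, *PPG_BAND)
    r_peaks = detect_r_peaks(ecg_f, recording.fs)
    beats = segment_beats(ecg_f, ppg_f, r_peaks, recording.fs)
    if len(beats) == 0:
        qc = MeasurementQC(0, 0, float("nan"), float("nan"), False, "too_few_beats")
        return None, qc
    selected, qc = score_and_select_beats(beats, n_select=n_beats)
    if not gate_measurement(qc, threshold=quality_threshold):
        return None, qc
    rr = np.diff([b.r_peak_time for b in beats])
    heart_rate = 60.0 / float(np.median(rr)) if len(rr) else 60.0
    table = assemble_features(selected, demographics, heart_rate, recording.fs)
    return table, qc


def estimate_measurement(
    model: GeneralModel,
    recording: Recording,
    demographics: Union[SubjectProfile, Mapping[str, float]],
    terms=None,
    quality_threshold: float = DEFAULT_QUALITY_THRESHOLD,
    n_beats: int = 10,
) -> MeasurementEstimate:
    """Full chain for one recording: denoise -> beats -> QC -> features ->
    per-beat prediction -> median over beats (-> calibration).

    The measurement estimate is the median of the 10 per-beat predictions;
    calibration terms, when given, apply their affine correction per
    channel.  A QC failure returns an explicit no-estimate result.
    """
    table, qc = extract_measurement_features(
        recording, demographics, quality_threshold, n_beats
    )
    if table is None:
        return MeasurementEstimate(False, None, None, qc, reason=qc.reject_reason)
    preds, hidden = model.predict(table)
    sbp = float(np.median(preds[:, 0]))
    dbp = float(np.median(preds[:, 1]))
    if terms is not None:
        from .calibration import apply_calibration_values

        sbp, dbp = apply_calibration_values(model, terms, sbp, dbp)
    return MeasurementEstimate(
        True, sbp, dbp, qc,
        per_beat=preds, hidden_mean=hidden.mean(axis=0),
    )
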
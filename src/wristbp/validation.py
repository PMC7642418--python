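"""Device-validation statistics for paired watch/manual BP readings.

Implements the method-comparison surface used to validate cuff-less BP
devices against an auscultatory reference: the sequential-protocol pairing
rule (each device reading is compared with the temporally closest of the
bracketing manual readings), Bland-Altman bias and limits of agreement,
the +-5/10/15 mmHg accuracy bins, RMSE, Pearson correlation with a paired
t-test, and the 2-of-3 hypertension classification concordance.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .types import ProtocolEvent

__all__ = [
    "PairedReading",
    "BlandAltman",
    "ValidationReport",
    "PairingError",
    "pair_readings",
    "bland_altman",
    "accuracy_bins",
    "rmse",
    "rmse_from_bias_sd",
    "correlation_and_ttest",
    "classify_hypertension",
    "count_threshold_discordance",
    "diagnostic_concordance",
    "build_report",
    "HYPERTENSION_SBP_THRESHOLD",
    "HYPERTENSION_DBP_THRESHOLD",
]

HYPERTENSION_SBP_THRESHOLD = 135.0
HYPERTENSION_DBP_THRESHOLD = 85.0
HIGH_CORRELATION_R = 0.90


class PairingError(ValueError):
    """A watch reading lacks bracketing manual references."""


@dataclass(frozen=True)
class PairedReading:
    """One device estimate matched to its closest manual reference."""

    subject_id: str
    device_sbp: float
    device_dbp: float
    manual_sbp: float
    manual_dbp: float
    manual_source: str  # "previous" | "next"

    @property
    def diff_sbp(self) -> float:
        return self.device_sbp - self.manual_sbp

    @property
    def diff_dbp(self) -> float:
        return self.device_dbp - self.manual_dbp


def pair_readings(
    events: Sequence[ProtocolEvent], subject_id: str = ""
) -> list[PairedReading]:
    """Pair every watch event with the temporally closest manual reading.

    Only the bracketing manual readings (previous and next) are candidates;
    exact time ties resolve to the previous one.  Every watch event in a
    well-formed alternating session yields exactly one pair; a watch event
    without both a previous and a next manual raises :class:`PairingError`.
    Watch events must already carry their estimates in ``sbp``/``dbp``.
    """
    ordered = sorted(events, key=lambda e: e.t_s)
    pairs: list[PairedReading] = []
    for i, ev in enumerate(ordered):
        if ev.kind != "watch":
            continue
        prev_m = next((e for e in reversed(ordered[:i]) if e.kind == "manual"), None)
        next_m = next((e for e in ordered[i + 1:] if e.kind == "manual"), None)
        if prev_m is None or next_m is None:
            raise PairingError(
                f"watch event at t={ev.t_s:.1f}s lacks bracketing manual readings"
            )
        if ev.sbp is None or ev.dbp is None:
            raise PairingError(
                f"watch event at t={ev.t_s:.1f}s carries no estimate to pair"
            )
        chosen = prev_m if (ev.t_s - prev_m.t_s) <= (next_m.t_s - ev.t_s) else next_m
        pairs.append(
            PairedReading(
                subject_id=subject_id,
                device_sbp=float(ev.sbp),
                device_dbp=float(ev.dbp),
                manual_sbp=float(chosen.sbp),
                manual_dbp=float(chosen.dbp),
                manual_source="previous" if chosen is prev_m else "next",
            )
        )
    return pairs


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    sd: float
    loa_lower: float
    loa_upper: float
    means: np.ndarray = field(repr=False, default=None)
    diffs: np.ndarray = field(repr=False, default=None)


def bland_altman(diffs: np.ndarray, means: Optional[np.ndarray] = None) -> BlandAltman:
    """Bias, sample SD and 95% limits of agreement (bias +- 1.96 SD)."""
    diffs = np.asarray(diffs, dtype=float)
    if len(diffs) < 2:
        raise ValueError("Bland-Altman needs at least 2 paired differences")
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltman(
        bias=bias,
        sd=sd,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        means=None if means is None else np.asarray(means, dtype=float),
        diffs=diffs,
    )


def accuracy_bins(
    diffs: np.ndarray, thresholds: tuple[float, ...] = (5.0, 10.0, 15.0)
) -> tuple[float, ...]:
    """Percentage of readings with |difference| <= each threshold (inclusive)."""
    diffs = np.asarray(diffs, dtype=float)
    if len(diffs) == 0:
        raise ValueError("no differences supplied")
    return tuple(float(100.0 * np.mean(np.abs(diffs) <= t)) for t in thresholds)


def rmse(diffs: np.ndarray) -> float:
    """Root mean squared difference."""
    diffs = np.asarray(diffs, dtype=float)
    if len(diffs) == 0:
        raise ValueError("no differences supplied")
    return float(np.sqrt(np.mean(diffs**2)))


def rmse_from_bias_sd(bias: float, sd: float) -> float:
    """RMSE implied by a reported bias and (population) SD: sqrt(b^2+s^2)."""
    return math.hypot(bias, sd)


def correlation_and_ttest(
    device: np.ndarray, manual: np.ndarray
) -> tuple[float, float, float, bool]:
    """Pearson r between methods plus a two-sided paired t-test.

    Returns (r, t, p, high_correlation) with r > 0.90 flagged as high.
    Zero variance in either series makes r undefined (NaN); zero variance
    of the differences makes the paired t degenerate (NaN t/p) unless the
    series are identical, where t=0, p=1 by convention.
    """
    device = np.asarray(device, dtype=float)
    manual = np.asarray(manual, dtype=float)
    if len(device) != len(manual) or len(device) < 3:
        raise ValueError("need >= 3 matched readings")
    if device.std() == 0 or manual.std() == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(device, manual).statistic)
    d = device - manual
    if d.std(ddof=1) == 0:
        if np.allclose(d, 0):
            t, p = 0.0, 1.0
        else:
            t, p = float("nan"), float("nan")
    else:
        tt = stats.ttest_rel(device, manual)
        t, p = float(tt.statistic), float(tt.pvalue)
    return r, t, p, bool(r > HIGH_CORRELATION_R) if np.isfinite(r) else False


def classify_hypertension(
    sbps: Sequence[float],
    dbps: Sequence[float],
    sbp_threshold: float = HYPERTENSION_SBP_THRESHOLD,
    dbp_threshold: float = HYPERTENSION_DBP_THRESHOLD,
) -> bool:
    """2-of-3 rule: a reading is high iff SBP > 135 or DBP > 85 (strict);
    the subject is hypertensive iff at least two of the three readings are
    high."""
    if len(sbps) != 3 or len(dbps) != 3:
        raise ValueError("exactly 3 readings per channel required")
    high = sum(
        1 for s, d in zip(sbps, dbps) if s > sbp_threshold or d > dbp_threshold
    )
    return high >= 2


def count_threshold_discordance(
    device_vals: Sequence[float], manual_vals: Sequence[float], threshold: float
) -> int:
    """Measurement pairs where exactly one of device/manual exceeds the
    threshold (strict >)."""
    if len(device_vals) != len(manual_vals):
        raise ValueError("length mismatch")
    return sum(
        1
        for d, m in zip(device_vals, manual_vals)
        if (d > threshold) != (m > threshold)
    )


def diagnostic_concordance(
    device_class: Mapping[str, bool],
    manual_class: Mapping[str, bool],
    n_total_subjects: int,
) -> tuple[float, int]:
    """Diagnostic accuracy of the device's hypertension classification.

    Subjects absent from the mappings are counted concordant (they were not
    flagged by either method).  Returns (accuracy %, discordant subjects).
    """
    if set(device_class) != set(manual_class):
        raise ValueError("device and manual classifications cover different subjects")
    if n_total_subjects < len(device_class):
        raise ValueError("n_total_subjects smaller than listed subjects")
    discordant = sum(
        1 for s in device_class if device_class[s] != manual_class[s]
    )
    accuracy = 100.0 * (n_total_subjects - discordant) / n_total_subjects
    return float(accuracy), int(discordant)


@dataclass
class ValidationReport:
    """Full statistical report over a set of paired readings."""

    n_pairs: int
    sbp: dict
    dbp: dict
    n_subjects: Optional[int] = None
    diagnostic_accuracy: Optional[float] = None
    n_discordant_subjects: Optional[int] = None

    def to_json(self, indent: int = 2) -> str:
        def clean(x):
            if isinstance(x, dict):
                return {k: clean(v) for k, v in x.items()}
            if isinstance(x, (np.floating, float)):
                return round(float(x), 6)
            if isinstance(x, (np.integer,)):
                return int(x)
            return x

        return json.dumps(clean(self.__dict__), indent=indent)

    def summary(self) -> str:
        lines = [f"Paired readings: {self.n_pairs}"]
        for name in ("sbp", "dbp"):
            ch = getattr(self, name)
            lines += [
                f"{name.upper()}: mean diff {ch['mean_diff']:+.1f} +/- {ch['sd_diff']:.1f} mmHg"
                f"  (r={ch['pearson_r']:.3f}, P={ch['p_value']:.3f})",
                f"  within 5/10/15 mmHg: {ch['pct_within_5']:.1f}% / "
                f"{ch['pct_within_10']:.1f}% / {ch['pct_within_15']:.1f}%"
                f"   RMSE {ch['rmse']:.1f} mmHg",
                f"  limits of agreement: {ch['loa_lower']:+.1f} to {ch['loa_upper']:+.1f} mmHg",
            ]
        if self.diagnostic_accuracy is not None:
            lines.append(
                f"Hypertension diagnostic accuracy: {self.diagnostic_accuracy:.1f}% "
                f"({self.n_discordant_subjects} discordant of {self.n_subjects})"
            )
        return "\n".join(lines)


def _channel_stats(device: np.ndarray, manual: np.ndarray) -> dict:
    diffs = device - manual
    ba = bland_altman(diffs, means=(device + manual) / 2.0)
    p5, p10, p15 = accuracy_bins(diffs)
    r, t, p, high = correlation_and_ttest(device, manual)
    return {
        "device_mean": float(device.mean()),
        "manual_mean": float(manual.mean()),
        "mean_diff": ba.bias,
        "sd_diff": ba.sd,
        "loa_lower": ba.loa_lower,
        "loa_upper": ba.loa_upper,
        "pct_within_5": p5,
        "pct_within_10": p10,
        "pct_within_15": p15,
        "rmse": rmse(diffs),
        "pearson_r": r,
        "t_statistic": t,
        "p_value": p,
        "high_correlation": high,
    }


def build_report(
    pairs: Sequence[PairedReading], n_total_subjects: Optional[int] = None
) -> ValidationReport:
    """Aggregate paired readings into the full validation report.

    When every subject contributes exactly three device readings, the
    2-of-3 hypertension concordance is evaluated as well (device readings
    against their paired manual references).
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 paired readings")
    dev_s = np.array([p.device_sbp for p in pairs])
    dev_d = np.array([p.device_dbp for p in pairs])
    man_s = np.array([p.manual_sbp for p in pairs])
    man_d = np.array([p.manual_dbp for p in pairs])

    report = ValidationReport(
        n_pairs=len(pairs),
        sbp=_channel_stats(dev_s, man_s),
        dbp=_channel_stats(dev_d, man_d),
    )

    by_subject: dict[str, list[PairedReading]] = {}
    for p in pairs:
        by_subject.setdefault(p.subject_id, []).append(p)
    if by_subject and all(len(v) == 3 for v in by_subject.values()):
        dev_cls, man_cls = {}, {}
        for sid, sp in by_subject.items():
            dev_cls[sid] = classify_hypertension(
                [q.device_sbp for q in sp], [q.device_dbp for q in sp]
            )
            man_cls[sid] = classify_hypertension(
                [q.manual_sbp for q in sp], [q.manual_dbp for q in sp]
            )
        n_total = n_total_subjects if n_total_subjects is not None else len(by_subject)
        acc, n_disc = diagnostic_concordance(dev_cls, man_cls, n_total)
        report.n_subjects = n_total
        report.diagnostic_accuracy = acc
        report.n_discordant_subjects = n_disc
    return report
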
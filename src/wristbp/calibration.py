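"""Per-subject calibration of the general BP network.

The wrist device systematically mis-reads some subjects (sensor placement,
vascular tone, wrist anatomy), so after the general model is frozen each
subject contributes >= 3 paired (manual, watch) measurements from which a
per-channel affine correction is fitted:

    calibrated = gain * uncalibrated + offset

Because the network's outputs are an affine read-out of the final hidden
layer, this correction is exactly equivalent to rescaling and shifting the
output-layer weights — a correction term inserted between the final hidden
and output layers — without touching the learned representation.

With only three pairs taken minutes apart, the subject's true BP barely
moves, so the gain is weakly identified; the least-squares gain is ridge-
shrunk toward 1 (penalty ``ridge_lambda`` on (gain-1)^2, default 2000
mmHg^2, i.e. a prior sd of ~0.14 on the gain for typical prediction
spreads) and calibration acts mainly as an offset correction.  Gains
escaping the (0.25, 4) sanity interval fall back to gain 1 with the mean
difference as offset.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .model import GeneralModel

__all__ = [
    "CalibrationError",
    "CalibrationPair",
    "CalibrationTerms",
    "DEFAULT_RIDGE_LAMBDA",
    "fit_calibration",
    "apply_calibration",
    "apply_calibration_values",
    "as_output_layer_adjustment",
]

DEFAULT_RIDGE_LAMBDA = 2000.0
_GAIN_BOUNDS = (0.25, 4.0)


class CalibrationError(ValueError):
    """Calibration refused (too few pairs, or model/terms mismatch)."""


@dataclass(frozen=True)
class CalibrationPair:
    """One calibration measurement: the device's uncalibrated estimate and
    its reference manual reading, plus the measurement's aggregated final-
    hidden activations (mean over the 10 beats)."""

    device_sbp: float
    device_dbp: float
    manual_sbp: float
    manual_dbp: float
    timestamp: float = 0.0
    hidden: Optional[np.ndarray] = None


@dataclass(frozen=True)
class CalibrationTerms:
    """Per-subject affine correction, bound to one model by hash."""

    sbp_gain: float
    sbp_offset: float
    dbp_gain: float
    dbp_offset: float
    n_pairs_used: int
    fit_residual_rmse_sbp: float
    fit_residual_rmse_dbp: float
    model_hash: str = ""

    def __post_init__(self) -> None:
        for g in (self.sbp_gain, self.dbp_gain):
            if not (_GAIN_BOUNDS[0] < g < _GAIN_BOUNDS[1]):
                raise ValueError(f"gain {g} outside sanity bounds {_GAIN_BOUNDS}")
        if self.n_pairs_used < 3:
            raise ValueError("calibration requires >= 3 pairs")


def _fit_channel(
    device: np.ndarray, manual: np.ndarray, ridge_lambda: float
) -> tuple[float, float, float]:
    """Ridge-toward-identity affine fit of manual = g*device + o."""
    dp = device - device.mean()
    dm = manual - manual.mean()
    s_pp = float(dp @ dp)
    if s_pp < 1e-9:
        g = 1.0
    else:
        g = (float(dm @ dp) + ridge_lambda) / (s_pp + ridge_lambda)
        if not (_GAIN_BOUNDS[0] < g < _GAIN_BOUNDS[1]):
            g = 1.0
    o = float(manual.mean() - g * device.mean())
    resid = manual - (g * device + o)
    return g, o, float(np.sqrt(np.mean(resid**2)))


def fit_calibration(
    model: GeneralModel,
    pairs: Sequence[CalibrationPair],
    ridge_lambda: float = DEFAULT_RIDGE_LAMBDA,
) -> CalibrationTerms:
    """Fit per-channel correction terms from >= 3 (manual, watch) pairs."""
    pairs = list(pairs)
    if len(pairs) < 3:
        raise CalibrationError(
            f"calibration requires >= 3 manual/device measurement pairs, got {len(pairs)}"
        )
    dev_s = np.array([p.device_sbp for p in pairs], dtype=float)
    dev_d = np.array([p.device_dbp for p in pairs], dtype=float)
    man_s = np.array([p.manual_sbp for p in pairs], dtype=float)
    man_d = np.array([p.manual_dbp for p in pairs], dtype=float)
    gs, os_, rs = _fit_channel(dev_s, man_s, ridge_lambda)
    gd, od, rd = _fit_channel(dev_d, man_d, ridge_lambda)
    return CalibrationTerms(
        sbp_gain=gs,
        sbp_offset=os_,
        dbp_gain=gd,
        dbp_offset=od,
        n_pairs_used=len(pairs),
        fit_residual_rmse_sbp=rs,
        fit_residual_rmse_dbp=rd,
        model_hash=model.model_hash,
    )


def _check_binding(model: GeneralModel, terms: CalibrationTerms) -> None:
    if terms.model_hash and terms.model_hash != model.model_hash:
        raise CalibrationError(
            f"terms were fitted against model {terms.model_hash}, "
            f"not {model.model_hash}"
        )


def apply_calibration_values(
    model: GeneralModel, terms: CalibrationTerms, sbp: float, dbp: float
) -> tuple[float, float]:
    """Affine-correct an uncalibrated (sbp, dbp) estimate."""
    _check_binding(model, terms)
    return (
        terms.sbp_gain * sbp + terms.sbp_offset,
        terms.dbp_gain * dbp + terms.dbp_offset,
    )


def apply_calibration(
    model: GeneralModel, terms: CalibrationTerms, fv
) -> tuple[float, float]:
    """Calibrated prediction for one feature vector.

    The hidden representation is untouched; only the output read-out is
    corrected.
    """
    _check_binding(model, terms)
    out, _ = model.predict(fv)
    sbp, dbp = float(out[0, 0]), float(out[0, 1])
    return apply_calibration_values(model, terms, sbp, dbp)


def as_output_layer_adjustment(
    model: GeneralModel, terms: CalibrationTerms
) -> GeneralModel:
    """Fold the correction terms into the output layer.

    Returns a new model whose output weights/bias are rescaled and shifted
    so that its raw predictions equal the calibrated predictions of the
    original model — the "correction terms between final hidden and output
    layers" view, exact to machine precision.
    """
    _check_binding(model, terms)
    p = model.params.copy()
    gains = np.array([terms.sbp_gain, terms.dbp_gain])
    offsets = np.array([terms.sbp_offset, terms.dbp_offset])
    p.W_out = p.W_out * gains[:, None]
    p.b_out = p.b_out * gains + offsets
    return replace(model, params=p)
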
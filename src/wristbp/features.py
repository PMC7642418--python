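"""Per-beat feature extraction: PTT, PPG band spectrum, pulse morphology.

The feature schema is fixed and versioned; every beat of every measurement
yields one vector with the same ordered columns so feature tables from
different sessions can be concatenated safely.
"""
from __future__ import annotations

from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import Beat, SubjectProfile

__all__ = [
    "SCHEMA_VERSION",
    "FEATURE_COLUMNS",
    "SPECTRAL_BAND_RANGE",
    "N_SPECTRAL_BANDS",
    "MORPH_COLUMNS",
    "InvalidBeatError",
    "compute_ptt",
    "ppg_spectrum_features",
    "morphological_features",
    "assemble_features",
]

SCHEMA_VERSION = "bpfv-1"
N_SPECTRAL_BANDS = 8
SPECTRAL_BAND_RANGE = (0.8, 11.0)  # matches the PPG denoising passband

MORPH_COLUMNS = [
    "sys_amp",        # systolic amplitude (signal units)
    "width_half",     # pulse width at half height (s)
    "rise_time",      # 10%-amplitude crossing -> peak (s)
    "decay_time",     # peak -> 10%-amplitude crossing (s)
    "area_norm",      # area under pulse / amplitude (s); gain-invariant
    "max_upslope",    # max of first derivative (signal units / s)
    "downslope_ratio",  # |min derivative| / max derivative; gain-invariant
]

FEATURE_COLUMNS = (
    ["ptt"]
    + [f"spec_{i}" for i in range(N_SPECTRAL_BANDS)]
    + MORPH_COLUMNS
    + ["heart_rate", "age", "sex_code", "height", "weight"]
)

_DEMOGRAPHIC_FIELDS = ("age", "sex_code", "height", "weight")


class InvalidBeatError(ValueError):
    """Raised when a beat cannot yield a valid feature (degenerate shape)."""


def compute_ptt(beat: Beat, fs: float) -> float:
    """Pulse transit time for one beat, in seconds.

    Defined as the lag from the R wave peak to the peak of the PPG first
    derivative.  The beat's PPG segment is anchored at the R-peak, so the
    PTT is simply the within-segment position of the derivative maximum.
    A derivative maximum on the segment boundary means the upstroke was not
    captured (or the segment is degenerate, e.g. a pure ramp) and the beat
    is flagged invalid.
    """
    seg = np.asarray(beat.ppg_segment, dtype=float)
    if len(seg) < 3:
        raise InvalidBeatError("segment too short for a derivative")
    deriv = np.gradient(seg)
    if np.ptp(deriv) <= 1e-9 * max(np.abs(deriv).max(), 1e-30):
        # Constant derivative (e.g. a pure ramp): no upstroke to anchor on.
        raise InvalidBeatError("PPG derivative is constant over the segment")
    i = int(np.argmax(deriv))
    if i == 0 or i == len(seg) - 1:
        raise InvalidBeatError("PPG derivative maximum at segment boundary")
    return i / fs


def ppg_spectrum_features(
    ppg_segment: np.ndarray,
    fs: float,
    n_bands: int = N_SPECTRAL_BANDS,
    band_range: tuple[float, float] = SPECTRAL_BAND_RANGE,
) -> np.ndarray:
    """Normalized band-integrated magnitude spectrum of a beat's PPG.

    The mean-removed segment's rFFT magnitudes are integrated over
    ``n_bands`` equal-width bands spanning the denoising passband and
    normalized to sum to one, making the feature invariant to PPG gain.
    """
    seg = np.asarray(ppg_segment, dtype=float)
    if len(seg) < 16:
        raise ValueError("segment must hold at least 16 samples")
    if not np.any(seg != seg[0]):
        raise ValueError("all-constant segment: normalization undefined")
    mag = np.abs(np.fft.rfft(seg - seg.mean()))
    freqs = np.fft.rfftfreq(len(seg), d=1.0 / fs)
    edges = np.linspace(band_range[0], band_range[1], n_bands + 1)
    out = np.empty(n_bands)
    for b in range(n_bands):
        in_band = (freqs >= edges[b]) & (freqs < edges[b + 1])
        out[b] = mag[in_band].sum()
    total = out.sum()
    if total <= 0:
        raise ValueError("no spectral mass inside the feature bands")
    return out / total


def _cross_time(seg: np.ndarray, level: float, start: int, stop: int, step: int, fs: float) -> Optional[float]:
    """Interpolated time (s, from segment start) of the first crossing of
    ``level`` scanning from ``start`` toward ``stop`` in direction ``step``."""
    i = start
    while i != stop:
        j = i + step
        a, b = seg[i], seg[j]
        if (a - level) * (b - level) <= 0 and a != b:
            frac = (level - a) / (b - a)
            return (i + step * frac) / fs if step > 0 else (i + step * frac) / fs
        i = j
    return None


def morphological_features(ppg_segment: np.ndarray, fs: float) -> np.ndarray:
    """Fixed ordered pulse-shape descriptors (see :data:`MORPH_COLUMNS`).

    The pulse baseline is the segment minimum; rise/decay are measured at
    the 10%-amplitude level and the width at 50%.  If the pulse has not
    decayed back to 10% by the end of the window, the window end stands in
    for the crossing (flagged situations are rare for QC-passed beats).
    """
    seg = np.asarray(ppg_segment, dtype=float)
    if not np.all(np.isfinite(seg)):
        raise ValueError("non-finite values in PPG segment")
    if len(seg) < 5:
        raise ValueError("segment too short for morphology")
    base = float(seg.min())
    peak_i = int(np.argmax(seg))
    amp = float(seg[peak_i] - base)
    if amp <= 0:
        raise ValueError("flat segment has no pulse")

    lo_level = base + 0.10 * amp
    half_level = base + 0.50 * amp

    t_rise_start = _cross_time(seg, lo_level, peak_i, 0, -1, fs)
    rise_time = peak_i / fs - t_rise_start if t_rise_start is not None else peak_i / fs

    t_decay_end = _cross_time(seg, lo_level, peak_i, len(seg) - 1, +1, fs)
    decay_time = (
        t_decay_end - peak_i / fs
        if t_decay_end is not None
        else (len(seg) - 1 - peak_i) / fs
    )

    t_half_l = _cross_time(seg, half_level, peak_i, 0, -1, fs)
    t_half_r = _cross_time(seg, half_level, peak_i, len(seg) - 1, +1, fs)
    left = t_half_l if t_half_l is not None else 0.0
    right = t_half_r if t_half_r is not None else (len(seg) - 1) / fs
    width_half = right - left

    area_norm = float(np.trapezoid(seg - base)) / fs / amp

    deriv = np.gradient(seg) * fs
    max_up = float(deriv.max())
    max_down = float(-deriv.min())
    down_ratio = max_down / max_up if max_up > 0 else 0.0

    return np.array(
        [amp, width_half, rise_time, decay_time, area_norm, max_up, down_ratio]
    )


def assemble_features(
    beats: Sequence[Beat],
    demographics: Union[SubjectProfile, Mapping[str, float]],
    heart_rate: float,
    fs: float,
) -> pd.DataFrame:
    """One feature row per selected beat, demographics broadcast to all.

    ``demographics`` may be a SubjectProfile or a mapping with keys
    ``age``, ``sex_code``, ``height``, ``weight``.  Raises if any
    demographic field is missing or any produced value is non-finite —
    NaNs must never leave this module for a QC-passed measurement.
    """
    if isinstance(demographics, SubjectProfile):
        demo = {
            "age": demographics.age,
            "sex_code": demographics.sex_code,
            "height": demographics.height,
            "weight": demographics.weight,
        }
    else:
        try:
            demo = {k: float(demographics[k]) for k in _DEMOGRAPHIC_FIELDS}
        except KeyError as e:
            raise ValueError(f"missing demographic field: {e.args[0]!r}") from e
    rows = []
    for beat in beats:
        ptt = compute_ptt(beat, fs)
        spec = ppg_spectrum_features(beat.ppg_segment, fs)
        morph = morphological_features(beat.ppg_segment, fs)
        rows.append(
            np.concatenate(
                (
                    [ptt],
                    spec,
                    morph,
                    [heart_rate, demo["age"], demo["sex_code"], demo["height"], demo["weight"]],
                )
            )
        )
    table = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    if not np.all(np.isfinite(table.to_numpy())):
        raise ValueError("non-finite feature produced")
    return table
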
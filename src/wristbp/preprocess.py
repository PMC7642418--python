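"""Denoising, beat detection/segmentation, and measurement quality gating.

The processing chain for one 24-s measurement is:

1. zero-phase Butterworth bandpass (PPG 0.8-11 Hz, ECG 5-30 Hz),
2. R-peak detection on the filtered ECG (derivative-energy detector with a
   0.25 s refractory period),
3. per-beat segmentation from each R-peak to 90% of the local RR interval,
4. beat quality scoring by pairwise correlation of the per-beat PPG
   waveforms (resampled to a common 100-point grid), selection of the 10
   best beats, and
5. a whole-measurement gate: if the minimum pairwise correlation across the
   measurement's beats falls below threshold, the measurement is excluded
   outright rather than patched — inconsistently shaped PPG usually means
   bad sensor contact, not a few bad beats.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .types import Beat, MeasurementQC

__all__ = [
    "PPG_BAND",
    "ECG_BAND",
    "DEFAULT_QUALITY_THRESHOLD",
    "bandpass",
    "detect_r_peaks",
    "segment_beats",
    "resample_segment",
    "beat_quality_matrix",
    "score_and_select_beats",
    "gate_measurement",
]

PPG_BAND = (0.8, 11.0)
ECG_BAND = (5.0, 30.0)
DEFAULT_QUALITY_THRESHOLD = 0.90
_RESAMPLE_POINTS = 100
_REFRACTORY_S = 0.25
_BEAT_WINDOW_FRAC = 0.90


def bandpass(x: np.ndarray, fs: float, low: float, high: float, order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth bandpass.

    ``order`` is the one-way filter order; the forward-backward pass doubles
    the effective order and cancels the phase delay, so symmetric features
    (R-peak, pulse upstroke) are not displaced.
    """
    if not (0 < low < high):
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    if high >= fs / 2:
        raise ValueError(f"high cutoff {high} Hz must lie below Nyquist {fs / 2} Hz")
    x = np.asarray(x, dtype=float)
    sos = sps.butter(order, (low, high), btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """R-peak indices on an already-bandpassed ECG.

    Derivative-energy detector: square the first difference, smooth with a
    150 ms moving window, pick peaks above an adaptive threshold with a
    0.25 s refractory period, then refine each candidate to the local ECG
    maximum (+-100 ms).  Returns a strictly increasing index array; empty if
    the signal carries no detectable beats.
    """
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) < int(0.5 * fs) or not np.any(ecg):
        return np.array([], dtype=int)
    energy = np.gradient(ecg) ** 2
    win = max(1, int(round(0.150 * fs)))
    smoothed = np.convolve(energy, np.ones(win) / win, mode="same")
    peak_level = np.percentile(smoothed, 99)
    if peak_level <= 0:
        return np.array([], dtype=int)
    height = 0.30 * peak_level
    distance = max(1, int(round(_REFRACTORY_S * fs)))
    cand, _ = sps.find_peaks(smoothed, height=height, distance=distance)
    if len(cand) == 0:
        return np.array([], dtype=int)
    # Refine to the true R maximum on the filtered ECG.
    half = int(round(0.100 * fs))
    refined = []
    for c in cand:
        lo, hi = max(0, c - half), min(len(ecg), c + half + 1)
        refined.append(lo + int(np.argmax(ecg[lo:hi])))
    refined = np.unique(refined)
    # Re-impose the refractory spacing after refinement.
    out = [int(refined[0])]
    for r in refined[1:]:
        if r - out[-1] >= distance:
            out.append(int(r))
        elif ecg[r] > ecg[out[-1]]:
            out[-1] = int(r)
    return np.asarray(out, dtype=int)


def segment_beats(
    ecg: np.ndarray,
    ppg: np.ndarray,
    r_peaks: Sequence[int],
    fs: float,
    window_frac: float = _BEAT_WINDOW_FRAC,
) -> list[Beat]:
    """Cut one Beat per R-peak, spanning the peak to ``window_frac`` of the
    local RR interval.  The final peak has no RR interval and is dropped.
    Returns an empty list for fewer than two peaks.
    """
    r_peaks = np.asarray(r_peaks, dtype=int)
    if len(r_peaks) < 2:
        return []
    beats: list[Beat] = []
    for k in range(len(r_peaks) - 1):
        start = r_peaks[k]
        rr = r_peaks[k + 1] - r_peaks[k]
        stop = start + max(2, int(round(window_frac * rr)))
        if stop > len(ppg):
            continue  # partial beat at the end of the record
        beats.append(
            Beat(
                index=k,
                r_peak_time=start / fs,
                ecg_segment=np.asarray(ecg[start:stop], dtype=float),
                ppg_segment=np.asarray(ppg[start:stop], dtype=float),
            )
        )
    return beats


def resample_segment(seg: np.ndarray, n_points: int = _RESAMPLE_POINTS) -> np.ndarray:
    """Linear resampling onto a fixed grid so unequal RR windows compare."""
    seg = np.asarray(seg, dtype=float)
    if len(seg) == n_points:
        return seg.copy()
    old = np.linspace(0.0, 1.0, len(seg))
    new = np.linspace(0.0, 1.0, n_points)
    return np.interp(new, old, seg)


def beat_quality_matrix(beats: Sequence[Beat]) -> np.ndarray:
    """Pairwise Pearson correlations between resampled per-beat PPG shapes.

    Beats are compared over their common time support (all segments
    truncated to the shortest, which is always anchored at the R-peak)
    before resampling to the fixed grid; otherwise ordinary RR-interval
    variability stretches identical pulses apart and healthy beats would
    decorrelate.  Degenerate (constant) segments correlate 0 with
    everything: a flat beat carries no pulse and must rank as poor quality,
    not undefined.
    """
    n = len(beats)
    L = min(len(b.ppg_segment) for b in beats)
    mat = np.stack([resample_segment(b.ppg_segment[:L]) for b in beats])
    sd = mat.std(axis=1)
    ok = sd > 1e-12
    corr = np.zeros((n, n))
    if ok.sum() >= 2:
        sub = np.corrcoef(mat[ok])
        idx = np.flatnonzero(ok)
        corr[np.ix_(idx, idx)] = sub
    np.fill_diagonal(corr, 1.0)
    return corr


def score_and_select_beats(
    beats: Sequence[Beat], n_select: int = 10
) -> tuple[list[Beat], MeasurementQC]:
    """Score every beat, pick the ``n_select`` best, summarize measurement QC.

    Each beat's quality is its mean pairwise correlation against all other
    beats.  The QC correlation summary (min/mean of the off-diagonal) is
    taken over *all* beats of the measurement: the exclusion rule screens
    the whole measurement, so one inconsistent beat anywhere is evidence of
    unstable contact.  ``passed`` is left for :func:`gate_measurement`.
    """
    beats = list(beats)
    if len(beats) == 0:
        raise ValueError("no beats to score")
    if len(beats) < n_select:
        qc = MeasurementQC(
            n_beats_detected=len(beats),
            n_beats_selected=0,
            pairwise_corr_min=float("nan"),
            pairwise_corr_mean=float("nan"),
            passed=False,
            reject_reason="too_few_beats",
        )
        return [], qc
    corr = beat_quality_matrix(beats)
    n = len(beats)
    for i, b in enumerate(beats):
        b.quality = float((corr[i].sum() - 1.0) / (n - 1)) if n > 1 else 1.0
    order = sorted(range(n), key=lambda i: (-beats[i].quality, i))
    chosen = sorted(order[:n_select])
    off = corr[~np.eye(n, dtype=bool)]
    qc = MeasurementQC(
        n_beats_detected=n,
        n_beats_selected=len(chosen),
        pairwise_corr_min=float(off.min()),
        pairwise_corr_mean=float(off.mean()),
        passed=False,
        reject_reason="not_evaluated",
    )
    return [beats[i] for i in chosen], qc


def gate_measurement(
    qc: MeasurementQC, threshold: float = DEFAULT_QUALITY_THRESHOLD
) -> bool:
    """Accept the measurement iff 10 beats were selected and the minimum
    pairwise correlation is at or above threshold (boundary passes).

    Mutates ``qc.passed`` / ``qc.reject_reason`` and returns the verdict.
    """
    if qc.n_beats_selected < 10 or qc.reject_reason == "too_few_beats":
        qc.passed = False
        qc.reject_reason = "too_few_beats"
        return False
    if not np.isfinite(qc.pairwise_corr_min) or qc.pairwise_corr_min < threshold:
        qc.passed = False
        qc.reject_reason = "low_correlation"
        return False
    qc.passed = True
    qc.reject_reason = "none"
    return True
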
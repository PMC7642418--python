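"""Synthetic ECG/PPG study generator.

Every downstream stage of the pipeline is exercised against data from this
module, which produces subjects, two-channel recordings with ground truth,
and full measurement-protocol sessions.

The physiological model is deliberately minimal but exact where it matters:

* ECG: a sum of Gaussian bumps per beat (P, QRS, T) with the R wave the
  tallest, so R-peak timing is unambiguous.
* PPG: one asymmetric pulse per beat, ``w(t) = (t/2tau)^2 exp(2 - t/tau)``
  (gamma-shaped rise, exponential decay).  Its first derivative has a single
  dominant maximum at ``t* = (2 - sqrt(2)) * tau`` after pulse onset, so the
  pulse can be placed to make the R-peak -> PPG-derivative-peak lag equal
  the prescribed pulse transit time exactly — a closed-form oracle for the
  feature extractor.
* PTT: ``ptt = ptt_intercept - ptt_slope * true_sbp`` plus small per-beat
  noise; PTT falls as systolic pressure rises.
* The pulse time constant ``tau`` shrinks weakly with diastolic pressure,
  giving the morphological features a DBP signal to learn from.
"""
from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .types import (
    CohortSpec,
    NoiseConfig,
    ProtocolEvent,
    Recording,
    RecordingTruth,
    SubjectProfile,
    SubjectSession,
)

__all__ = [
    "simulate_cohort",
    "simulate_recording",
    "corrupt_recording",
    "simulate_manual_reading",
    "simulate_protocol_session",
    "simulate_calibration_pairs",
    "simulate_subject_session",
    "simulate_feature_table",
    "pulse_template",
    "pulse_tau",
    "PULSE_DERIV_PEAK_FRAC",
]

# Derivative of t^2 exp(-t/tau) peaks at t = (2 - sqrt(2)) tau.
PULSE_DERIV_PEAK_FRAC = 2.0 - math.sqrt(2.0)

_CORRUPTION_MODES = ("flatline_segment", "noise_burst", "saturation")


def pulse_tau(true_dbp: float, tau0: float = 0.12, dbp_coupling: float = 0.002) -> float:
    """Pulse time constant (s): decays slightly as diastolic pressure rises."""
    return tau0 * (1.0 - dbp_coupling * (true_dbp - 70.0))


def pulse_template(t: np.ndarray, tau: float) -> np.ndarray:
    """Unit-amplitude PPG pulse, zero for t < 0, peak 1 at t = 2*tau."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = (tp / (2.0 * tau)) ** 2 * np.exp(2.0 - tp / tau)
    return out


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_cohort(spec: CohortSpec) -> list[SubjectProfile]:
    """Draw a reproducible cohort of subject profiles.

    SBP/DBP are bivariate normal with the spec's marginals and correlation,
    redrawn (rejection sampling) until SBP > DBP + 10 mmHg and the implied
    PTT is positive; this keeps the stated marginal means approximately.
    """
    rng = _rng(spec.seed)
    profiles: list[SubjectProfile] = []
    cov = np.array(
        [
            [spec.sbp_sd**2, spec.sbp_dbp_corr * spec.sbp_sd * spec.dbp_sd],
            [spec.sbp_dbp_corr * spec.sbp_sd * spec.dbp_sd, spec.dbp_sd**2],
        ]
    )
    mean = np.array([spec.sbp_mean, spec.dbp_mean])
    for i in range(spec.n_subjects):
        intercept = spec.ptt_intercept_mean + spec.ptt_intercept_sd * rng.standard_normal()
        for _ in range(10_000):
            sbp, dbp = rng.multivariate_normal(mean, cov)
            if (
                sbp > dbp + 10.0
                and dbp > 30.0
                and intercept - spec.ptt_slope * sbp > 0.05
            ):
                break
        else:  # pragma: no cover - pathological spec
            raise RuntimeError("cohort rejection sampling failed to converge")
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i:03d}",
                age=float(rng.uniform(*spec.age_range)),
                sex="M" if rng.random() < 0.5 else "F",
                height=float(np.clip(rng.normal(spec.height_mean, spec.height_sd), 140, 200)),
                weight=float(np.clip(rng.normal(spec.weight_mean, spec.weight_sd), 35, 140)),
                true_sbp=float(sbp),
                true_dbp=float(dbp),
                heart_rate=float(np.clip(rng.normal(spec.heart_rate_mean, spec.heart_rate_sd), 45, 120)),
                ptt_intercept=float(intercept),
                ptt_slope=spec.ptt_slope,
                beat_jitter_sd=spec.beat_jitter_sd,
            )
        )
    return profiles


def _gaussian_bump(t: np.ndarray, center: float, sd: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - center) / sd) ** 2)


def _bad_contact_gain(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Slow random gain flicker in [0.05, 1], emulating unstable contact."""
    raw = rng.standard_normal(n)
    sos = sps.butter(2, 1.0, btype="low", fs=fs, output="sos")
    slow = sps.sosfiltfilt(sos, raw)
    slow = slow / (np.std(slow) + 1e-12) * 0.35
    return np.clip(0.55 + slow, 0.05, 1.0)


def simulate_recording(
    profile: SubjectProfile,
    fs: float = 250.0,
    duration: float = 24.0,
    noise: Optional[NoiseConfig] = None,
    seed: int | np.random.SeedSequence = 0,
    ptt_noise_sd: float = 0.002,
    sbp_override: Optional[float] = None,
) -> Recording:
    """Simulate one two-channel measurement with ground truth attached.

    ``sbp_override`` lets a caller impose the hemodynamic state sensed by
    the watch for this measurement (defaults to the subject's true SBP).
    """
    if fs < 125.0:
        raise ValueError("fs must be >= 125 Hz")
    if duration <= 2 * 60.0 / profile.heart_rate:
        raise ValueError("duration must span more than 2 beats")
    noise = noise if noise is not None else NoiseConfig()
    rng = _rng(seed)
    sbp_for_ptt = profile.true_sbp if sbp_override is None else sbp_override
    base_ptt = profile.ptt_intercept - profile.ptt_slope * sbp_for_ptt
    if base_ptt <= 0:
        raise ValueError(f"implied PTT {base_ptt:.4f} s is not positive")

    n = int(round(fs * duration))
    t = np.arange(n) / fs
    mean_rr = 60.0 / profile.heart_rate
    tau = pulse_tau(profile.true_dbp)

    # Beat train with jittered RR intervals.
    r_times: list[float] = []
    tk = 0.5 + rng.uniform(0.0, mean_rr / 4)
    while tk < duration + 1.0:
        r_times.append(tk)
        tk += mean_rr + profile.beat_jitter_sd * rng.standard_normal()
    r_arr = np.array(r_times)

    ecg = np.zeros(n)
    ppg = np.zeros(n)
    ptts = np.empty(len(r_arr))
    for k, rt in enumerate(r_arr):
        ecg += _gaussian_bump(t, rt, 0.012, 1.0)  # QRS (R wave)
        ecg += _gaussian_bump(t, rt - 0.18, 0.025, 0.15)  # P
        ecg += _gaussian_bump(t, rt + 0.22, 0.060, 0.30)  # T
        ptt_k = base_ptt + ptt_noise_sd * rng.standard_normal()
        ptts[k] = ptt_k
        onset = rt + ptt_k - PULSE_DERIV_PEAK_FRAC * tau
        amp = 1.0 + 0.05 * rng.standard_normal()
        ppg += amp * pulse_template(t - onset, tau)

    # Corruption per NoiseConfig.
    if noise.baseline_wander_amp > 0 and noise.baseline_wander_freq > 0:
        phase = rng.uniform(0, 2 * np.pi)
        ppg += noise.baseline_wander_amp * np.sin(
            2 * np.pi * noise.baseline_wander_freq * t + phase
        )
    if noise.powerline_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        ecg += noise.powerline_amp * np.sin(2 * np.pi * noise.powerline_freq * t + phase)
        ppg += 0.5 * noise.powerline_amp * np.sin(
            2 * np.pi * noise.powerline_freq * t + phase
        )
    if noise.white_noise_sd > 0:
        ecg += noise.white_noise_sd * rng.standard_normal(n)
        ppg += noise.white_noise_sd * rng.standard_normal(n)
    if noise.bad_contact:
        ppg *= _bad_contact_gain(n, fs, rng)
        n_bursts = rng.poisson(25)
        for _ in range(n_bursts):
            b0 = rng.integers(0, n)
            blen = int(rng.uniform(0.2, 0.6) * fs)
            sl = slice(b0, min(n, b0 + blen))
            ppg[sl] += rng.standard_normal(sl.stop - sl.start) * 1.0

    keep = r_arr < duration
    truth = RecordingTruth(
        r_peak_times=r_arr[keep],
        ptt=ptts[keep],
        true_sbp=profile.true_sbp,
        true_dbp=profile.true_dbp,
    )
    return Recording(
        subject_id=profile.subject_id,
        fs=fs,
        duration=duration,
        ecg=ecg,
        ppg=ppg,
        truth=truth,
    )


def corrupt_recording(
    rec: Recording,
    mode: str,
    seed: int = 0,
    span_frac: float = 0.3,
    start_frac: Optional[float] = None,
) -> Recording:
    """Apply a contiguous-span corruption to the PPG channel (copy returned).

    Modes: ``flatline_segment`` (sensor dropout), ``noise_burst`` (motion
    artifact), ``saturation`` (rail clipping).  ``span_frac = 0`` returns an
    identical copy.  Ground truth is retained.
    """
    if mode not in _CORRUPTION_MODES:
        raise ValueError(f"unknown corruption mode {mode!r}; choose from {_CORRUPTION_MODES}")
    out = rec.copy()
    n = out.n_samples
    span = int(round(span_frac * n))
    if span <= 0:
        return out
    rng = _rng(seed)
    start = (
        int(round(start_frac * n))
        if start_frac is not None
        else int(rng.integers(0, max(1, n - span)))
    )
    sl = slice(start, min(n, start + span))
    if mode == "flatline_segment":
        out.ppg[sl] = out.ppg[sl.start]
    elif mode == "noise_burst":
        out.ppg[sl] += 3.0 * rng.standard_normal(sl.stop - sl.start)
    elif mode == "saturation":
        ceiling = float(np.max(out.ppg))
        out.ppg[sl] = ceiling
    return out


def simulate_manual_reading(
    rng: np.random.Generator,
    true_sbp: float,
    true_dbp: float,
    observer_sd: float = 2.0,
    max_observer_diff: float = 4.0,
) -> tuple[float, float]:
    """One auscultatory reading by two observers.

    Each observer errs i.i.d. N(0, observer_sd); if they disagree by more
    than ``max_observer_diff`` mmHg both re-measure (redraw).  The reported
    value is their mean.  Because (e1+e2) is independent of (e1-e2), the
    reported error has sd exactly observer_sd/sqrt(2) regardless of the
    agreement rule.
    """

    def one(truth: float) -> float:
        if observer_sd == 0.0:
            return truth
        while True:
            e1, e2 = observer_sd * rng.standard_normal(2)
            if abs(e1 - e2) <= max_observer_diff:
                return truth + 0.5 * (e1 + e2)

    return one(true_sbp), one(true_dbp)


def _watch_event(
    profile: SubjectProfile,
    t_s: float,
    rng: np.random.Generator,
    fs: float,
    duration: float,
    noise: NoiseConfig,
    ptt_noise_sd: float,
) -> ProtocolEvent:
    rec = simulate_recording(
        profile,
        fs=fs,
        duration=duration,
        noise=noise,
        seed=int(rng.integers(0, 2**31 - 1)),
        ptt_noise_sd=ptt_noise_sd,
    )
    return ProtocolEvent(kind="watch", t_s=t_s, recording=rec)


def simulate_protocol_session(
    profile: SubjectProfile,
    seed: int | np.random.SeedSequence = 0,
    fs: float = 250.0,
    duration: float = 24.0,
    noise: Optional[NoiseConfig] = None,
    observer_sd: float = 2.0,
    t0: float = 0.0,
    ptt_noise_sd: float = 0.002,
) -> list[ProtocolEvent]:
    """The 7-measurement alternating sequence M,W,M,W,M,W,M (BP1..BP7).

    Four manual sphygmomanometer readings interleaved with three watch
    measurements, strictly increasing timestamps ~1 min apart.  Manual
    readings are true BP plus two-observer noise; watch events carry a
    fresh simulated Recording.
    """
    noise = noise if noise is not None else NoiseConfig()
    rng = _rng(seed)
    events: list[ProtocolEvent] = []
    t_s = t0
    for i in range(7):
        if i % 2 == 0:
            sbp, dbp = simulate_manual_reading(
                rng, profile.true_sbp, profile.true_dbp, observer_sd
            )
            events.append(ProtocolEvent(kind="manual", t_s=t_s, sbp=sbp, dbp=dbp))
        else:
            events.append(
                _watch_event(profile, t_s, rng, fs, duration, noise, ptt_noise_sd)
            )
        t_s += float(rng.uniform(50.0, 70.0))
    return events


def simulate_calibration_pairs(
    profile: SubjectProfile,
    seed: int | np.random.SeedSequence = 0,
    n_pairs: int = 3,
    fs: float = 250.0,
    duration: float = 24.0,
    noise: Optional[NoiseConfig] = None,
    observer_sd: float = 2.0,
    t0: float = 0.0,
    ptt_noise_sd: float = 0.002,
) -> list[tuple[ProtocolEvent, ProtocolEvent]]:
    """(manual, watch) pairs for per-subject calibration (default 3)."""
    noise = noise if noise is not None else NoiseConfig()
    rng = _rng(seed)
    pairs = []
    t_s = t0
    for _ in range(n_pairs):
        sbp, dbp = simulate_manual_reading(
            rng, profile.true_sbp, profile.true_dbp, observer_sd
        )
        manual = ProtocolEvent(kind="manual", t_s=t_s, sbp=sbp, dbp=dbp)
        t_s += float(rng.uniform(50.0, 70.0))
        watch = _watch_event(profile, t_s, rng, fs, duration, noise, ptt_noise_sd)
        t_s += float(rng.uniform(50.0, 70.0))
        pairs.append((manual, watch))
    return pairs


def simulate_subject_session(
    profile: SubjectProfile,
    seed: int | np.random.SeedSequence = 0,
    n_calibration_pairs: int = 3,
    fs: float = 250.0,
    duration: float = 24.0,
    noise: Optional[NoiseConfig] = None,
    observer_sd: float = 2.0,
    ptt_noise_sd: float = 0.002,
) -> SubjectSession:
    """Full visit: calibration pairs, a 5-10 min gap, then the 7-event run."""
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    cal_seed, primary_seed = ss.spawn(2)
    pairs = simulate_calibration_pairs(
        profile, cal_seed, n_calibration_pairs, fs, duration, noise, observer_sd,
        t0=0.0, ptt_noise_sd=ptt_noise_sd,
    )
    gap_start = pairs[-1][1].t_s + 420.0  # ~7 min after calibration
    events = simulate_protocol_session(
        profile, primary_seed, fs, duration, noise, observer_sd,
        t0=gap_start, ptt_noise_sd=ptt_noise_sd,
    )
    return SubjectSession(profile=profile, calibration=pairs, events=events)


def simulate_feature_table(
    profiles: Sequence[SubjectProfile],
    n_measurements: int = 3,
    beats_per_measurement: int = 10,
    seed: int = 0,
    ptt_noise_sd: float = 0.002,
    observer_sd: float = 2.0,
    feature_noise_sd: float = 0.01,
    fs: float = 250.0,
):
    """Per-beat feature table generated directly in feature space.

    A fast stand-in for the full signal chain used by model-level studies:
    PTT, spectral and morphological features are computed from the same
    pulse template the signal simulator uses (via the real extractors on a
    clean per-beat pulse), with small i.i.d. feature noise added.  Returns
    ``(X, y, groups)`` — features, per-beat reference SBP/DBP targets, and
    subject ids for grouped cross-validation.
    """
    import pandas as pd

    from .features import (
        FEATURE_COLUMNS,
        morphological_features,
        ppg_spectrum_features,
    )

    rng = _rng(seed)
    rows, targets, groups = [], [], []
    for prof in profiles:
        tau = pulse_tau(prof.true_dbp)
        tseg = np.arange(int(round(0.85 * fs))) / fs
        base_pulse = pulse_template(tseg - 0.02, tau)
        spec_base = ppg_spectrum_features(base_pulse, fs)
        morph_base = morphological_features(base_pulse, fs)
        for _ in range(n_measurements):
            man_sbp, man_dbp = simulate_manual_reading(
                rng, prof.true_sbp, prof.true_dbp, observer_sd
            )
            for _ in range(beats_per_measurement):
                ptt = prof.ptt() + ptt_noise_sd * rng.standard_normal()
                spec = np.abs(
                    spec_base + feature_noise_sd * rng.standard_normal(len(spec_base))
                )
                spec = spec / spec.sum()
                morph = morph_base * (
                    1.0 + feature_noise_sd * rng.standard_normal(len(morph_base))
                )
                rows.append(
                    np.concatenate(
                        (
                            [ptt],
                            spec,
                            morph,
                            [
                                prof.heart_rate,
                                prof.age,
                                prof.sex_code,
                                prof.height,
                                prof.weight,
                            ],
                        )
                    )
                )
                targets.append((man_sbp, man_dbp))
                groups.append(prof.subject_id)
    X = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    y = pd.DataFrame(targets, columns=["sbp", "dbp"])
    return X, y, np.array(groups)
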
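"""Core domain containers shared across the pipeline.

Numeric containers are plain dataclasses holding numpy arrays; validation
happens at construction so downstream code can assume the invariants.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "SubjectProfile",
    "NoiseConfig",
    "CohortSpec",
    "RecordingTruth",
    "Recording",
    "Beat",
    "MeasurementQC",
]


@dataclass(frozen=True)
class SubjectProfile:
    """A synthetic subject: demographics plus the ground-truth hemodynamics.

    The pulse transit time (PTT) of every beat is generated as
    ``ptt = ptt_intercept - ptt_slope * true_sbp`` (seconds), i.e. PTT falls
    as systolic pressure rises.  ``ptt_intercept`` varies slightly between
    subjects, which is exactly the subject-specific offset that per-subject
    calibration exists to remove.
    """

    subject_id: str
    age: float
    sex: str  # "M" or "F"
    height: float  # cm
    weight: float  # kg
    true_sbp: float  # mmHg
    true_dbp: float  # mmHg
    heart_rate: float  # beats/min
    ptt_intercept: float = 0.40  # seconds
    ptt_slope: float = 0.001  # seconds per mmHg, positive
    beat_jitter_sd: float = 0.02  # seconds
    device_bias: float = 0.0  # mmHg, systematic watch bias (0 = unbiased)

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if not (self.true_sbp > self.true_dbp > 0):
            raise ValueError(
                f"need true_sbp > true_dbp > 0, got {self.true_sbp}/{self.true_dbp}"
            )
        if not (40 <= self.heart_rate <= 180):
            raise ValueError(f"heart_rate {self.heart_rate} outside [40, 180]")
        if self.ptt_slope <= 0:
            raise ValueError("ptt_slope must be positive")
        if self.ptt() <= 0:
            raise ValueError(
                f"implied PTT {self.ptt():.4f} s is not positive for "
                f"SBP {self.true_sbp} mmHg"
            )

    def ptt(self, sbp: Optional[float] = None) -> float:
        """Ground-truth PTT in seconds at the given (default: subject's) SBP."""
        s = self.true_sbp if sbp is None else sbp
        return self.ptt_intercept - self.ptt_slope * s

    @property
    def sex_code(self) -> int:
        return 1 if self.sex == "M" else 0


@dataclass(frozen=True)
class NoiseConfig:
    """Additive corruption applied to the simulated channels.

    Amplitudes are in signal units (the clean PPG pulse has unit amplitude,
    the ECG R wave has unit amplitude).  ``bad_contact`` models unstable
    optical contact at the wrist: a slow random gain flicker plus scattered
    noise bursts on the PPG, distorting most beats in the recording.
    """

    white_noise_sd: float = 0.02
    baseline_wander_amp: float = 0.10
    baseline_wander_freq: float = 0.25  # Hz, must stay below 0.8 Hz
    powerline_amp: float = 0.02
    powerline_freq: float = 50.0  # Hz, 45-65
    bad_contact: bool = False

    def __post_init__(self) -> None:
        for name in ("white_noise_sd", "baseline_wander_amp", "powerline_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.baseline_wander_freq < 0.8):
            raise ValueError("baseline_wander_freq must lie below 0.8 Hz")
        if not (45.0 <= self.powerline_freq <= 65.0):
            raise ValueError("powerline_freq must lie within 45-65 Hz")

    @classmethod
    def clean(cls) -> "NoiseConfig":
        """Noise-free configuration (for oracle round-trip checks)."""
        return cls(white_noise_sd=0.0, baseline_wander_amp=0.0, powerline_amp=0.0)


@dataclass(frozen=True)
class CohortSpec:
    """Distribution parameters for a simulated study cohort.

    Defaults reproduce the published study population: SBP 129.6 +/- 23.6,
    DBP 69.5 +/- 12.9 mmHg, ages spanning young adults to the elderly,
    height 162.2 +/- 8.6 cm, weight 67.5 +/- 12.3 kg.
    """

    n_subjects: int
    sbp_mean: float = 129.6
    sbp_sd: float = 23.6
    dbp_mean: float = 69.5
    dbp_sd: float = 12.9
    sbp_dbp_corr: float = 0.6
    age_range: tuple[float, float] = (20.0, 90.0)
    height_mean: float = 162.2
    height_sd: float = 8.6
    weight_mean: float = 67.5
    weight_sd: float = 12.3
    heart_rate_mean: float = 70.0
    heart_rate_sd: float = 8.0
    ptt_intercept_mean: float = 0.40
    ptt_intercept_sd: float = 0.005
    ptt_slope: float = 0.001
    beat_jitter_sd: float = 0.02
    noise_cfg: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("sbp_sd", "dbp_sd", "height_sd", "weight_sd",
                     "heart_rate_sd", "ptt_intercept_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (-1.0 < self.sbp_dbp_corr < 1.0):
            raise ValueError("sbp_dbp_corr must lie in (-1, 1)")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")


@dataclass(frozen=True)
class RecordingTruth:
    """Ground-truth annotations carried by simulated recordings."""

    r_peak_times: np.ndarray  # seconds
    ptt: np.ndarray  # seconds, one entry per beat
    true_sbp: float
    true_dbp: float


@dataclass
class Recording:
    """One two-channel (ECG, PPG) measurement, uniformly sampled."""

    subject_id: str
    fs: float  # Hz
    duration: float  # seconds
    ecg: np.ndarray
    ppg: np.ndarray
    truth: Optional[RecordingTruth] = None

    def __post_init__(self) -> None:
        n = int(round(self.fs * self.duration))
        if len(self.ecg) != n or len(self.ppg) != n:
            raise ValueError(
                f"channel length must equal round(fs*duration)={n}, "
                f"got ecg={len(self.ecg)}, ppg={len(self.ppg)}"
            )
        if self.fs <= 120.0:
            raise ValueError("fs must exceed 2x the highest filter cutoff (60 Hz)")

    @property
    def n_samples(self) -> int:
        return len(self.ecg)

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def copy(self) -> "Recording":
        return replace(
            self, ecg=self.ecg.copy(), ppg=self.ppg.copy(), truth=self.truth
        )


@dataclass
class Beat:
    """A per-heartbeat ECG+PPG segment anchored at an R-peak."""

    index: int
    r_peak_time: float  # seconds
    ecg_segment: np.ndarray
    ppg_segment: np.ndarray
    quality: float = float("nan")  # mean pairwise PPG correlation, in [-1, 1]

    def __post_init__(self) -> None:
        if len(self.ecg_segment) == 0 or len(self.ppg_segment) == 0:
            raise ValueError("beat segments must be non-empty")


@dataclass
class MeasurementQC:
    """Quality-control record for one 24-s measurement."""

    n_beats_detected: int
    n_beats_selected: int
    pairwise_corr_min: float
    pairwise_corr_mean: float
    passed: bool = False
    reject_reason: str = "not_evaluated"  # none|too_few_beats|low_correlation


@dataclass
class ProtocolEvent:
    """One timed event of a measurement session.

    ``kind`` is "manual" (sphygmomanometer reading, sbp/dbp filled) or
    "watch" (device measurement; carries a Recording, and sbp/dbp once an
    estimate has been produced).
    """

    kind: str  # "manual" | "watch"
    t_s: float
    sbp: Optional[float] = None
    dbp: Optional[float] = None
    recording: Optional[Recording] = None

    def __post_init__(self) -> None:
        if self.kind not in ("manual", "watch"):
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class SubjectSession:
    """A subject's full visit: calibration pairs then the 7-event sequence.

    ``calibration`` holds (manual, watch) event pairs; ``events`` is the
    alternating M,W,M,W,M,W,M primary sequence.
    """

    profile: SubjectProfile
    calibration: list[tuple[ProtocolEvent, ProtocolEvent]]
    events: list[ProtocolEvent]
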
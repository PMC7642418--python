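"""Shared fixtures: canonical subjects, recordings, and processed beats."""
from __future__ import annotations

import numpy as np
import pytest

from wristbp.preprocess import (
    ECG_BAND,
    PPG_BAND,
    bandpass,
    detect_r_peaks,
    segment_beats,
)
from wristbp.sim import simulate_recording
from wristbp.types import NoiseConfig, SubjectProfile


@pytest.fixture(scope="session")
def default_profile() -> SubjectProfile:
    return SubjectProfile(
        subject_id="S000", age=50.0, sex="M", height=165.0, weight=70.0,
        true_sbp=130.0, true_dbp=80.0, heart_rate=60.0,
    )


@pytest.fixture(scope="session")
def clean_recording(default_profile):
    return simulate_recording(
        default_profile, noise=NoiseConfig.clean(), seed=42
    )


@pytest.fixture(scope="session")
def nominal_recording(default_profile):
    return simulate_recording(default_profile, noise=NoiseConfig(), seed=42)


def preprocess_chain(rec):
    """Filter both channels, detect R-peaks, and segment beats."""
    ecg_f = bandpass(rec.ecg, rec.fs, *ECG_BAND)
    ppg_f = bandpass(rec.ppg, rec.fs, *PPG_BAND)
    peaks = detect_r_peaks(ecg_f, rec.fs)
    beats = segment_beats(ecg_f, ppg_f, peaks, rec.fs)
    return ecg_f, ppg_f, peaks, beats


@pytest.fixture(scope="session")
def clean_beats(clean_recording):
    return preprocess_chain(clean_recording)[3]
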
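"""File formats and run configuration.

Everything on disk is plain text: recordings are CSV (``time_s,ecg,ppg``),
session manifests / models / calibration terms / reports are JSON.  The
run configuration is a pydantic model whose defaults are the package's
declared design choices; an expanded copy is written next to every output
for provenance.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .types import (
    NoiseConfig,
    ProtocolEvent,
    Recording,
    RecordingTruth,
    SubjectProfile,
    SubjectSession,
)

__all__ = [
    "RecordingFormatError",
    "read_recording",
    "write_recording",
    "RunConfig",
    "save_manifest",
    "load_manifest",
]

_REL_TOL = 1e-6


class RecordingFormatError(ValueError):
    """Malformed recording file (missing columns, ragged sampling...)."""


def write_recording(rec: Recording, path) -> None:
    """Write a recording as CSV with columns ``time_s, ecg, ppg``."""
    df = pd.DataFrame({"time_s": rec.time, "ecg": rec.ecg, "ppg": rec.ppg})
    df.to_csv(path, index=False, float_format="%.9g")


def read_recording(path, subject_id: str = "") -> Recording:
    """Read a CSV recording, checking the header and sampling uniformity.

    The time column must be uniform to within 1e-6 relative tolerance; the
    first offending row is named in the error.
    """
    df = pd.read_csv(path)
    for col in ("time_s", "ecg", "ppg"):
        if col not in df.columns:
            raise RecordingFormatError(f"{path}: missing column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise RecordingFormatError(f"{path}: fewer than 2 samples")
    dt = np.diff(t)
    dt0 = dt[0]
    if dt0 <= 0:
        raise RecordingFormatError(f"{path}: non-increasing time at row 2")
    bad = np.flatnonzero(np.abs(dt - dt0) > _REL_TOL * max(abs(dt0), 1e-12))
    if len(bad):
        # bad[0] indexes the first offending interval; the sample ending it
        # sits at data row bad[0]+1, i.e. file line bad[0]+3 (header, 1-based).
        raise RecordingFormatError(
            f"{path}: non-uniform sampling at row {int(bad[0]) + 3}"
        )
    fs = 1.0 / dt0
    return Recording(
        subject_id=subject_id,
        fs=fs,
        duration=len(t) / fs,
        ecg=df["ecg"].to_numpy(dtype=float),
        ppg=df["ppg"].to_numpy(dtype=float),
    )


# --------------------------------------------------------------------------
# Run configuration


class FilterConfig(BaseModel):
    ppg_band: tuple[float, float] = (0.8, 11.0)
    ecg_band: tuple[float, float] = (5.0, 30.0)
    order: int = 4


class ScreenConfig(BaseModel):
    bottleneck_dim: Optional[int] = None  # None -> ceil(d/2)
    seed: int = 0


class TrainSearchConfig(BaseModel):
    layer_options: tuple[int, ...] = (1, 2, 3)
    node_options: tuple[int, ...] = (8, 16, 32)
    activation_options: tuple[str, ...] = ("relu", "tanh")
    cv_folds: int = 5
    max_epochs: int = 500
    learning_rate: float = 0.01
    seed: int = 0


class RunConfig(BaseModel):
    """Full pipeline configuration; defaults are the declared design choices."""

    data_dir: str = "."
    output_dir: str = "out"
    fs: float = 250.0
    duration_s: float = 24.0
    filters: FilterConfig = Field(default_factory=FilterConfig)
    quality_threshold: float = 0.90
    n_beats: int = 10
    screen: ScreenConfig = Field(default_factory=ScreenConfig)
    train: TrainSearchConfig = Field(default_factory=TrainSearchConfig)
    calibration_ridge_lambda: float = 2000.0
    device_noise_sd: float = 6.0
    observer_sd: float = 2.0
    seed: int = 0

    def to_json(self) -> str:
        return self.model_dump_json(indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls.model_validate_json(text)


# --------------------------------------------------------------------------
# Session manifests


def _event_to_dict(ev: ProtocolEvent, rec_path: Optional[str]) -> dict:
    return {
        "kind": ev.kind,
        "t_s": ev.t_s,
        "sbp": ev.sbp,
        "dbp": ev.dbp,
        "recording": rec_path,
    }


def save_manifest(session: SubjectSession, directory) -> Path:
    """Persist a session: one JSON manifest plus one CSV per recording.

    Returns the manifest path.  Recordings are written relative to the
    manifest's directory.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    prof = session.profile
    rec_counter = 0

    def dump_event(ev: ProtocolEvent) -> dict:
        nonlocal rec_counter
        rec_path = None
        if ev.recording is not None:
            rec_path = f"{prof.subject_id}_rec{rec_counter:02d}.csv"
            write_recording(ev.recording, directory / rec_path)
            rec_counter += 1
        return _event_to_dict(ev, rec_path)

    manifest = {
        "schema_version": 1,
        "subject": {
            "subject_id": prof.subject_id,
            "age": prof.age,
            "sex": prof.sex,
            "height": prof.height,
            "weight": prof.weight,
        },
        "truth": {
            "true_sbp": prof.true_sbp,
            "true_dbp": prof.true_dbp,
            "heart_rate": prof.heart_rate,
        },
        "calibration": [
            {"manual": dump_event(m), "watch": dump_event(w)}
            for m, w in session.calibration
        ],
        "events": [dump_event(e) for e in session.events],
    }
    path = directory / f"{prof.subject_id}_session.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def _event_from_dict(d: dict, directory: Path, subject_id: str) -> ProtocolEvent:
    rec = None
    if d.get("recording"):
        rec = read_recording(directory / d["recording"], subject_id=subject_id)
    return ProtocolEvent(
        kind=d["kind"], t_s=d["t_s"], sbp=d.get("sbp"), dbp=d.get("dbp"), recording=rec
    )


def load_manifest(path) -> SubjectSession:
    """Load a session manifest and its referenced recordings."""
    path = Path(path)
    d = json.loads(path.read_text())
    s = d["subject"]
    truth = d.get("truth") or {}
    profile = SubjectProfile(
        subject_id=s["subject_id"],
        age=s["age"],
        sex=s["sex"],
        height=s["height"],
        weight=s["weight"],
        true_sbp=truth.get("true_sbp", 120.0),
        true_dbp=truth.get("true_dbp", 80.0),
        heart_rate=truth.get("heart_rate", 70.0),
    )
    directory = path.parent
    sid = profile.subject_id
    calibration = [
        (
            _event_from_dict(p["manual"], directory, sid),
            _event_from_dict(p["watch"], directory, sid),
        )
        for p in d.get("calibration", [])
    ]
    events = [_event_from_dict(e, directory, sid) for e in d.get("events", [])]
    return SubjectSession(profile=profile, calibration=calibration, events=events)
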
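"""On-disk formats: gaze CSV, cohort CSV, profile CSV, config JSON.

Gaze CSV schema (one file per task run): columns ``t_s, x_deg, y_deg,
valid`` with timestamps in seconds, positions in degrees of visual
angle, validity 0/1.  Schema violations are rejected with the
offending line number.  Tables are CSV; nested model reports are JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import EmptyRecordingError, GazeRecording

GAZE_COLUMNS = ("t_s", "x_deg", "y_deg", "valid")


class GazeParseError(ValueError):
    pass


def write_gaze_csv(rec: GazeRecording, path) -> None:
    df = pd.DataFrame({
        "t_s": rec.t,
        "x_deg": rec.x,
        "y_deg": rec.y,
        "valid": rec.valid.astype(int),
    })
    df.to_csv(path, index=False, float_format="%.9g")


def read_gaze_csv(path, rate_hz: float = 60.0,
                  participant_id: str = "", task_id: str = "") -> GazeRecording:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyRecordingError(f"{path}: empty gaze file") from None
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise GazeParseError(f"{path}: missing column(s) {missing}")
    if len(df) == 0:
        raise EmptyRecordingError(f"{path}: no samples")
    t = df["t_s"].to_numpy(float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        # +2: one for the diff offset, one for the header line
        raise GazeParseError(
            f"{path}: timestamps not strictly increasing at line {bad[0] + 3}")
    return GazeRecording(
        t=t, x=df["x_deg"].to_numpy(float), y=df["y_deg"].to_numpy(float),
        valid=df["valid"].to_numpy().astype(bool), rate_hz=rate_hz,
        participant_id=participant_id, task_id=task_id)


from .tasks import (AntisaccadeTrial, FixationTrial, ProsaccadeTrial,
                    PursuitTrial, TaskSpec)

_TRIAL_TYPES = {
    "fixation": FixationTrial,
    "prosaccade": ProsaccadeTrial,
    "antisaccade": AntisaccadeTrial,
    "pursuit": PursuitTrial,
}


def write_taskspec_json(spec: TaskSpec, path) -> None:
    """Stimulus-timeline sidecar for one task run."""
    payload = {
        "task_kind": spec.task_kind,
        "duration_s": spec.duration_s,
        "trials": [dataclasses.asdict(tr) for tr in spec.trials],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_taskspec_json(path) -> TaskSpec:
    data = json.loads(Path(path).read_text())
    kind = data["task_kind"]
    if kind not in _TRIAL_TYPES:
        raise ValueError(f"{path}: unknown task kind {kind!r}")
    cls = _TRIAL_TYPES[kind]
    trials = tuple(cls(**tr) for tr in data["trials"])
    return TaskSpec(kind, trials, duration_s=data["duration_s"])


COHORT_COLUMNS = ("participant_id", "age", "edss", "sdmt", "ravlt", "bvmtr",
                  "t25fw", "hpt9")


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: cohort table missing column(s) {missing}")
    return df


def write_profiles_csv(profiles: pd.DataFrame, path) -> None:
    profiles.to_csv(path, index=True, index_label="participant_id")


def read_profiles_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="participant_id")


@dataclass
class PipelineConfig:
    """End-to-end run settings; round-trips through JSON unchanged."""

    n_participants: int = 60
    seed: int = 0
    output_dir: str = "results"
    alpha: float = 0.05
    bh_family: str = "per_outcome"
    detection: dict = field(default_factory=dict)    # DetectionSettings overrides
    search: dict = field(default_factory=dict)       # SearchSettings overrides
    cohort: dict = field(default_factory=dict)       # SyntheticCohortConfig overrides
    include_time_to_target: bool = True

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def load_config(path) -> PipelineConfig:
    return PipelineConfig.from_json(Path(path).read_text())


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(config.to_json())
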
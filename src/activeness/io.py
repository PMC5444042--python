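"""CSV/JSON/YAML readers and writers for every pipeline artifact.

Interchange formats (all plain text):

* heart-rate log CSV: ``timestamp`` (ISO-8601), ``bpm``;
* episode CSV: ``start``, ``end``, ``total_calories_kcal``, ``total_steps``;
* processed series CSV: ``timestamp``, ``heart_rate_bpm``, ``calories_kcal``,
  ``steps``, plus a ``<path>.json`` sidecar recording the transform state
  and the normalization bounds, so a reader always knows which scale the
  numbers are on;
* run configuration as YAML.

Timestamps are timezone-naive local time throughout: daily averages and
circadian structure are clock-time concepts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocessing import (
    CHANNELS,
    ActivenessSeries,
    NormalizationSpec,
    TransformState,
)
from .synthetic import ActivityEpisode, RawHeartRateLog, UserProfile

logger = logging.getLogger(__name__)

__all__ = [
    "write_heart_rate_csv",
    "read_heart_rate_log",
    "write_episodes_csv",
    "read_episodes",
    "read_raw_logs",
    "write_series",
    "read_series",
    "RunConfig",
]

HR_COLUMNS = ["timestamp", "bpm"]
EPISODE_COLUMNS = ["start", "end", "total_calories_kcal", "total_steps"]
SERIES_COLUMNS = ["timestamp", "heart_rate_bpm", "calories_kcal", "steps"]


def _require_columns(df: pd.DataFrame, required: list, path) -> None:
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")


def write_heart_rate_csv(log: RawHeartRateLog, path) -> None:
    pd.DataFrame(
        {"timestamp": log.times.strftime("%Y-%m-%dT%H:%M:%S"), "bpm": log.bpm}
    ).to_csv(path, index=False, float_format="%.17g")


def read_heart_rate_log(path) -> RawHeartRateLog:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, HR_COLUMNS, path)
    try:
        times = pd.DatetimeIndex(pd.to_datetime(df["timestamp"], format="ISO8601"))
        bpm = df["bpm"].astype(float).to_numpy()
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: malformed row ({exc})") from exc
    bad = np.flatnonzero(np.diff(times.asi8) <= 0)
    if bad.size:
        raise ValueError(
            f"{path}: timestamps not strictly increasing at line {bad[0] + 3}"
        )
    return RawHeartRateLog(times=times, bpm=bpm)


def write_episodes_csv(episodes: list, path) -> None:
    pd.DataFrame(
        {
            "start": [ep.start.strftime("%Y-%m-%dT%H:%M:%S") for ep in episodes],
            "end": [ep.end.strftime("%Y-%m-%dT%H:%M:%S") for ep in episodes],
            "total_calories_kcal": [ep.total_calories for ep in episodes],
            "total_steps": [ep.total_steps for ep in episodes],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_episodes(path) -> list:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, EPISODE_COLUMNS, path)
    episodes = []
    for i, row in df.iterrows():
        try:
            episodes.append(
                ActivityEpisode(
                    start=pd.Timestamp(row["start"]),
                    end=pd.Timestamp(row["end"]),
                    total_calories=float(row["total_calories_kcal"]),
                    total_steps=int(row["total_steps"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed row at line {i + 2} ({exc})") from exc
    return episodes


def read_raw_logs(hr_path, episodes_path) -> tuple[RawHeartRateLog, list]:
    return read_heart_rate_log(hr_path), read_episodes(episodes_path)


def write_series(
    series: ActivenessSeries, path, spec: NormalizationSpec | None = None
) -> None:
    """Write the per-minute CSV plus the JSON sidecar describing its state."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "timestamp": series.index.strftime("%Y-%m-%dT%H:%M:%S"),
            "heart_rate_bpm": series.values[:, 0],
            "calories_kcal": series.values[:, 1],
            "steps": series.values[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "transform_state": series.transform_state.value,
        "start_time": str(series.start_time),
        "normalization": None
        if spec is None
        else {"bounds": {c: list(spec.bounds[c]) for c in CHANNELS},
              "log_applied": spec.log_applied},
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def read_series(path) -> tuple[ActivenessSeries, NormalizationSpec | None]:
    """Read a per-minute series CSV; the sidecar restores its transform state."""
    path = Path(path)
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise ValueError(f"{path}: missing sidecar {sidecar_path.name}")
    sidecar = json.loads(sidecar_path.read_text())
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, SERIES_COLUMNS, path)
    times = pd.DatetimeIndex(pd.to_datetime(df["timestamp"], format="ISO8601"))
    if len(times) > 1:
        deltas = np.diff(times.asi8)
        if (deltas != 60 * 10**9).any():
            bad = int(np.flatnonzero(deltas != 60 * 10**9)[0])
            raise ValueError(f"{path}: non-minute or unordered grid at line {bad + 3}")
    values = df[["heart_rate_bpm", "calories_kcal", "steps"]].to_numpy(dtype=float)
    state = TransformState(sidecar["transform_state"])
    if str(times[0]) != str(pd.Timestamp(sidecar["start_time"])):
        raise ValueError(f"{path}: sidecar start_time does not match the CSV")
    try:
        series = ActivenessSeries(
            start_time=times[0], values=values, transform_state=state
        )
    except ValueError as exc:
        raise ValueError(f"{path}: sidecar/state mismatch ({exc})") from exc
    spec = None
    if sidecar.get("normalization"):
        norm = sidecar["normalization"]
        spec = NormalizationSpec(
            bounds={c: tuple(norm["bounds"][c]) for c in CHANNELS},
            log_applied=norm["log_applied"],
        )
    return series, spec


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    seed: int = 0
    log_level: str = "INFO"
    profile: dict = field(default_factory=dict)
    normalization: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    experiment: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config sections {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    def user_profile(self, **overrides) -> UserProfile:
        block = {**self.profile, **overrides}
        block.setdefault("seed", self.seed)
        return UserProfile(**block)

    def normalization_spec(self) -> NormalizationSpec:
        if not self.normalization:
            return NormalizationSpec()
        bounds = {
            c: tuple(v) for c, v in self.normalization.get("bounds", {}).items()
        }
        default = NormalizationSpec()
        merged = {**default.bounds, **bounds}
        return NormalizationSpec(
            bounds=merged,
            log_applied=self.normalization.get("log_applied", True),
        )
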
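"""Raw tracker logs -> normalized per-minute 3-channel activeness series.

The processing chain mirrors how minute-epoch actigraphy data are usually
prepared:

1. heart-rate events, logged at irregular intervals, are linearly
   interpolated onto a one-minute grid (constant extension outside the
   observed range);
2. episode totals (calories, steps) are spread uniformly over the episode's
   minutes — each covered minute receives the episode mean, partial boundary
   minutes a proportional share, so per-episode mass is conserved;
3. a log(1 + x) transform tames the heavy positive skew of the activity
   channels (many exact zeros);
4. min–max normalization maps each channel to [0, 1] using fixed
   physiological bounds rather than data-dependent extremes.

``ActivenessSeries`` tracks which of these transforms have been applied via
``transform_state`` so stages cannot be applied out of order or twice.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .synthetic import MINUTES_PER_DAY, ActivityEpisode, RawHeartRateLog

logger = logging.getLogger(__name__)

#: Fixed channel order used everywhere in the package.
CHANNELS = ("heart_rate", "calories", "steps")

__all__ = [
    "CHANNELS",
    "TransformState",
    "ActivenessSeries",
    "NormalizationSpec",
    "WindowedDataset",
    "interpolate_heart_rate",
    "distribute_episode_totals",
    "build_raw_series",
    "log_transform",
    "minmax_normalize",
    "inverse_transform",
    "preprocess",
    "make_windows",
]


class TransformState(str, enum.Enum):
    RAW = "raw"
    LOGGED = "logged"
    NORMALIZED = "normalized"


@dataclass
class ActivenessSeries:
    """Aligned per-minute (heart rate, calories, steps) series."""

    start_time: pd.Timestamp
    values: np.ndarray  # shape (minutes, 3), channel order = CHANNELS
    transform_state: TransformState = TransformState.RAW

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(CHANNELS):
            raise ValueError(f"values must have shape (minutes, {len(CHANNELS)})")
        if not np.isfinite(self.values).all():
            raise ValueError("series values must be finite")
        self.transform_state = TransformState(self.transform_state)
        if self.transform_state is TransformState.NORMALIZED:
            if self.values.min() < 0.0 or self.values.max() > 1.0:
                raise ValueError("normalized series must lie in [0, 1]")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def minutes(self) -> int:
        return self.values.shape[0]

    @property
    def index(self) -> pd.DatetimeIndex:
        return self.start_time + pd.to_timedelta(np.arange(len(self)), unit="m")

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, CHANNELS.index(name)]

    def slice(self, start_minute: int, end_minute: int) -> "ActivenessSeries":
        return ActivenessSeries(
            start_time=self.start_time + pd.Timedelta(minutes=start_minute),
            values=self.values[start_minute:end_minute].copy(),
            transform_state=self.transform_state,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.index, columns=list(CHANNELS))


@dataclass(frozen=True)
class NormalizationSpec:
    """Per-channel physical [min, max] bounds for min–max normalization.

    The defaults are physiological extremes for adult wrist-tracker data:
    heart rate 30–220 BPM (deep rest to maximal exertion), 0–20 kcal/min
    (above elite sustained output), 0–220 steps/min (above sprint cadence).
    """

    bounds: dict = field(
        default_factory=lambda: {
            "heart_rate": (30.0, 220.0),
            "calories": (0.0, 20.0),
            "steps": (0.0, 220.0),
        }
    )
    log_applied: bool = True

    def __post_init__(self) -> None:
        for name in CHANNELS:
            if name not in self.bounds:
                raise ValueError(f"missing bounds for channel {name!r}")
            lo, hi = self.bounds[name]
            if hi <= lo:
                raise ValueError(f"max must exceed min for channel {name!r}")

    def arrays(self, logged: bool) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.bounds[c][0] for c in CHANNELS], dtype=float)
        hi = np.array([self.bounds[c][1] for c in CHANNELS], dtype=float)
        if logged:
            lo, hi = np.log1p(lo), np.log1p(hi)
        return lo, hi


def interpolate_heart_rate(
    log: RawHeartRateLog, start: pd.Timestamp, minutes: int
) -> np.ndarray:
    """Linear interpolation of irregular heart-rate events onto minute grid.

    Grid minutes before the first / after the last event take the nearest
    event's value (constant extension).
    """
    if len(log) == 0:
        raise ValueError("no heart-rate events")
    if minutes < 1:
        raise ValueError("minutes must be >= 1")
    start = pd.Timestamp(start)
    event_min = (log.times - start) / pd.Timedelta(minutes=1)
    grid = np.arange(minutes, dtype=float)
    return np.interp(grid, np.asarray(event_min, dtype=float), log.bpm)


def distribute_episode_totals(
    episodes: list[ActivityEpisode], start: pd.Timestamp, minutes: int
) -> np.ndarray:
    """Spread episode totals uniformly over their minutes.

    Returns an array of shape (minutes, 2) with columns (calories, steps).
    Episodes are half-open intervals [start, end): a minute belongs to the
    episode covering its left edge, so abutting episodes never double-count.
    A grid minute overlapped for a fraction f of its length receives f times
    the episode's per-minute mean, which conserves per-episode totals exactly
    for fully contained episodes.
    """
    start = pd.Timestamp(start)
    out = np.zeros((minutes, 2))
    by_start = sorted(episodes, key=lambda ep: ep.start)
    for prev, nxt in zip(by_start, by_start[1:]):
        if nxt.start < prev.end:
            raise ValueError("overlapping episodes")
    for ep in by_start:
        s = (ep.start - start) / pd.Timedelta(minutes=1)
        e = (ep.end - start) / pd.Timedelta(minutes=1)
        duration = e - s
        cs, ce = max(s, 0.0), min(e, float(minutes))
        if ce <= cs:
            logger.warning("episode starting %s lies outside the grid; skipped", ep.start)
            continue
        if cs > s or ce < e:
            logger.warning("episode starting %s clipped to the grid", ep.start)
        rate = np.array([ep.total_calories, ep.total_steps]) / duration
        m0, m1 = int(np.floor(cs)), int(np.ceil(ce))
        grid = np.arange(m0, m1)
        overlap = np.minimum(grid + 1.0, ce) - np.maximum(grid, cs)
        out[m0:m1] += overlap[:, None] * rate[None, :]
    return out


def build_raw_series(
    hr_log: RawHeartRateLog,
    episodes: list[ActivityEpisode],
    start: pd.Timestamp,
    minutes: int,
) -> ActivenessSeries:
    """Assemble the raw per-minute 3-channel series from raw logs."""
    hr = interpolate_heart_rate(hr_log, start, minutes)
    cal_steps = distribute_episode_totals(episodes, start, minutes)
    values = np.column_stack([hr, cal_steps])
    return ActivenessSeries(start_time=start, values=values)


def log_transform(series: ActivenessSeries) -> ActivenessSeries:
    """Elementwise log(1 + x); requires a raw, nonnegative series."""
    if series.transform_state is not TransformState.RAW:
        raise ValueError("log_transform expects a raw series")
    if series.values.min() < 0:
        raise ValueError("log_transform requires nonnegative values")
    return ActivenessSeries(
        start_time=series.start_time,
        values=np.log1p(series.values),
        transform_state=TransformState.LOGGED,
    )


def minmax_normalize(
    series: ActivenessSeries, spec: NormalizationSpec
) -> ActivenessSeries:
    """(v - min)/(max - min) per channel, on the log scale of the spec bounds.

    Values outside the bounds (tracker artifacts) are clipped to the boundary
    with a logged warning rather than aborting.
    """
    if series.transform_state is not TransformState.LOGGED:
        raise ValueError("minmax_normalize expects a logged series")
    lo, hi = spec.arrays(logged=spec.log_applied)
    scaled = (series.values - lo) / (hi - lo)
    n_out = int(((scaled < 0.0) | (scaled > 1.0)).sum())
    if n_out:
        logger.warning("%d values outside the normalization bounds were clipped", n_out)
        scaled = np.clip(scaled, 0.0, 1.0)
    return ActivenessSeries(
        start_time=series.start_time,
        values=scaled,
        transform_state=TransformState.NORMALIZED,
    )


def inverse_transform(
    series: ActivenessSeries, spec: NormalizationSpec
) -> ActivenessSeries:
    """Exact algebraic inverse of min–max then log1p; returns a raw series."""
    if series.transform_state is not TransformState.NORMALIZED:
        raise ValueError("inverse_transform expects a normalized series")
    if not spec.log_applied:
        raise ValueError("normalization spec does not match the recorded state")
    lo, hi = spec.arrays(logged=True)
    values = np.expm1(series.values * (hi - lo) + lo)
    return ActivenessSeries(
        start_time=series.start_time,
        values=np.maximum(values, 0.0),
        transform_state=TransformState.RAW,
    )


def preprocess(
    series: ActivenessSeries, spec: NormalizationSpec | None = None
) -> tuple[ActivenessSeries, NormalizationSpec]:
    """Full forward pipeline: raw -> log1p -> min–max normalized."""
    spec = spec or NormalizationSpec()
    return minmax_normalize(log_transform(series), spec), spec


@dataclass
class WindowedDataset:
    """Sliding input/target windows cut from one series.

    ``inputs[i]`` covers minutes ``[offsets[i], offsets[i] + input_len)`` of
    the source series and ``targets[i]`` the ``output_len`` minutes starting
    exactly at the input window's end.
    """

    inputs: np.ndarray  # (samples, input_len, channels_in)
    targets: np.ndarray  # (samples, output_len, channels_out)
    stride: int
    offsets: np.ndarray  # start minute of each input window in the source
    channels_in: tuple
    channels_out: tuple
    series_id: str | None = None

    @property
    def n_samples(self) -> int:
        return self.inputs.shape[0]

    @property
    def input_len(self) -> int:
        return self.inputs.shape[1]

    @property
    def output_len(self) -> int:
        return self.targets.shape[1]


def make_windows(
    series: ActivenessSeries,
    input_len: int,
    output_len: int,
    stride: int = 1,
    channels_in: tuple | str = CHANNELS,
    channels_out: tuple | str | None = None,
    series_id: str | None = None,
) -> WindowedDataset:
    """Cut a series into supervised (input window, target window) samples.

    The sample count is ``floor((L - input_len - output_len) / stride) + 1``
    for a series of length L.
    """
    if isinstance(channels_in, str):
        channels_in = (channels_in,)
    if channels_out is None:
        channels_out = channels_in
    elif isinstance(channels_out, str):
        channels_out = (channels_out,)
    if stride < 1:
        raise ValueError("stride must be >= 1")
    L = len(series)
    if L < input_len + output_len:
        raise ValueError("insufficient length")
    idx_in = [CHANNELS.index(c) for c in channels_in]
    idx_out = [CHANNELS.index(c) for c in channels_out]
    offsets = np.arange(0, L - input_len - output_len + 1, stride)
    inputs = np.stack(
        [series.values[o : o + input_len][:, idx_in] for o in offsets]
    )
    targets = np.stack(
        [
            series.values[o + input_len : o + input_len + output_len][:, idx_out]
            for o in offsets
        ]
    )
    return WindowedDataset(
        inputs=inputs,
        targets=targets,
        stride=stride,
        offsets=offsets,
        channels_in=tuple(channels_in),
        channels_out=tuple(channels_out),
        series_id=series_id,
    )
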
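"""Study harness: walk-forward forecasting and the length-parameter grids.

Reproduces the study designs around the forecasters:

* walk-forward prediction — a future span is tiled with consecutive
  non-overlapping output windows, each predicted from the ``input_len``
  minutes immediately before it. By default those inputs are the *observed*
  (true) series ("observational" mode); a "recursive" mode that feeds
  predictions back in is available. Either way no input minute may lie at or
  after its own forecast window's start, and every forecast carries a
  timestamp audit proving it.
* the hidden-unit sweep over the four recurrent layouts;
* the five length-parameter experiments — varying input length, output
  length, both together, training length and prediction length over fixed
  grids while the other parameters stay at the defaults (training 1 month,
  input 15 min, output 15 min, prediction 1 week) — comparing the
  many-to-one GRU against the DNN and OLS baselines;
* per-day, per-time-of-day MSE profiles for the regular-vs-irregular user
  contrast.

Durations use fixed conversions: 1 day = 1440 min, 1 week = 7 days,
1 month = 30 days. Forecast accuracy (SMAPE/MSE) is reported in the
models' normalized space.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .models import (
    Architecture,
    ModelConfig,
    ModelHandle,
    MULTIVARIATE,
    UNIVARIATE,
    build_model,
    train,
    predict_window,
)
from .preprocessing import CHANNELS, ActivenessSeries, TransformState, make_windows
from .stats import mse, smape

logger = logging.getLogger(__name__)

DAY = 1440
WEEK = 7 * DAY
MONTH = 30 * DAY

#: Table-style grids for the five length experiments.
LENGTH_GRIDS = {
    1: ("input_len", (5, 15, 30, 60, 120)),
    2: ("output_len", (5, 15, 30, 60, 120)),
    3: ("input_output_len", (5, 15, 30, 60, 120)),
    4: ("training_len", (7 * DAY, 14 * DAY, MONTH, 90 * DAY, 150 * DAY)),
    5: ("prediction_len", (DAY, 3 * DAY, WEEK, MONTH, 90 * DAY)),
}

__all__ = [
    "DAY",
    "WEEK",
    "MONTH",
    "LENGTH_GRIDS",
    "ExperimentConfig",
    "ExperimentReport",
    "Forecast",
    "train_for_experiment",
    "walk_forward_predict",
    "walk_forward_all_channels",
    "run_hidden_unit_sweep",
    "run_length_experiment",
    "mse_time_profile",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Length parameters and model settings for one study run."""

    training_len: int = MONTH  # minutes
    input_len: int = 15
    output_len: int = 15
    prediction_len: int = WEEK  # minutes
    architectures: tuple = (Architecture.UNI_MO,)
    hidden_grid: tuple = (32, 52, 64, 128)
    hidden_units: int = 52
    stride: int = 1
    seed: int = 0
    model_overrides: dict = field(default_factory=dict)  # e.g. max_epochs

    def __post_init__(self) -> None:
        if self.training_len < self.input_len + self.output_len:
            raise ValueError("training_len must cover at least one input+output window")
        if self.prediction_len < self.output_len:
            raise ValueError("prediction_len must cover at least one output window")

    def replace(self, **kwargs) -> "ExperimentConfig":
        return replace(self, **kwargs)


def _derive_seed(base: int, *tokens) -> int:
    """Stable per-model seed below 2**31 derived from a base seed."""
    tag = "|".join(str(t) for t in tokens)
    return (int(base) * 2654435761 + zlib.crc32(tag.encode())) % (2**31)


@dataclass
class Forecast:
    """An aligned span of per-minute values with walk-forward provenance.

    ``audit`` holds one (input_start, input_end, window_start) triple of
    absolute source-series minute offsets per predicted window; walk-forward
    legality requires input_end <= window_start for all of them.
    """

    start_time: pd.Timestamp
    channels: tuple
    values: np.ndarray  # (minutes, len(channels))
    audit: list = field(default_factory=list)
    source: str = "predicted"

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def index(self) -> pd.DatetimeIndex:
        return self.start_time + pd.to_timedelta(np.arange(len(self)), unit="m")

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, self.channels.index(name)]

    def assert_no_leakage(self) -> None:
        for input_start, input_end, window_start in self.audit:
            if input_end > window_start:
                raise AssertionError(
                    f"forecast window at minute {window_start} consumed input "
                    f"up to minute {input_end}"
                )

    def to_series(self, clip: bool = True) -> ActivenessSeries:
        """View a full 3-channel forecast as a normalized ActivenessSeries."""
        if tuple(self.channels) != CHANNELS:
            raise ValueError("need all three channels to build an ActivenessSeries")
        vals = np.clip(self.values, 0.0, 1.0) if clip else self.values
        return ActivenessSeries(
            start_time=self.start_time,
            values=vals,
            transform_state=TransformState.NORMALIZED,
        )


def train_for_experiment(
    series: ActivenessSeries,
    exp: ExperimentConfig,
    architecture: Architecture,
    channel: str | None = None,
    hidden_units: int | None = None,
    seed: int | None = None,
) -> ModelHandle:
    """Train one model on the first ``training_len`` minutes of a series."""
    architecture = Architecture(architecture)
    if architecture in MULTIVARIATE:
        channels = CHANNELS
    else:
        if channel is None:
            raise ValueError("univariate/baseline models need a target channel")
        channels = (channel,)
    training = series.slice(0, exp.training_len)
    data = make_windows(
        training,
        exp.input_len,
        exp.output_len,
        stride=exp.stride,
        channels_in=channels,
        channels_out=channels,
    )
    config = ModelConfig(
        architecture=architecture,
        input_len=exp.input_len,
        output_len=exp.output_len,
        channels_in=len(channels),
        channels_out=len(channels),
        hidden_units=hidden_units or exp.hidden_units,
        seed=seed if seed is not None else exp.seed,
        **exp.model_overrides,
    )
    return train(build_model(config), data)


def walk_forward_predict(
    handle: ModelHandle,
    series: ActivenessSeries,
    exp: ExperimentConfig,
    channels: tuple | str | None = None,
    mode: str = "observational",
) -> tuple[Forecast, Forecast]:
    """Tile the prediction span with consecutive forecast windows.

    Returns (predicted, true) forecasts covering the same minutes with
    identical timestamps. ``mode="observational"`` (default) conditions each
    window on the immediately preceding true data; ``mode="recursive"``
    feeds previously predicted minutes back in where they overlap the input
    window.
    """
    if mode not in ("observational", "recursive"):
        raise ValueError("mode must be 'observational' or 'recursive'")
    cfg = handle.config
    if channels is None:
        channels = CHANNELS if cfg.channels_in == 3 else None
    if isinstance(channels, str):
        channels = (channels,)
    if channels is None or len(channels) != cfg.channels_in:
        raise ValueError("channel selection must match the model's input width")
    n, m = cfg.input_len, cfg.output_len
    t0 = exp.training_len
    if len(series) < t0 + exp.prediction_len:
        raise ValueError("insufficient series length for training + prediction span")
    n_windows = exp.prediction_len // m
    if exp.prediction_len % m:
        logger.warning(
            "prediction span not a multiple of output_len; dropping %d trailing minutes",
            exp.prediction_len % m,
        )
    idx = [CHANNELS.index(c) for c in channels]
    buffer = series.values[:, idx].copy()
    preds = np.empty((n_windows * m, len(channels)))
    audit = []
    if mode == "observational":
        starts = t0 + m * np.arange(n_windows)
        batch = np.stack([series.values[p - n : p][:, idx] for p in starts])
        out = predict_window(handle, batch)
        preds = out.reshape(n_windows * m, len(channels))
        audit = [(int(p - n), int(p), int(p)) for p in starts]
    else:
        for w in range(n_windows):
            p = t0 + w * m
            out = predict_window(handle, buffer[p - n : p])
            buffer[p : p + m] = out
            preds[w * m : (w + 1) * m] = out
            audit.append((int(p - n), int(p), int(p)))
    span_start = series.start_time + pd.Timedelta(minutes=t0)
    predicted = Forecast(
        start_time=span_start, channels=tuple(channels), values=preds, audit=audit
    )
    truth = Forecast(
        start_time=span_start,
        channels=tuple(channels),
        values=series.values[t0 : t0 + n_windows * m][:, idx].copy(),
        source="true_data",
    )
    return predicted, truth


def walk_forward_all_channels(
    handles: dict, series: ActivenessSeries, exp: ExperimentConfig, mode: str = "observational"
) -> tuple[Forecast, Forecast]:
    """Combine three univariate walk-forward forecasts into one 3-channel span."""
    preds, truths, audit = {}, {}, []
    for c in CHANNELS:
        pf, tf = walk_forward_predict(handles[c], series, exp, channels=c, mode=mode)
        preds[c], truths[c] = pf, tf
        audit = pf.audit
    values = np.column_stack([preds[c].values[:, 0] for c in CHANNELS])
    tvalues = np.column_stack([truths[c].values[:, 0] for c in CHANNELS])
    start = preds[CHANNELS[0]].start_time
    return (
        Forecast(start_time=start, channels=CHANNELS, values=values, audit=audit),
        Forecast(start_time=start, channels=CHANNELS, values=tvalues, source="true_data"),
    )


@dataclass
class ExperimentReport:
    """Tidy per-(model, user, channel, setting) SMAPE table + aggregations."""

    table: pd.DataFrame

    def aggregate(self) -> pd.DataFrame:
        """Mean SMAPE over users per (experiment, setting, model, channel)."""
        ok = self.table[self.table["status"] == "ok"]
        keys = [
            c
            for c in ("experiment", "architecture", "hidden_units", "setting", "channel")
            if c in ok.columns
        ]
        return ok.groupby(keys, dropna=False)["smape"].mean().reset_index()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def summary(self) -> dict:
        agg = self.aggregate()
        return {
            "n_rows": int(len(self.table)),
            "n_unavailable": int((self.table["status"] != "ok").sum()),
            "mean_smape": agg.to_dict(orient="records"),
        }


def _score_rows(pred: Forecast, truth: Forecast) -> dict:
    out = {}
    for c in pred.channels:
        out[c] = smape(truth.channel(c), pred.channel(c))
    return out


def run_hidden_unit_sweep(
    series_by_user: dict, exp: ExperimentConfig
) -> ExperimentReport:
    """Train every architecture at every hidden-unit grid point per user.

    Univariate architectures are trained once per channel (three models per
    user); multivariate architectures once per user.
    """
    if not series_by_user:
        raise ValueError("at least one user series is required")
    rows = []
    for arch in exp.architectures:
        arch = Architecture(arch)
        for units in exp.hidden_grid:
            for user, series in series_by_user.items():
                if arch in MULTIVARIATE:
                    handle = train_for_experiment(
                        series, exp, arch, hidden_units=units,
                        seed=_derive_seed(exp.seed, arch.value, units, user),
                    )
                    pred, truth = walk_forward_predict(handle, series, exp)
                    scores = _score_rows(pred, truth)
                else:
                    handles = {
                        c: train_for_experiment(
                            series, exp, arch, channel=c, hidden_units=units,
                            seed=_derive_seed(exp.seed, arch.value, units, user, c),
                        )
                        for c in CHANNELS
                    }
                    pred, truth = walk_forward_all_channels(handles, series, exp)
                    scores = _score_rows(pred, truth)
                for c, s in scores.items():
                    rows.append(
                        dict(
                            architecture=arch.value,
                            hidden_units=units,
                            user=user,
                            channel=c,
                            smape=s,
                            status="ok",
                        )
                    )
                rows.append(
                    dict(
                        architecture=arch.value,
                        hidden_units=units,
                        user=user,
                        channel="combined",
                        smape=float(np.mean(list(scores.values()))),
                        status="ok",
                    )
                )
    return ExperimentReport(table=pd.DataFrame(rows))


#: Models compared in the length experiments.
LENGTH_EXPERIMENT_MODELS = (
    Architecture.UNI_MO,
    Architecture.DNN_BASELINE,
    Architecture.OLS_BASELINE,
)


def run_length_experiment(
    which: int,
    series_by_user: dict,
    exp: ExperimentConfig | None = None,
    settings: tuple | None = None,
) -> ExperimentReport:
    """Run one of the five length-parameter experiments.

    ``which`` selects the varied parameter (1 input, 2 output, 3 both tied,
    4 training length, 5 prediction length); the grid is the study's unless
    ``settings`` overrides it (e.g. a scaled-down subset). Settings a user's
    series cannot cover are marked unavailable and skipped.
    """
    if which not in LENGTH_GRIDS:
        raise ValueError("experiment number must be in 1..5")
    exp = exp or ExperimentConfig()
    param, grid = LENGTH_GRIDS[which]
    grid = tuple(settings) if settings is not None else grid
    rows = []
    for value in grid:
        if param == "input_output_len":
            exp_s = exp.replace(input_len=value, output_len=value)
        else:
            exp_s = exp.replace(**{param: value})
        for user, series in series_by_user.items():
            needed = exp_s.training_len + exp_s.prediction_len
            if len(series) < needed:
                logger.warning(
                    "user %s series (%d min) cannot cover setting %s=%s; marked unavailable",
                    user, len(series), param, value,
                )
                for c in CHANNELS + ("combined",):
                    for arch in LENGTH_EXPERIMENT_MODELS:
                        rows.append(
                            dict(
                                experiment=which, setting=value, architecture=arch.value,
                                user=user, channel=c, smape=np.nan, status="unavailable",
                            )
                        )
                continue
            for arch in LENGTH_EXPERIMENT_MODELS:
                handles = {
                    c: train_for_experiment(
                        series, exp_s, arch, channel=c,
                        seed=_derive_seed(exp.seed, which, value, arch.value, user, c),
                    )
                    for c in CHANNELS
                }
                pred, truth = walk_forward_all_channels(handles, series, exp_s)
                pred.assert_no_leakage()
                scores = _score_rows(pred, truth)
                for c, s in scores.items():
                    rows.append(
                        dict(
                            experiment=which, setting=value, architecture=arch.value,
                            user=user, channel=c, smape=s, status="ok",
                        )
                    )
                rows.append(
                    dict(
                        experiment=which, setting=value, architecture=arch.value,
                        user=user, channel="combined",
                        smape=float(np.mean(list(scores.values()))), status="ok",
                    )
                )
    return ExperimentReport(table=pd.DataFrame(rows))


def mse_time_profile(
    predicted: Forecast, truth: Forecast, channel: str, bucket: int = 60
) -> pd.DataFrame:
    """Per-(day, clock-time bucket) MSE table of a forecast.

    Rows are calendar days, columns bucket start minutes-of-day. Regular
    users show day-to-day consistent low-error valleys; irregular users a
    flat, high profile.
    """
    if len(predicted) != len(truth):
        raise ValueError("predicted and true spans must be aligned")
    if DAY % bucket:
        raise ValueError("bucket must divide the day")
    err = (predicted.channel(channel) - truth.channel(channel)) ** 2
    idx = predicted.index
    frame = pd.DataFrame(
        {
            "day": idx.date,
            "bucket": (idx.hour * 60 + idx.minute) // bucket * bucket,
            "err": err,
        }
    )
    return frame.pivot_table(index="day", columns="bucket", values="err", aggfunc="mean")
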
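"""Detection and scoring of low-activeness time windows.

A 15-minute window is *less active* for one channel when strictly more than
70% of its minutes (10.5 of 15, i.e. at least 11) lie strictly below that
calendar day's channel average (definition 1). A window is less active
overall when all three channels mark it so (definition 2, the intersection).

Two evaluation approaches compare a forecast against truth:

* approach 1 — label predicted and true series separately under the chosen
  definition and score them against each other (per channel for
  definition 1);
* approach 2 — fuse the three per-channel predicted label sets by 2-of-3
  majority vote and score against the definition-2 truth.

Ties break toward "not less active": both the minute comparison ("lower
than") and the window fraction ("more than 70%") are strict. Windows tile
the evaluated span from its start; a trailing partial window is dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import CHANNELS, ActivenessSeries

logger = logging.getLogger(__name__)

__all__ = [
    "WindowLabelSet",
    "PrfScore",
    "daily_average",
    "label_windows_def1",
    "label_windows_def2",
    "vote_windows",
    "score_prf",
    "evaluate_approach1",
    "evaluate_approach2",
]

DEFAULT_WINDOW_LEN = 15
DEFAULT_FRAC = 0.70


@dataclass
class WindowLabelSet:
    """Boolean less-active labels over consecutive windows of one span."""

    start_time: pd.Timestamp
    window_len: int
    labels: np.ndarray  # bool, one per window
    channel: str  # one of CHANNELS or "fused"
    source: str  # "true_data" or "predicted"

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        self.labels = np.asarray(self.labels, dtype=bool)

    def __len__(self) -> int:
        return len(self.labels)

    def window_bounds(self) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
        step = pd.Timedelta(minutes=self.window_len)
        return [
            (self.start_time + i * step, self.start_time + (i + 1) * step)
            for i in range(len(self.labels))
        ]

    def to_frame(self) -> pd.DataFrame:
        bounds = self.window_bounds()
        return pd.DataFrame(
            {
                "window_start": [b[0] for b in bounds],
                "window_end": [b[1] for b in bounds],
                "channel": self.channel,
                "label": self.labels,
            }
        )


@dataclass
class PrfScore:
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
        }


def daily_average(series: ActivenessSeries, channel: str, day) -> float:
    """Arithmetic mean of one channel's values over one calendar day."""
    day = pd.Timestamp(day).date()
    mask = np.asarray(series.index.date) == day
    if not mask.any():
        raise ValueError(f"series contains no minutes on {day}")
    return float(series.channel(channel)[mask].mean())


def _per_minute_daily_means(values: np.ndarray, dates: np.ndarray) -> np.ndarray:
    """Each minute's own calendar day's mean, as a vector aligned to values."""
    s = pd.Series(values)
    return s.groupby(dates).transform("mean").to_numpy()


def label_windows_def1(
    series: ActivenessSeries,
    channel: str,
    window_len: int = DEFAULT_WINDOW_LEN,
    frac: float = DEFAULT_FRAC,
    reference: ActivenessSeries | None = None,
    source: str = "true_data",
) -> WindowLabelSet:
    """Definition-1 labels: > frac of a window's minutes strictly sub-average.

    The daily average is taken from ``reference`` when given (e.g. threshold
    a predicted series against the true data's averages), otherwise from the
    labeled series itself. Windows straddling midnight compare each minute
    against its own day's average.
    """
    if len(series) < window_len:
        raise ValueError("series shorter than one window")
    ref = reference if reference is not None else series
    if reference is not None and len(reference) != len(series):
        raise ValueError("reference series must align with the labeled series")
    values = series.channel(channel)
    means = _per_minute_daily_means(
        ref.channel(channel), np.asarray(ref.index.date)
    )
    below = values < means
    n_windows = len(series) // window_len
    if n_windows * window_len < len(series):
        logger.debug("dropping trailing partial window of %d minutes", len(series) - n_windows * window_len)
    counts = below[: n_windows * window_len].reshape(n_windows, window_len).sum(axis=1)
    labels = counts > frac * window_len
    return WindowLabelSet(
        start_time=series.start_time,
        window_len=window_len,
        labels=labels,
        channel=channel,
        source=source,
    )


def _check_aligned(sets: list[WindowLabelSet]) -> None:
    first = sets[0]
    for s in sets[1:]:
        if (
            len(s) != len(first)
            or s.window_len != first.window_len
            or s.start_time != first.start_time
        ):
            raise ValueError("label sets are not aligned")


def label_windows_def2(per_channel: list[WindowLabelSet]) -> WindowLabelSet:
    """Definition-2 labels: intersection (logical AND) of the three channels."""
    if len(per_channel) != 3:
        raise ValueError("definition 2 fuses exactly three channel label sets")
    _check_aligned(per_channel)
    fused = np.logical_and.reduce([s.labels for s in per_channel])
    return WindowLabelSet(
        start_time=per_channel[0].start_time,
        window_len=per_channel[0].window_len,
        labels=fused,
        channel="fused",
        source=per_channel[0].source,
    )


def vote_windows(per_channel: list[WindowLabelSet], k: int = 2) -> WindowLabelSet:
    """Majority fusion: a window is less active iff >= k of the 3 sets say so."""
    if len(per_channel) != 3:
        raise ValueError("voting fuses exactly three channel label sets")
    if not 1 <= k <= 3:
        raise ValueError("k must be in 1..3")
    _check_aligned(per_channel)
    votes = np.sum([s.labels for s in per_channel], axis=0)
    return WindowLabelSet(
        start_time=per_channel[0].start_time,
        window_len=per_channel[0].window_len,
        labels=votes >= k,
        channel="fused",
        source=per_channel[0].source,
    )


def score_prf(predicted: WindowLabelSet, truth: WindowLabelSet) -> PrfScore:
    """Precision/recall/F1 with less-active as the positive class."""
    _check_aligned([predicted, truth])
    p, t = predicted.labels, truth.labels
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    if tp + fp == 0:
        logger.warning("no predicted positives; precision set to 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        logger.warning("no true positives; recall set to 0")
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    f1 = 2.0 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return PrfScore(precision=precision, recall=recall, f1=f1, tp=tp, fp=fp, fn=fn)


def evaluate_approach1(
    predicted: ActivenessSeries,
    truth: ActivenessSeries,
    definition: int = 1,
    window_len: int = DEFAULT_WINDOW_LEN,
    frac: float = DEFAULT_FRAC,
    use_true_averages: bool = False,
):
    """Label forecast and truth under one definition and score them.

    Returns a dict of per-channel ``PrfScore`` for definition 1, a single
    fused ``PrfScore`` for definition 2. By default the predicted labels
    threshold against the predicted series' own daily averages (usable
    before the day's true data exist); ``use_true_averages`` switches both
    to the true series' averages.
    """
    if len(predicted) != len(truth) or predicted.start_time != truth.start_time:
        raise ValueError("predicted and true series must be aligned")
    ref = truth if use_true_averages else None
    pred_sets = {
        c: label_windows_def1(
            predicted, c, window_len, frac, reference=ref, source="predicted"
        )
        for c in CHANNELS
    }
    true_sets = {
        c: label_windows_def1(truth, c, window_len, frac) for c in CHANNELS
    }
    if definition == 1:
        return {c: score_prf(pred_sets[c], true_sets[c]) for c in CHANNELS}
    if definition == 2:
        return score_prf(
            label_windows_def2(list(pred_sets.values())),
            label_windows_def2(list(true_sets.values())),
        )
    raise ValueError("definition must be 1 or 2")


def evaluate_approach2(
    predicted: ActivenessSeries,
    truth: ActivenessSeries,
    window_len: int = DEFAULT_WINDOW_LEN,
    frac: float = DEFAULT_FRAC,
    k: int = 2,
    use_true_averages: bool = False,
) -> PrfScore:
    """2-of-3 vote over per-channel predicted labels vs definition-2 truth."""
    if len(predicted) != len(truth) or predicted.start_time != truth.start_time:
        raise ValueError("predicted and true series must be aligned")
    ref = truth if use_true_averages else None
    pred_sets = [
        label_windows_def1(
            predicted, c, window_len, frac, reference=ref, source="predicted"
        )
        for c in CHANNELS
    ]
    true_sets = [label_windows_def1(truth, c, window_len, frac) for c in CHANNELS]
    return score_prf(vote_windows(pred_sets, k=k), label_windows_def2(true_sets))
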
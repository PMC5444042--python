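"""Descriptive statistics and forecast-evaluation metrics.

Covers the exploratory statistics used on activeness data — Pearson
correlations between the three channels (computed on the raw, pre-log,
pre-normalization series), the sample autocorrelation function with
white-noise confidence bands, and lag-1 scatter pairs — plus the forecast
metrics: SMAPE, per-channel MSE, and the "combined" SMAPE (the arithmetic
mean of the three per-channel SMAPEs).

SMAPE here is

    SMAPE(y, yhat) = (100 / n) * sum |yhat_t - y_t| / ((|y_t| + |yhat_t|) / 2)

which is symmetric in its arguments and bounded by 200%. The formula is
undefined when y_t = yhat_t = 0; since zero minutes are common in step and
calorie data, such terms contribute 0 by default (``zero_zero="zero"``), or
can be dropped from the average entirely (``zero_zero="skip"``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from statsmodels.tsa.stattools import acf as _sm_acf

from .preprocessing import CHANNELS, ActivenessSeries, TransformState

logger = logging.getLogger(__name__)

__all__ = [
    "pearson",
    "correlation_matrix",
    "CorrelationMatrix",
    "autocorrelation",
    "AcfResult",
    "lag_pairs",
    "smape",
    "mse",
    "combined_smape",
    "EvalReport",
    "evaluate_forecast",
]


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson requires two equal-length 1-D vectors")
    if len(x) < 2:
        raise ValueError("pearson requires length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant series")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class CorrelationMatrix:
    values: np.ndarray  # (3, 3)
    labels: tuple = CHANNELS

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))


def correlation_matrix(series: ActivenessSeries) -> CorrelationMatrix:
    """Pairwise Pearson correlations of the three channels.

    Computed on raw physical values; pass the series before log/min–max.
    """
    if series.transform_state is not TransformState.RAW:
        raise ValueError("channel correlations are defined on the raw series")
    vals = np.eye(len(CHANNELS))
    for i in range(len(CHANNELS)):
        for j in range(i + 1, len(CHANNELS)):
            r = pearson(series.values[:, i], series.values[:, j])
            vals[i, j] = vals[j, i] = r
    return CorrelationMatrix(values=vals)


@dataclass
class AcfResult:
    """Sample ACF with white-noise confidence bands.

    band95/band99 are the +-z/sqrt(n) limits for a white-noise null
    (z = 1.96 and 2.576). ``bartlett_band95`` gives the per-lag large-lag
    standard-error band from Bartlett's formula, the appropriate null band
    once short-range correlation is present.
    """

    lags: np.ndarray
    acf: np.ndarray
    band95: float
    band99: float
    n: int

    def bartlett_band95(self) -> np.ndarray:
        """95% band for lags 1..max_lag; entry k uses sum_{j<k} acf_j^2."""
        r2 = self.acf[1:] ** 2
        cum_below = np.concatenate([[0.0], np.cumsum(r2)[:-1]])
        return 1.96 * np.sqrt((1.0 + 2.0 * cum_below) / self.n)


def autocorrelation(x: np.ndarray, max_lag: int) -> AcfResult:
    """Sample ACF (global-mean, lag-truncated estimator) up to ``max_lag``."""
    x = np.asarray(x, dtype=float)
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if max_lag >= len(x):
        raise ValueError("max_lag must be smaller than the series length")
    r = _sm_acf(x, nlags=max_lag, fft=True)
    n = len(x)
    return AcfResult(
        lags=np.arange(max_lag + 1),
        acf=r,
        band95=1.96 / np.sqrt(n),
        band99=2.576 / np.sqrt(n),
        n=n,
    )


def lag_pairs(x: np.ndarray) -> np.ndarray:
    """(y_t, y_{t+1}) pairs for a lag plot; shape (n-1, 2)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("lag_pairs requires length >= 2")
    return np.column_stack([x[:-1], x[1:]])


def smape(y: np.ndarray, yhat: np.ndarray, zero_zero: str = "zero") -> float:
    """Symmetric mean absolute percentage error, in percent (0–200)."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("smape requires equal-length vectors")
    if len(y) == 0:
        raise ValueError("smape requires length >= 1")
    denom = (np.abs(y) + np.abs(yhat)) / 2.0
    zero = denom == 0.0
    terms = np.zeros_like(denom)
    np.divide(np.abs(yhat - y), denom, out=terms, where=~zero)
    if zero_zero == "zero":
        return float(100.0 * terms.sum() / len(y))
    elif zero_zero == "skip":
        kept = int((~zero).sum())
        if kept == 0:
            return 0.0
        return float(100.0 * terms[~zero].sum() / kept)
    raise ValueError("zero_zero must be 'zero' or 'skip'")


def mse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean squared error."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("mse requires equal-length vectors")
    return float(np.mean((y - yhat) ** 2))


def combined_smape(per_channel) -> float:
    """Arithmetic mean of the three per-channel SMAPEs."""
    per_channel = np.asarray(per_channel, dtype=float)
    if per_channel.shape != (3,):
        raise ValueError("combined_smape expects exactly three values")
    if (per_channel < 0).any():
        raise ValueError("SMAPE values must be nonnegative")
    return float(per_channel.mean())


@dataclass
class EvalReport:
    """Per-channel SMAPE/MSE plus the combined SMAPE for one forecast."""

    smape_per_channel: dict
    mse_per_channel: dict
    combined_smape: float

    def to_dict(self) -> dict:
        return {
            "smape_per_channel": dict(self.smape_per_channel),
            "mse_per_channel": dict(self.mse_per_channel),
            "combined_smape": self.combined_smape,
        }


def evaluate_forecast(
    true_values: np.ndarray,
    predicted_values: np.ndarray,
    channels: tuple = CHANNELS,
    zero_zero: str = "zero",
) -> EvalReport:
    """Score an aligned (minutes x channels) forecast against the truth."""
    true_values = np.atleast_2d(np.asarray(true_values, dtype=float))
    predicted_values = np.atleast_2d(np.asarray(predicted_values, dtype=float))
    if true_values.shape != predicted_values.shape:
        raise ValueError("forecast and truth must have identical shape")
    smapes = {
        c: smape(true_values[:, i], predicted_values[:, i], zero_zero=zero_zero)
        for i, c in enumerate(channels)
    }
    mses = {
        c: mse(true_values[:, i], predicted_values[:, i]) for i, c in enumerate(channels)
    }
    if len(channels) == 3:
        comb = combined_smape([smapes[c] for c in channels])
    else:
        comb = float(np.mean(list(smapes.values())))
    return EvalReport(smape_per_channel=smapes, mse_per_channel=mses, combined_smape=comb)
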
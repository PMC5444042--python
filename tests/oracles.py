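"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive each quantity with the most literal possible
loop, sharing no code with the package.
"""

from __future__ import annotations

import numpy as np


def brute_smape(y, yhat) -> float:
    """Literal term-by-term evaluation of the SMAPE sum (0/0 terms -> 0)."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    total = 0.0
    for a, b in zip(y, yhat):
        denom = (abs(a) + abs(b)) / 2.0
        if denom == 0.0:
            continue
        total += abs(b - a) / denom
    return 100.0 * total / len(y)


def brute_def1_labels(values, day_means, window_len: int, frac: float):
    """Loop-over-windows low-activeness labeler.

    ``day_means`` gives, for every minute, the mean of that minute's own
    calendar day.
    """
    labels = []
    n_windows = len(values) // window_len
    for w in range(n_windows):
        count = 0
        for i in range(w * window_len, (w + 1) * window_len):
            if values[i] < day_means[i]:
                count += 1
        labels.append(count > frac * window_len)
    return np.array(labels, dtype=bool)


def brute_vote(a: bool, b: bool, c: bool, k: int) -> bool:
    return (int(a) + int(b) + int(c)) >= k


def normal_equations(X, y):
    """Least-squares coefficients via the explicit normal equations."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.linalg.solve(X.T @ X, X.T @ y)
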
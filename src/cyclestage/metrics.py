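"""Concordance measures on a circular 0–100 cycle scale.

The percentage scale wraps at 100, so agreement between two stagings must
respect the seam: a sample placed at 99% by one model and 1% by the other is
2 points apart, not 98.  Two flavours of correlation are provided:

* :func:`circular_pearson` — Pearson correlation after unwrapping one series
  around the other (each value replaced by its nearest circular
  representative relative to the reference).  Appropriate once the two
  stagings share an origin and orientation, e.g. after alignment.
* :func:`fisher_lee_r` — the Fisher–Lee circular–circular correlation, which
  is invariant to rotations of either variable and flips sign under
  reflection; its magnitude is the natural rotation-free concordance.

Rank versions convert values to circular ranks first, making them invariant
to any monotone circular deformation of either scale.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import ArrayLike
from scipy.stats import pearsonr, rankdata

__all__ = [
    "circular_difference",
    "mean_abs_circular_difference",
    "circular_pearson",
    "fisher_lee_r",
    "circular_rank_correlation",
]


def circular_difference(a: ArrayLike, b: ArrayLike, period: float = 100.0) -> np.ndarray:
    """Signed difference a - b wrapped into [-period/2, period/2)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return np.mod(a - b + period / 2.0, period) - period / 2.0


def mean_abs_circular_difference(a: ArrayLike, b: ArrayLike, period: float = 100.0) -> float:
    return float(np.mean(np.abs(circular_difference(a, b, period))))


def circular_pearson(est: ArrayLike, ref: ArrayLike, period: float = 100.0) -> float:
    """Pearson correlation of ``est`` against ``ref`` after unwrapping
    ``est`` to the circular representative nearest each reference value."""
    ref = np.asarray(ref, dtype=float)
    unwrapped = ref + circular_difference(est, ref, period)
    if np.ptp(ref) == 0 or np.ptp(unwrapped) == 0:
        return 0.0
    return float(pearsonr(unwrapped, ref).statistic)


def fisher_lee_r(a: ArrayLike, b: ArrayLike, period_a: float = 100.0, period_b: float = 100.0) -> float:
    """Fisher–Lee circular correlation between two circular variables."""
    alpha = 2.0 * np.pi * np.asarray(a, dtype=float) / period_a
    beta = 2.0 * np.pi * np.asarray(b, dtype=float) / period_b
    da = alpha[:, None] - alpha[None, :]
    db = beta[:, None] - beta[None, :]
    num = np.sum(np.sin(da) * np.sin(db))
    den = np.sqrt(np.sum(np.sin(da) ** 2) * np.sum(np.sin(db) ** 2))
    if den == 0:
        return 0.0
    return float(num / den)


def circular_rank_correlation(a: ArrayLike, b: ArrayLike) -> float:
    """Magnitude of the Fisher–Lee correlation on circular ranks.

    Invariant to rotation and reflection of either scale, so it measures
    whether two cyclic orderings agree regardless of starting point or
    direction around the circle.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = len(a)
    ra = rankdata(a, method="average")
    rb = rankdata(b, method="average")
    return abs(fisher_lee_r(ra, rb, period_a=n, period_b=n))
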
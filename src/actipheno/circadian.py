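"""Classical rest-activity rhythm metrics and global activity statistics.

Implements the nonparametric circadian variables in their standard forms:

* M10 / L5 — per day, the maximum (minimum) mean count over consecutive
  10-hour (5-hour) windows inside the day, averaged across days.
* RA — relative amplitude (M10 - L5)/(M10 + L5).
* ADAT — grand mean count (total average daily activity per minute).
* IS — interdaily stability,
  ``IS = N * sum_h (xbar_h - xbar)^2 / (p * sum_i (x_i - xbar)^2)``
  with ``xbar_h`` the p per-time-of-day means; 1 for a perfectly repeated
  daily profile, ~1/d for d days of white noise.
* IV — intradaily variability,
  ``IV = N * sum (x_i - x_{i-1})^2 / ((N-1) * sum (x_i - xbar)^2)``,
  maximal (4, asymptotically; exactly 4 for an even-length alternating
  series) for epoch-to-epoch alternation.
* Sleep fragmentation index — fraction of a sleep bout spent moving,
  counting zero-gaps of at most ``short_immobile_max`` epochs as movement.

Undefined values (constant series, no valid night) propagate as NaN; the
feature-table layer imputes them downstream.
"""

from __future__ import annotations

import numpy as np

from .ingest import EpochSeries
from .sleep import NightActivity

__all__ = [
    "m10_l5_ra_adat",
    "interdaily_stability",
    "intradaily_variability",
    "global_stats",
    "fragmentation_index",
]


def _window_means(day: np.ndarray, width: int) -> np.ndarray:
    """Means of all consecutive windows of ``width`` epochs within a day
    (no wrap-around)."""
    if width > len(day):
        raise ValueError("window longer than day")
    c = np.concatenate([[0.0], np.cumsum(day)])
    return (c[width:] - c[:-width]) / width


def m10_l5_ra_adat(
    series: EpochSeries, *, mean_profile: bool = False
) -> tuple[float, float, float, float]:
    """(M10, L5, RA, ADAT) from a whole-day-aligned record.

    ``mean_profile=True`` scans the across-day mean 24 h profile instead
    of scanning each day separately.
    """
    days = series.day_view()
    w10 = int(round(10 * 3600 / series.epoch_len_s))
    w5 = int(round(5 * 3600 / series.epoch_len_s))
    if mean_profile:
        profile = days.mean(axis=0)
        m10 = float(_window_means(profile, w10).max())
        l5 = float(_window_means(profile, w5).min())
    else:
        m10 = float(np.mean([_window_means(day, w10).max() for day in days]))
        l5 = float(np.mean([_window_means(day, w5).min() for day in days]))
    adat = float(days.mean())
    ra = 0.0 if m10 + l5 == 0 else (m10 - l5) / (m10 + l5)
    return m10, l5, ra, adat


def interdaily_stability(series: EpochSeries, *, hourly: bool = False) -> float:
    """IS in [0, 1]; NaN for a constant record.

    Default uses the per-epoch (minute) daily profile, p = 1440 for 1-min
    epochs; ``hourly=True`` uses the classical hourly-mean variant.
    """
    days = series.day_view()
    if len(days) < 2:
        raise ValueError("IS needs at least 2 whole days")
    if hourly:
        per_hour = days.shape[1] // 24
        days = days.reshape(len(days), 24, per_hour).mean(axis=2)
    x = days.ravel()
    n = x.size
    grand = x.mean()
    denom = ((x - grand) ** 2).sum()
    if denom == 0:
        return float("nan")
    profile = days.mean(axis=0)
    p = days.shape[1]
    return float(n * ((profile - grand) ** 2).sum() / (p * denom))


def intradaily_variability(series: EpochSeries) -> float:
    """IV in [0, 4]; NaN for a constant record."""
    x = series.counts
    if len(x) < 2:
        raise ValueError("IV needs at least 2 epochs")
    n = len(x)
    denom = ((x - x.mean()) ** 2).sum()
    if denom == 0:
        return float("nan")
    return float(n * (np.diff(x) ** 2).sum() / ((n - 1) * denom))


def global_stats(series: EpochSeries) -> tuple[float, float, float]:
    """(activity_mean, activity_std, zero_ratio); SD is the population SD."""
    x = series.counts
    if len(x) == 0:
        raise ValueError("empty series")
    return float(x.mean()), float(x.std()), float((x == 0).mean())


def fragmentation_index(night: NightActivity, short_immobile_max: int = 2) -> float:
    """Fraction of a sleep bout spent in movement.

    Epochs with count > 0 are mobile; zero-runs no longer than
    ``short_immobile_max`` epochs count as movement too (brief pauses
    within a restless stretch).
    """
    x = night.counts
    if len(x) == 0:
        raise ValueError("empty night")
    mobile = x > 0
    credited = int(mobile.sum())
    n = len(x)
    i = 0
    while i < n:
        if not mobile[i]:
            j = i
            while j < n and not mobile[j]:
                j += 1
            if j - i <= short_immobile_max:
                credited += j - i
            i = j
        else:
            i += 1
    return credited / n
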
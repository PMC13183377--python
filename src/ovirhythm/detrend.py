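"""Trend removal and population averaging for egg-count series.

A mated female's egg output declines over the course of an experiment,
so raw counts E(i) are divided by a local trend estimate: a 6-point
moving average T(i). The resulting ratio series D(i) = E(i) / T(i)
fluctuates around 1 and is what the periodogram consumes. Averaging
the detrended series of many flies then suppresses individual noise and
lets a shared circadian component emerge.

Conventions (the records are short, ~36-48 bins, so they matter):

* The even window is centred with 3 neighbours on the left and 2 on the
  right of the focal bin (window 6 at index i covers i-3 .. i+2).
* Edge bins use the truncated window (partial mean) so no bins are lost.
* Where T(i) = 0 (a stretch of bins with no eggs at all) the ratio is
  undefined and D(i) is marked missing (NaN), never infinity; downstream
  stages simply omit missing bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import EggRecord, RecordError

__all__ = ["DetrendedSeries", "moving_average", "detrend",
           "detrend_record", "average_population"]


@dataclass(frozen=True)
class DetrendedSeries:
    """Dimensionless detrended ratios on the record's time grid.

    ``values`` uses NaN for missing bins. ``n`` (present on averaged
    series) counts the contributing flies per bin.
    """

    times_h: np.ndarray
    values: np.ndarray
    source_fly: str = ""
    n: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "times_h", np.asarray(self.times_h, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.times_h) != len(self.values):
            raise RecordError("times_h and values must have equal length")

    def dropna(self):
        """(times, values) restricted to non-missing bins."""
        ok = ~np.isnan(self.values)
        return self.times_h[ok], self.values[ok]


def moving_average(record: EggRecord, window: int = 6) -> np.ndarray:
    """Trend series T: centred moving average of the counts.

    Window 6 at index i averages counts[i-3 .. i+2]; edge bins average
    over the part of the window that exists, so len(T) == len(record).
    """
    if window < 2:
        raise RecordError(f"window must be >= 2, got {window}")
    n = len(record)
    if n < window:
        raise RecordError(f"record {record.fly_id!r} has {n} bins, shorter than window {window}")
    counts = np.asarray(record.counts, dtype=float)
    left = window // 2
    right = window - left - 1
    csum = np.concatenate([[0.0], np.cumsum(counts)])
    i = np.arange(n)
    lo = np.maximum(i - left, 0)
    hi = np.minimum(i + right, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi + 1 - lo)


def detrend(record: EggRecord, trend: np.ndarray) -> DetrendedSeries:
    """Pointwise ratio D(i) = E(i) / T(i); bins with T(i) = 0 are missing."""
    trend = np.asarray(trend, dtype=float)
    if len(trend) != len(record):
        raise RecordError(
            f"trend length {len(trend)} != record length {len(record)}"
        )
    counts = np.asarray(record.counts, dtype=float)
    values = np.full(len(record), np.nan)
    ok = trend > 0
    values[ok] = counts[ok] / trend[ok]
    return DetrendedSeries(times_h=record.times_h, values=values,
                           source_fly=record.fly_id)


def detrend_record(record: EggRecord, window: int = 6) -> DetrendedSeries:
    """Convenience: moving-average trend then pointwise division."""
    return detrend(record, moving_average(record, window))


def average_population(series: list) -> DetrendedSeries:
    """Per-bin mean over flies, ignoring missing bins.

    All series must share a time grid. Bins where no fly contributes stay
    missing. The per-bin contributor count is reported in ``n``. The
    result is invariant to the order of the input series.
    """
    if not series:
        raise RecordError("no detrended series to average")
    grid = series[0].times_h
    for s in series[1:]:
        if len(s.times_h) != len(grid) or not np.allclose(s.times_h, grid):
            raise RecordError(f"series {s.source_fly!r} is not on the common time grid")
    stack = np.vstack([s.values for s in series])
    n = np.sum(~np.isnan(stack), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, np.nansum(stack, axis=0) / np.maximum(n, 1), np.nan)
    return DetrendedSeries(times_h=grid, values=mean,
                           source_fly="population-average", n=n)
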
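"""Calendar-aware daily series, rolling aggregation and climatological samples.

A :class:`DailySeries` is a strictly contiguous daily sequence of one variable
with NaN as the missing marker.  A :class:`ClimatologicalSample` collects, for
one calendar day (month, day) and one aggregation length k, the cross-year
values against which a single day is standardized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    CalendarError,
    InsufficientClimatologyError,
    InvalidInputError,
    InvalidParameterError,
)

__all__ = [
    "DailySeries",
    "AggregationScheme",
    "ClimatologicalSample",
    "aggregate_rolling",
    "default_aggregation_periods",
    "climatological_sample",
]


@dataclass(frozen=True)
class DailySeries:
    """One variable on a contiguous daily calendar; NaN marks missing."""

    index: pd.DatetimeIndex
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        idx = pd.DatetimeIndex(self.index)
        vals = np.asarray(self.values, dtype=float)
        if len(idx) != len(vals):
            raise InvalidInputError(
                f"dates ({len(idx)}) and values ({len(vals)}) differ in length"
            )
        if len(idx) == 0:
            raise InvalidInputError("series must not be empty")
        deltas = np.diff(idx.asi8)
        if len(deltas) and not (deltas == 86_400_000_000_000).all():
            raise CalendarError("dates must be strictly increasing with step 1 day")
        if np.isinf(vals).any():
            raise InvalidInputError("values must be finite or NaN, not infinite")
        object.__setattr__(self, "index", idx)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.index)

    @classmethod
    def from_series(cls, s: pd.Series, units: str = "") -> "DailySeries":
        return cls(pd.DatetimeIndex(s.index), s.to_numpy(dtype=float), units)

    def to_series(self, name: str | None = None) -> pd.Series:
        return pd.Series(self.values, index=self.index, name=name)

    def same_calendar(self, other: "DailySeries") -> bool:
        return len(self.index) == len(other.index) and (
            self.index == other.index
        ).all()


@dataclass(frozen=True)
class AggregationScheme:
    """Ordered list of aggregation lengths k (in days)."""

    periods: tuple[int, ...]

    def __post_init__(self) -> None:
        periods = tuple(int(k) for k in self.periods)
        if not periods:
            raise InvalidParameterError("scheme must contain at least one period")
        if any(k < 1 for k in periods):
            raise InvalidParameterError("all aggregation periods must be >= 1")
        if any(b <= a for a, b in zip(periods, periods[1:])):
            raise InvalidParameterError("periods must be strictly increasing")
        object.__setattr__(self, "periods", periods)

    def __iter__(self):
        return iter(self.periods)

    def __len__(self) -> int:
        return len(self.periods)


def default_aggregation_periods() -> AggregationScheme:
    """The published scheme: 5..365 step 5, then 370..720 step 10 (109 values)."""
    periods = tuple(range(5, 366, 5)) + tuple(range(370, 721, 10))
    return AggregationScheme(periods)


@dataclass(frozen=True)
class ClimatologicalSample:
    """Cross-year sample for one calendar day and one aggregation length.

    ``year_labels`` may repeat only when Feb 29 is pooled with Feb 28 (a leap
    year then contributes two values); otherwise they are unique.
    """

    month_day: tuple[int, int]
    period_k: int
    year_labels: tuple[int, ...]
    sample_values: np.ndarray
    pooled: bool = field(default=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.sample_values, dtype=float)
        if len(vals) != len(self.year_labels):
            raise InvalidInputError("year_labels and sample_values lengths differ")
        if not np.isfinite(vals).all():
            raise InvalidInputError("climatological sample must not contain missing")
        if not self.pooled and len(set(self.year_labels)) != len(self.year_labels):
            raise InvalidInputError("year labels must be unique")
        object.__setattr__(self, "sample_values", vals)
        object.__setattr__(self, "year_labels", tuple(int(y) for y in self.year_labels))

    @property
    def n(self) -> int:
        return len(self.sample_values)


def aggregate_rolling(
    series: DailySeries, k: int, completeness: float = 0.9
) -> DailySeries:
    """Trailing k-day rolling sum ending on (and including) each day.

    The aggregate on day j sums days j-k+1 .. j.  It is missing whenever fewer
    than ``ceil(completeness * k)`` window values are present, and always for
    the first k-1 days (no full window exists yet).
    """
    k = int(k)
    if k < 1:
        raise InvalidParameterError(f"aggregation length k must be >= 1, got {k}")
    min_count = max(1, math.ceil(completeness * k))
    s = series.to_series()
    agg = s.rolling(window=k, min_periods=min_count).sum()
    if k > 1:
        agg.iloc[: k - 1] = np.nan
    return DailySeries(series.index, agg.to_numpy(), series.units)


def _pool_mask(index: pd.DatetimeIndex, month: int, day: int, window: int) -> np.ndarray:
    """Boolean mask of calendar days within ``window`` days of (month, day).

    Distance is computed on a fixed non-leap day-of-year scale, wrapping at
    the year boundary, so pooling is leap-safe.
    """
    ref = pd.Timestamp(2001, month, day).dayofyear
    # map all dates onto the 365-day scale; Feb 29 rides with Feb 28
    m, d = index.month.to_numpy(), index.day.to_numpy()
    feb29 = (m == 2) & (d == 29)
    d_eff = np.where(feb29, 28, d)
    doy = np.array(
        [pd.Timestamp(2001, mm, dd).dayofyear for mm, dd in zip(m, d_eff)]
    )
    dist = np.abs(doy - ref)
    dist = np.minimum(dist, 365 - dist)
    return dist <= window


def climatological_sample(
    series: DailySeries,
    month_day: tuple[int, int],
    period_k: int,
    min_sample_size: int = 30,
    feb29_pooling: bool = True,
    day_pooling_window: int = 0,
) -> ClimatologicalSample:
    """Cross-year sample of the (already aggregated) series at one calendar day.

    Years with a missing value on that day are excluded.  With
    ``feb29_pooling`` (the default) Feb 28 and Feb 29 share one pooled sample.
    ``day_pooling_window`` > 0 additionally pools +/- that many neighbouring
    calendar days (for users with short records).
    """
    month, day = int(month_day[0]), int(month_day[1])
    try:
        pd.Timestamp(2000, month, day)  # 2000 is leap: validates Feb 29 too
    except ValueError as exc:
        raise InvalidParameterError(f"invalid calendar day {month_day}") from exc

    idx, vals = series.index, series.values
    pooled = False
    if day_pooling_window > 0:
        mask = _pool_mask(idx, month, day, day_pooling_window)
        pooled = True
    elif feb29_pooling and (month, day) in ((2, 28), (2, 29)):
        mask = (idx.month == 2) & ((idx.day == 28) | (idx.day == 29))
        pooled = True
    else:
        mask = (idx.month.to_numpy() == month) & (idx.day.to_numpy() == day)

    ok = mask & np.isfinite(vals)
    years = idx.year.to_numpy()[ok]  # date order == ascending years
    sample = vals[ok]

    if len(sample) < min_sample_size:
        raise InsufficientClimatologyError(
            f"calendar day {month:02d}-{day:02d}: only {len(sample)} contributing "
            f"years, need >= {min_sample_size} (robust estimation requires 30 "
            "years of data at least)"
        )
    return ClimatologicalSample(
        month_day=(month, day),
        period_k=int(period_k),
        year_labels=tuple(years),
        sample_values=sample,
        pooled=pooled,
    )
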
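"""Validation statistics and exploratory analyses.

nRMSE and R² compare paired series; ``doy_zscore`` removes seasonality by
standardizing each calendar day against its own cross-year statistics; and
``rolling_correlation_field`` correlates a seasonally-adjusted response with
every aggregation column of an SDI table over short calendar windows pooled
across years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import Settings
from .errors import InvalidInputError, UndefinedNormalizationError
from .pipeline import SdiTable
from .timeseries import DailySeries

__all__ = [
    "nrmse",
    "r_squared",
    "standardize",
    "doy_zscore",
    "CorrelationField",
    "rolling_correlation_field",
]

log = logging.getLogger(__name__)


def _paired(obs, sim) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(obs, dtype=float)
    sim = np.asarray(sim, dtype=float)
    if obs.shape != sim.shape:
        raise InvalidInputError("obs and sim must have identical shape")
    ok = np.isfinite(obs) & np.isfinite(sim)
    return obs[ok], sim[ok]


def nrmse(obs, sim, normalization: str = "sd") -> float:
    """RMSE of sim vs obs divided by sd (default), mean or range of obs."""
    o, s = _paired(obs, sim)
    if len(o) < 2:
        raise InvalidInputError("need at least 2 paired values")
    rmse = float(np.sqrt(np.mean((s - o) ** 2)))
    if normalization == "sd":
        denom = float(np.std(o, ddof=1))
    elif normalization == "mean":
        denom = float(np.mean(o))
    elif normalization == "range":
        denom = float(np.ptp(o))
    else:
        raise InvalidInputError(f"unknown normalization {normalization!r}")
    if denom == 0.0 or not np.isfinite(denom):
        raise UndefinedNormalizationError(
            f"normalization denominator ({normalization}) is zero"
        )
    return rmse / denom


def r_squared(obs, sim) -> float:
    """Square of the Pearson correlation of the paired values."""
    o, s = _paired(obs, sim)
    if len(o) < 3:
        raise InvalidInputError("need at least 3 paired values")
    so, ss = np.std(o), np.std(s)
    if so == 0.0 or ss == 0.0:
        raise UndefinedNormalizationError("zero variance; correlation undefined")
    r = float(np.corrcoef(o, s)[0, 1])
    return r * r


def standardize(series: DailySeries) -> DailySeries:
    """(x - mean)/sd over the non-missing entries."""
    vals = series.values
    ok = np.isfinite(vals)
    sd = float(np.std(vals[ok], ddof=1))
    if not sd > 0:
        raise UndefinedNormalizationError("zero variance; cannot standardize")
    out = np.full_like(vals, np.nan)
    out[ok] = (vals[ok] - np.mean(vals[ok])) / sd
    return DailySeries(series.index, out, "standardized")


def doy_zscore(series: DailySeries, min_years: int = 3) -> DailySeries:
    """Standardize each value against its own calendar day across years.

    Feb 29 is pooled with Feb 28.  Days with fewer than ``min_years``
    contributing years or zero cross-year variance come out missing.
    """
    idx, vals = series.index, series.values
    out = np.full_like(vals, np.nan)
    months = idx.month.to_numpy()
    days = idx.day.to_numpy()
    eff = days.copy()
    eff[(months == 2) & (days == 29)] = 28
    frame = pd.DataFrame({"m": months, "d": eff, "pos": np.arange(len(vals))})
    for (mm, dd), grp in frame.groupby(["m", "d"], sort=False):
        pos = grp["pos"].to_numpy()
        x = vals[pos]
        ok = np.isfinite(x)
        if ok.sum() < min_years:
            continue
        sd = np.std(x[ok], ddof=1)
        if np.ptp(x[ok]) == 0.0 or sd == 0.0:
            log.warning("calendar day %02d-%02d: zero variance; missing", mm, dd)
            continue
        out[pos[ok]] = (x[ok] - np.mean(x[ok])) / sd
    return DailySeries(idx, out, "z-score")


@dataclass(frozen=True)
class CorrelationField:
    """Calendar-day x aggregation-column grid of Pearson correlations."""

    frame: pd.DataFrame  # rows: (month, day); cols: SDI column names


def rolling_correlation_field(
    response_z: DailySeries,
    sdi_table: SdiTable,
    window_days: int = 14,
    settings: Settings | None = None,
    min_pairs: int = 3,
) -> CorrelationField:
    """Windowed Pearson correlation of a response vs each SDI column.

    For each calendar day in the configured season and each SDI column, the
    correlation pools all paired values whose calendar position falls in the
    trailing (or centered) ``window_days`` window, across every year.
    """
    settings = settings or Settings()
    if window_days < min_pairs:
        raise InvalidInputError(f"window_days must be >= {min_pairs}")
    idx = response_z.index
    tbl = sdi_table.frame
    if len(tbl.index) != len(idx) or not (pd.DatetimeIndex(tbl.index) == idx).all():
        raise InvalidInputError("response and SDI table must share one calendar")

    months = idx.month.to_numpy()
    days = idx.day.to_numpy()
    eff = days.copy()
    eff[(months == 2) & (days == 29)] = 28
    # non-leap day-of-year position of every date
    doy = np.array(
        [pd.Timestamp(2001, mm, dd).dayofyear for mm, dd in zip(months, eff)]
    )

    m0, m1 = settings.season_months
    season_days = [
        (ts.month, ts.day)
        for ts in pd.date_range("2001-01-01", "2001-12-31", freq="D")
        if m0 <= ts.month <= m1
    ]
    resp = response_z.values
    cols = sdi_table.columns
    out = np.full((len(season_days), len(cols)), np.nan)
    for i, (mm, dd) in enumerate(season_days):
        center = pd.Timestamp(2001, mm, dd).dayofyear
        if settings.rolling_window_centered:
            half = window_days // 2
            lo, hi = center - half, center - half + window_days - 1
        else:
            lo, hi = center - window_days + 1, center
        d = doy - center
        d = np.where(d > 182, d - 365, np.where(d < -182, d + 365, d))
        in_win = (d >= lo - center) & (d <= hi - center)
        for j, col in enumerate(cols):
            x = resp[in_win]
            y = tbl[col].to_numpy(dtype=float)[in_win]
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < min_pairs:
                continue
            xs, ys = x[ok], y[ok]
            if np.std(xs) == 0.0 or np.std(ys) == 0.0:
                continue
            out[i, j] = np.corrcoef(xs, ys)[0, 1]
    frame = pd.DataFrame(out, index=pd.MultiIndex.from_tuples(
        season_days, names=["month", "day"]), columns=cols)
    return CorrelationField(frame)
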
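"""Site-level orchestration: aggregation -> per-day climatology -> KDE -> SDI.

For every aggregation length k and every calendar day (month, day) the
cross-year sample of aggregated values is fitted with a KDE (zero-inflated
for precipitation) and each year's value is transformed to its standardized
score.  Computation is strictly per calendar day — any output value can be
reproduced by rebuilding that one day's climatology in isolation — and fully
deterministic.

Calendar days whose climatology is undersized or degenerate yield missing
values with a logged warning rather than aborting the site.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import Settings
from .errors import AlignmentError, DegenerateSampleError, InvalidInputError
from .kde import fit_kde, kde_cdf
from .timeseries import AggregationScheme, DailySeries, _pool_mask, aggregate_rolling
from .transform import (
    clip_probability,
    fit_zero_inflated,
    probability_to_sdi,
    zero_inflated_cdf,
)

__all__ = ["SdiTable", "compute_spi", "compute_spei", "compute_ssmi", "water_balance"]

log = logging.getLogger(__name__)

_COLUMN_RE = re.compile(r"^(SPI|SPEI)_(\d+)$|^SSMI_(top|full)$")


@dataclass(frozen=True)
class SdiTable:
    """Daily table of standardized-index columns (SPI_k / SPEI_k / SSMI_*)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        for col in self.frame.columns:
            if not _COLUMN_RE.match(str(col)):
                raise InvalidInputError(f"invalid SDI column name {col!r}")

    @property
    def index(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.frame.index)

    @property
    def columns(self) -> list[str]:
        return [str(c) for c in self.frame.columns]


def _standardized_column(
    agg: DailySeries, variable_kind: str, settings: Settings
) -> np.ndarray:
    """Per-calendar-day standardization of an (aggregated) daily series."""
    idx, vals = agg.index, agg.values
    out = np.full(len(vals), np.nan)
    finite = np.isfinite(vals)

    months = idx.month.to_numpy()
    days = idx.day.to_numpy()
    eff_days = days.copy()
    if settings.feb29_pooling:
        eff_days[(months == 2) & (days == 29)] = 28

    frame = pd.DataFrame({"m": months, "d": eff_days, "pos": np.arange(len(vals))})
    for (mm, dd), grp in frame.groupby(["m", "d"], sort=True):
        pos = grp["pos"].to_numpy()
        targets = pos[finite[pos]]
        if len(targets) == 0:
            continue
        if settings.day_pooling_window > 0:
            mask = _pool_mask(idx, int(mm), int(dd), settings.day_pooling_window)
            sample = vals[mask & finite]
        else:
            sample = vals[targets]
        if len(sample) < settings.min_sample_size:
            log.warning(
                "calendar day %02d-%02d: climatology n=%d < %d; leaving missing",
                mm, dd, len(sample), settings.min_sample_size,
            )
            continue
        try:
            if variable_kind == "precipitation":
                model = fit_zero_inflated(
                    sample, settings.wet_day_threshold, settings.bandwidth_method
                )
                f = zero_inflated_cdf(model, vals[targets])
            else:
                if np.ptp(sample) == 0.0:
                    raise DegenerateSampleError("constant cross-year sample")
                model = fit_kde(sample, method=settings.bandwidth_method)
                f = kde_cdf(model, vals[targets])
        except DegenerateSampleError as exc:
            log.warning(
                "calendar day %02d-%02d: degenerate climatology (%s); missing",
                mm, dd, exc,
            )
            continue
        out[targets] = probability_to_sdi(clip_probability(f, len(sample)))
    return out


def compute_spi(
    precip: DailySeries,
    scheme: AggregationScheme,
    settings: Settings | None = None,
) -> SdiTable:
    """SPI for every aggregation length: zero-inflated KDE on summed rainfall."""
    settings = settings or Settings()
    finite = np.isfinite(precip.values)
    if (precip.values[finite] < 0).any():
        raise InvalidInputError("precipitation must be >= 0")
    data = {}
    for k in scheme:
        agg = aggregate_rolling(precip, k, settings.completeness)
        data[f"SPI_{k}"] = _standardized_column(agg, "precipitation", settings)
    return SdiTable(pd.DataFrame(data, index=precip.index))


def water_balance(precip: DailySeries, pet: DailySeries) -> DailySeries:
    """Daily climatic water balance D = P - PET (missing where either is)."""
    if not precip.same_calendar(pet):
        raise AlignmentError("precipitation and PET must share one daily calendar")
    return DailySeries(precip.index, precip.values - pet.values, "mm")


def compute_spei(
    precip: DailySeries,
    pet: DailySeries,
    scheme: AggregationScheme,
    settings: Settings | None = None,
) -> SdiTable:
    """SPEI: plain-KDE standardization of the aggregated water balance."""
    settings = settings or Settings()
    d = water_balance(precip, pet)
    data = {}
    for k in scheme:
        agg = aggregate_rolling(d, k, settings.completeness)
        data[f"SPEI_{k}"] = _standardized_column(agg, "water_balance", settings)
    return SdiTable(pd.DataFrame(data, index=precip.index))


def compute_ssmi(
    sm: DailySeries,
    layer_label: str = "top",
    settings: Settings | None = None,
) -> SdiTable:
    """SSMI on raw daily soil moisture — no aggregation (soil moisture already
    integrates past meteorology)."""
    settings = settings or Settings()
    if layer_label not in ("top", "full"):
        raise InvalidInputError(f"layer_label must be 'top' or 'full', got {layer_label!r}")
    finite = np.isfinite(sm.values)
    vals = sm.values[finite]
    if ((vals < 0) | (vals > 1)).any():
        raise InvalidInputError("soil moisture must lie within [0, 1]")
    col = _standardized_column(sm, "soil_moisture", settings)
    return SdiTable(pd.DataFrame({f"SSMI_{layer_label}": col}, index=sm.index))
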
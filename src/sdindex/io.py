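"""Readers/writers for the per-site CSV layouts.

File 1 is the site input table (Date, Doy, lon, lat, PREC, TG, TN, TX, PET,
RG, AET, SM_top, SM_full); files 2-4 are the index tables
(``SSMI_[site].csv``, ``SPI_[site].csv``, ``SPEI_[site].csv``) with a Date
column plus one column per index.  Missing values are written as empty fields;
dates are ISO-8601.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CalendarError, InvalidInputError, SchemaError
from .pipeline import SdiTable
from .timeseries import DailySeries

__all__ = [
    "INPUT_COLUMNS",
    "SiteInput",
    "read_site_input",
    "write_site_input",
    "write_index_files",
    "read_index_file",
]

log = logging.getLogger(__name__)

INPUT_COLUMNS = [
    "Date", "Doy", "lon", "lat", "PREC", "TG", "TN", "TX",
    "PET", "RG", "AET", "SM_top", "SM_full",
]

_UNITS = {
    "PREC": "mm", "TG": "degC", "TN": "degC", "TX": "degC",
    "PET": "mm", "RG": "MJ m-2 day-1", "AET": "mm",
    "SM_top": "dimensionless", "SM_full": "dimensionless",
}


@dataclass(frozen=True)
class SiteInput:
    """Validated site input bundle: the raw frame plus typed daily series."""

    frame: pd.DataFrame
    index: pd.DatetimeIndex
    lat: float
    lon: float

    def series(self, column: str) -> DailySeries:
        if column not in _UNITS:
            raise SchemaError(f"unknown variable column {column!r}")
        return DailySeries(
            self.index, self.frame[column].to_numpy(dtype=float), _UNITS[column]
        )


def _validate_range(
    frame: pd.DataFrame, column: str, lo: float, hi: float, strict: bool
) -> None:
    vals = frame[column].to_numpy(dtype=float)
    bad = np.isfinite(vals) & ((vals < lo) | (vals > hi))
    if not bad.any():
        return
    msg = f"{column}: {int(bad.sum())} value(s) outside [{lo}, {hi}]"
    if strict:
        raise InvalidInputError(msg)
    log.warning("%s; set to missing", msg)
    vals[bad] = np.nan
    frame[column] = vals


def read_site_input(path: str | Path, strict: bool = True) -> SiteInput:
    """Read and validate a ``[site]_input.csv`` table."""
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in INPUT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing mandatory column(s) {missing}")
    dates = pd.to_datetime(frame["Date"], format="%Y-%m-%d")
    idx = pd.DatetimeIndex(dates)
    deltas = np.diff(idx.asi8)
    if len(deltas) and not (deltas == 86_400_000_000_000).all():
        raise CalendarError(f"{path.name}: dates are not contiguous daily")
    _validate_range(frame, "PREC", 0.0, np.inf, strict)
    _validate_range(frame, "SM_top", 0.0, 1.0, strict)
    _validate_range(frame, "SM_full", 0.0, 1.0, strict)
    lat = float(frame["lat"].iloc[0])
    lon = float(frame["lon"].iloc[0])
    return SiteInput(frame=frame, index=idx, lat=lat, lon=lon)


def _write_csv(frame: pd.DataFrame, path: Path, decimals: int) -> None:
    try:
        frame.to_csv(path, index=False, float_format=f"%.{decimals}f", na_rep="")
    except OSError as exc:
        raise OSError(f"failed writing {path}: {exc}") from exc


def write_site_input(
    frame: pd.DataFrame, path: str | Path, decimals: int = 4
) -> None:
    """Write a site input table with the canonical column order."""
    missing = [c for c in INPUT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"cannot write input table; missing column(s) {missing}")
    _write_csv(frame[INPUT_COLUMNS], Path(path), decimals)


def write_index_files(
    site_name: str,
    tables: dict[str, SdiTable],
    outdir: str | Path,
    decimals: int = 4,
) -> list[Path]:
    """Write ``{INDEX}_{site}.csv`` per table; keys are SPI / SPEI / SSMI."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for kind, table in tables.items():
        if kind not in ("SPI", "SPEI", "SSMI"):
            raise InvalidInputError(f"unknown index table kind {kind!r}")
        out = table.frame.copy()
        out.insert(0, "Date", table.index.strftime("%Y-%m-%d"))
        path = outdir / f"{kind}_{site_name}.csv"
        _write_csv(out, path, decimals)
        written.append(path)
    return written


def read_index_file(path: str | Path) -> SdiTable:
    """Read an index CSV back into an :class:`SdiTable`."""
    frame = pd.read_csv(path)
    if "Date" not in frame.columns:
        raise SchemaError(f"{Path(path).name}: missing Date column")
    idx = pd.DatetimeIndex(pd.to_datetime(frame.pop("Date"), format="%Y-%m-%d"))
    frame.index = idx
    return SdiTable(frame.astype(float))
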
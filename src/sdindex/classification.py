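"""Drought category schemes and the cross-site drought-area fraction.

Three published schemes map a standardized index to severity classes.  All
boundaries are strict "<" comparisons: a value exactly on a threshold falls to
the milder class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = ["ClassificationScheme", "SCHEMES", "classify", "drought_area_fraction",
           "NO_DROUGHT"]

NO_DROUGHT = "no drought"


@dataclass(frozen=True)
class ClassificationScheme:
    """Ordered (upper bound, label) pairs; most severe category first."""

    name: str
    thresholds: tuple[tuple[float, str], ...]

    def __post_init__(self) -> None:
        bounds = [b for b, _ in self.thresholds]
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise InvalidParameterError("thresholds must be strictly increasing")


SCHEMES: dict[str, ClassificationScheme] = {
    "mckee": ClassificationScheme(
        "mckee",
        (
            (-2.00, "extreme"),
            (-1.50, "severe"),
            (-1.00, "moderate"),
            (0.00, "mild"),
        ),
    ),
    "agnew": ClassificationScheme(
        "agnew",
        (
            (-1.65, "extreme"),
            (-1.28, "severe"),
            (-0.84, "moderate"),
        ),
    ),
    "usdm": ClassificationScheme(
        "usdm",
        (
            (-2.00, "D4"),
            (-1.65, "D3"),
            (-1.28, "D2"),
            (-0.84, "D1"),
            (-0.50, "D0"),
        ),
    ),
}


def _scheme(scheme: str | ClassificationScheme) -> ClassificationScheme:
    if isinstance(scheme, ClassificationScheme):
        return scheme
    try:
        return SCHEMES[scheme]
    except KeyError:
        raise InvalidParameterError(
            f"unknown scheme {scheme!r}; expected one of {sorted(SCHEMES)}"
        ) from None


def classify(sdi: float, scheme: str | ClassificationScheme) -> str:
    """Category label for one SDI value (``"no drought"`` above all bounds)."""
    sch = _scheme(scheme)
    if not np.isfinite(sdi):
        raise InvalidParameterError("sdi must be finite")
    for bound, label in sch.thresholds:
        if sdi < bound:
            return label
    return NO_DROUGHT


def classify_series(values, scheme: str | ClassificationScheme) -> np.ndarray:
    """Vectorized :func:`classify`; NaN maps to an empty label."""
    sch = _scheme(scheme)
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape, NO_DROUGHT, dtype=object)
    for bound, label in reversed(sch.thresholds):
        out[values < bound] = label
    out[~np.isfinite(values)] = ""
    return out


def drought_area_fraction(
    sdi_matrix: pd.DataFrame,
    scheme: str | ClassificationScheme,
    category: str,
    or_worse: bool = True,
) -> pd.Series:
    """Per-day share of sites at the given category (or worse).

    ``sdi_matrix`` has days as rows and sites as columns.  The denominator
    counts only sites with a non-missing SDI that day; days with no valid site
    are missing.
    """
    sch = _scheme(scheme)
    labels = [lab for _, lab in sch.thresholds]
    if category not in labels:
        raise InvalidParameterError(
            f"category {category!r} not in scheme {sch.name!r} ({labels})"
        )
    bound = dict((lab, b) for b, lab in sch.thresholds)[category]
    vals = sdi_matrix.to_numpy(dtype=float)
    valid = np.isfinite(vals)
    if or_worse:
        hit = valid & (vals < bound)
    else:
        idx = labels.index(category)
        lower = -np.inf if idx == 0 else sch.thresholds[idx - 1][0]
        hit = valid & (vals < bound) & (vals >= lower)
    denom = valid.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(denom > 0, hit.sum(axis=1) / denom, np.nan)
    return pd.Series(frac, index=sdi_matrix.index, name=f"{sch.name}_{category}")
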
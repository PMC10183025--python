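"""Latitude-only extraterrestrial radiation and Hargreaves-Samani PET.

Radiation needs nothing but latitude and day of year: solar declination,
inverse relative Earth-Sun distance and the sunrise hour angle combine into a
top-of-atmosphere energy flux in MJ m^-2 day^-1 (multiply by 11.574 for
W m^-2).  PET follows from that flux and the daily temperature range.

All functions accept scalars or numpy arrays and broadcast.
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "solar_declination",
    "inverse_relative_distance",
    "sunrise_hour_angle",
    "extraterrestrial_radiation",
    "hargreaves_pet",
]

log = logging.getLogger(__name__)

#: conversion of the solar constant term to MJ m^-2 day^-1
_SOLAR = 0.082
_ANOMALISTIC_YEAR = 365.25


def _check_doy(doy) -> np.ndarray:
    doy = np.asarray(doy, dtype=float)
    if ((doy < 1) | (doy > 366)).any():
        raise InvalidParameterError("day of year must be within 1..366")
    return doy


def solar_declination(doy) -> np.ndarray | float:
    """Solar declination delta (radians); |delta| <= 0.409."""
    doy = _check_doy(doy)
    out = 0.409 * np.sin(2.0 * np.pi * doy / _ANOMALISTIC_YEAR - 1.39)
    return out if out.ndim else float(out)


def inverse_relative_distance(doy) -> np.ndarray | float:
    """Inverse relative Earth-Sun distance dr (dimensionless, in [0.967, 1.033])."""
    doy = _check_doy(doy)
    out = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / _ANOMALISTIC_YEAR)
    return out if out.ndim else float(out)


def sunrise_hour_angle(lat_rad, delta_rad) -> np.ndarray | float:
    """Sunrise hour angle omega (radians).

    The arccos argument is clamped to [-1, 1]: omega = pi under polar day and
    omega = 0 under polar night.
    """
    lat = np.asarray(lat_rad, dtype=float)
    if (np.abs(lat) >= np.pi / 2).any():
        raise InvalidParameterError("latitude must satisfy |lat| < pi/2 radians")
    arg = -np.tan(lat) * np.tan(np.asarray(delta_rad, dtype=float))
    out = np.arccos(np.clip(arg, -1.0, 1.0))
    return out if out.ndim else float(out)


def extraterrestrial_radiation(lat_rad, doy) -> np.ndarray | float:
    """Top-of-atmosphere radiation RG (MJ m^-2 day^-1) from latitude + doy.

    Nonnegative by construction: the hour-angle clamping sends the polar-night
    geometry to zero, and any residual negative rounding is floored.
    """
    doy = _check_doy(doy)
    lat = np.asarray(lat_rad, dtype=float)
    delta = np.asarray(solar_declination(doy))
    dr = np.asarray(inverse_relative_distance(doy))
    omega = np.asarray(sunrise_hour_angle(lat, delta))
    rg = (
        (24.0 * 60.0)
        / np.pi
        * _SOLAR
        * dr
        * (
            omega * np.sin(lat) * np.sin(delta)
            + np.cos(lat) * np.cos(delta) * np.sin(omega)
        )
    )
    out = np.maximum(rg, 0.0)
    return out if out.ndim else float(out)


def hargreaves_pet(
    tg,
    tx,
    tn,
    rg,
    coefficient: float = 0.00023,
    floor_negative: bool = True,
) -> np.ndarray | float:
    """Hargreaves-Samani potential evapotranspiration (mm/day).

    PET = coefficient * RG * sqrt(TX - TN) * (TG + 17.8), floored at zero when
    TG < -17.8 degC (a negative evaporative demand is unphysical).

    Parameters
    ----------
    tg, tx, tn : daily mean / max / min air temperature (degC)
    rg : extraterrestrial radiation (MJ m^-2 day^-1)
    """
    tg = np.asarray(tg, dtype=float)
    tx = np.asarray(tx, dtype=float)
    tn = np.asarray(tn, dtype=float)
    rg = np.asarray(rg, dtype=float)
    if (tx < tn - 1e-9).any():
        raise InvalidInputError("TX must be >= TN")
    if (rg < 0).any():
        raise InvalidInputError("RG must be >= 0")
    rng = np.maximum(tx - tn, 0.0)
    pet = coefficient * rg * np.sqrt(rng) * (tg + 17.8)
    if floor_negative:
        neg = pet < 0
        if neg.any():
            log.warning(
                "PET floored at 0 for %d day(s) with TG < -17.8 degC", int(neg.sum())
            )
            pet = np.maximum(pet, 0.0)
    return pet if pet.ndim else float(pet)
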
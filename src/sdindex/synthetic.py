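"""Seeded synthetic weather: multi-decade site tables and known-distribution draws.

``generate_site`` emulates the statistical structure the pipeline assumes —
zero-inflated seasonal precipitation, a seasonal temperature cycle with AR(1)
noise and TN <= TG <= TX, radiation/PET from latitude, and a minimal leaky
soil bucket giving bounded autocorrelated moisture.  It makes no claim of
hydrological fidelity; it exists to exercise the pipeline end to end.

``generate_known_distribution`` draws i.i.d. daily values from a zero-inflated
Gamma and returns an exact-CDF oracle (including the k-day-sum mixture) — the
ground truth for KDE recovery tests.

One integer seed drives independent substreams per variable, so adding a
variable never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateSampleError, InvalidParameterError
from .pet import extraterrestrial_radiation, hargreaves_pet
from .timeseries import DailySeries

__all__ = [
    "SyntheticSiteConfig",
    "generate_site",
    "GammaMixtureOracle",
    "generate_known_distribution",
]


@dataclass(frozen=True)
class SyntheticSiteConfig:
    years: int = 72
    start_year: int = 1950
    latitude: float = 50.0
    longitude: float = 10.0
    #: wet-day probability in mid-winter / mid-summer (linearly blended by a
    #: cosine weight over the year)
    occ_winter: float = 0.55
    occ_summer: float = 0.40
    gamma_shape_winter: float = 0.8
    gamma_shape_summer: float = 1.0
    gamma_scale_winter: float = 4.0
    gamma_scale_summer: float = 6.0
    t_mean: float = 8.0
    t_amplitude: float = 9.0
    t_daily_range: float = 8.0
    t_ar1: float = 0.7
    t_noise_sd: float = 2.0
    bucket_capacity_top: float = 60.0
    bucket_capacity_full: float = 300.0
    drainage: float = 0.8
    sm_initial: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.occ_winter, self.occ_summer):
            if not 0.0 <= p <= 1.0:
                raise InvalidParameterError("occurrence probabilities must be in [0,1]")
        for g in (
            self.gamma_shape_winter,
            self.gamma_shape_summer,
            self.gamma_scale_winter,
            self.gamma_scale_summer,
        ):
            if not g > 0:
                raise InvalidParameterError("Gamma parameters must be > 0")
        if not 0.0 <= self.t_ar1 < 1.0:
            raise InvalidParameterError("AR(1) coefficient must be in [0, 1)")
        if not (self.bucket_capacity_top > 0 and self.bucket_capacity_full > 0):
            raise InvalidParameterError("bucket capacities must be > 0")
        if self.years < 1:
            raise InvalidParameterError("years must be >= 1")


def _season_weight(doy: np.ndarray) -> np.ndarray:
    """1 at mid-January, 0 at mid-July, cosine in between."""
    return 0.5 * (1.0 + np.cos(2.0 * np.pi * (doy - 15.0) / 365.25))


def _bucket(prec, pet, capacity, drainage, sm0) -> np.ndarray:
    sm = np.empty(len(prec))
    s = sm0
    for t in range(len(prec)):
        sm[t] = s
        s = s + (prec[t] - pet[t] * s - drainage * s) / capacity
        s = min(max(s, 0.0), 1.0)
    return sm


def generate_site(config: SyntheticSiteConfig) -> pd.DataFrame:
    """Full daily input table (Date, Doy, lon, lat, PREC..SM_full)."""
    idx = pd.date_range(
        f"{config.start_year}-01-01",
        f"{config.start_year + config.years - 1}-12-31",
        freq="D",
    )
    ndays = len(idx)
    doy = idx.dayofyear.to_numpy().astype(float)
    w = _season_weight(doy)

    streams = np.random.SeedSequence(config.seed).spawn(4)
    rng_occ, rng_amt, rng_temp, rng_range = (
        np.random.default_rng(s) for s in streams
    )

    occ_p = config.occ_summer + (config.occ_winter - config.occ_summer) * w
    shape = config.gamma_shape_summer + (
        config.gamma_shape_winter - config.gamma_shape_summer
    ) * w
    scale = config.gamma_scale_summer + (
        config.gamma_scale_winter - config.gamma_scale_summer
    ) * w
    wet = rng_occ.random(ndays) < occ_p
    prec = np.where(wet, rng_amt.gamma(shape, scale), 0.0)

    # AR(1) temperature noise around the seasonal cycle
    eps = rng_temp.normal(0.0, config.t_noise_sd, ndays)
    noise = np.empty(ndays)
    acc = 0.0
    for t in range(ndays):
        acc = config.t_ar1 * acc + eps[t]
        noise[t] = acc
    tg = (
        config.t_mean
        - config.t_amplitude * np.cos(2.0 * np.pi * (doy - 15.0) / 365.25)
        + noise
    )
    half = config.t_daily_range / 2.0
    tx = tg + half * (1.0 + 0.2 * np.abs(rng_range.normal(size=ndays)))
    tn = tg - half * (1.0 + 0.2 * np.abs(rng_range.normal(size=ndays)))

    lat_rad = np.deg2rad(config.latitude)
    rg = np.asarray(extraterrestrial_radiation(lat_rad, doy))
    pet = np.asarray(hargreaves_pet(tg, tx, tn, rg))

    sm_top = _bucket(prec, pet, config.bucket_capacity_top, config.drainage,
                     config.sm_initial)
    sm_full = _bucket(prec, pet, config.bucket_capacity_full,
                      config.drainage / 4.0, config.sm_initial)
    aet = pet * sm_top

    return pd.DataFrame(
        {
            "Date": idx.strftime("%Y-%m-%d"),
            "Doy": idx.dayofyear,
            "lon": config.longitude,
            "lat": config.latitude,
            "PREC": prec,
            "TG": tg,
            "TN": tn,
            "TX": tx,
            "PET": pet,
            "RG": rg,
            "AET": aet,
            "SM_top": sm_top,
            "SM_full": sm_full,
        }
    )


@dataclass(frozen=True)
class GammaMixtureOracle:
    """Exact CDF / SDI for a zero-inflated Gamma and its k-day i.i.d. sums."""

    q: float
    shape: float
    scale: float

    def cdf(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        out = np.where(
            x > 0,
            self.q + (1.0 - self.q) * stats.gamma.cdf(x, self.shape, scale=self.scale),
            np.where(x >= 0, self.q, 0.0),
        )
        return out if out.ndim else float(out)

    def sdi(self, x) -> np.ndarray | float:
        out = stats.norm.ppf(self.cdf(x))
        return out if np.ndim(out) else float(out)

    def aggregate_cdf(self, x, k: int) -> np.ndarray | float:
        """CDF of the sum of k i.i.d. draws: a Binomial(k, 1-q) mixture of
        Gamma(shape*m, scale) components (m = number of wet days)."""
        x = np.asarray(x, dtype=float)
        m = np.arange(0, k + 1)
        weights = stats.binom.pmf(m, k, 1.0 - self.q)
        comp = np.empty((len(m),) + x.shape)
        comp[0] = (x >= 0).astype(float)  # all-dry: point mass at 0
        for i, mi in enumerate(m[1:], start=1):
            comp[i] = stats.gamma.cdf(x, self.shape * mi, scale=self.scale)
        out = np.tensordot(weights, comp, axes=(0, 0))
        return out if out.ndim else float(out)

    def aggregate_sdi(self, x, k: int) -> np.ndarray | float:
        out = stats.norm.ppf(self.aggregate_cdf(x, k))
        return out if np.ndim(out) else float(out)


def generate_known_distribution(
    shape: float,
    scale: float,
    q: float,
    years: int,
    seed: int,
    start_year: int = 1950,
) -> tuple[DailySeries, GammaMixtureOracle]:
    """i.i.d. zero-inflated Gamma draws on a daily calendar, plus the oracle."""
    if not 0.0 <= q < 1.0:
        raise DegenerateSampleError("zero fraction q must be in [0, 1)")
    if not (shape > 0 and scale > 0):
        raise InvalidParameterError("Gamma parameters must be > 0")
    idx = pd.date_range(
        f"{start_year}-01-01", f"{start_year + years - 1}-12-31", freq="D"
    )
    streams = np.random.SeedSequence(seed).spawn(2)
    rng_occ, rng_amt = (np.random.default_rng(s) for s in streams)
    wet = rng_occ.random(len(idx)) >= q
    values = np.where(wet, rng_amt.gamma(shape, scale, len(idx)), 0.0)
    return DailySeries(idx, values, "mm"), GammaMixtureOracle(q, shape, scale)
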
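"""Equiprobability transform to standard-normal scores and the zero mixture.

``probability_to_sdi`` is the rational normal-quantile approximation with the
published coefficients (max error below 1e-3 against an exact quantile).  The
convention is non-exceedance: F < 0.5 maps to a negative score, so droughts
come out negative.

Precipitation gets a zero-inflated CDF, F(x) = q + (1-q) * F_plus(x) for
x > 0 and F(0) = q, with q the empirical zero fraction and F_plus a KDE fitted
on the strictly positive values only — zero mass is never double counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSampleError, InvalidParameterError
from .kde import KdeModel, fit_kde, kde_cdf

__all__ = [
    "NORMAL_SCORE_CONSTANTS",
    "probability_to_sdi",
    "ZeroInflatedCdf",
    "zero_inflated_cdf",
    "fit_zero_inflated",
    "clip_probability",
    "sdi_from_sample",
]

#: rational-approximation coefficients (C0..C2 numerator, d1..d3 denominator)
NORMAL_SCORE_CONSTANTS = {
    "C0": 2.515517,
    "C1": 0.802853,
    "C2": 0.010328,
    "d1": 1.432788,
    "d2": 0.189269,
    "d3": 0.001308,
}


def probability_to_sdi(f) -> np.ndarray | float:
    """Standardized score for non-exceedance probability F in (0, 1).

    For F <= 0.5: W = sqrt(-2 ln F) and SDI = -(W - rational(W)); for F > 0.5
    the mirrored branch gives the positive score.  Antisymmetric about 0.5.
    """
    f = np.asarray(f, dtype=float)
    if ((f <= 0.0) | (f >= 1.0)).any() or not np.isfinite(f).all():
        raise InvalidParameterError("probability must lie strictly inside (0, 1)")
    c0, c1, c2 = (NORMAL_SCORE_CONSTANTS[k] for k in ("C0", "C1", "C2"))
    d1, d2, d3 = (NORMAL_SCORE_CONSTANTS[k] for k in ("d1", "d2", "d3"))
    lower = f <= 0.5
    p = np.where(lower, f, 1.0 - f)
    w = np.sqrt(-2.0 * np.log(p))
    core = w - (c0 + c1 * w + c2 * w * w) / (1.0 + d1 * w + d2 * w * w + d3 * w**3)
    out = np.where(lower, -core, core)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ZeroInflatedCdf:
    """Mixture of a point mass at zero (weight q) and a positive-value KDE."""

    q: float
    positive_model: KdeModel

    def __post_init__(self) -> None:
        if not 0.0 <= self.q < 1.0:
            raise DegenerateSampleError(
                f"zero probability q={self.q} must lie in [0, 1)"
            )
        if (self.positive_model.sample <= 0).any():
            raise InvalidParameterError("positive_model must hold only values > 0")


def zero_inflated_cdf(model: ZeroInflatedCdf, x) -> np.ndarray | float:
    """F(x) = q + (1-q) * F_plus(x) for x > 0; exactly q at x = 0."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise InvalidParameterError("x must be >= 0 for a zero-inflated variable")
    pos = model.q + (1.0 - model.q) * np.asarray(kde_cdf(model.positive_model, x))
    out = np.where(x > 0, pos, model.q)
    return out if out.ndim else float(out)


def fit_zero_inflated(
    sample,
    zero_threshold: float = 0.0,
    bandwidth_method: str = "cv",
) -> ZeroInflatedCdf:
    """Split a nonnegative sample into zero mass + positive-value KDE.

    Values at or below ``zero_threshold`` count as zeros.
    """
    sample = np.asarray(sample, dtype=float)
    zeros = sample <= zero_threshold
    q = float(zeros.sum()) / len(sample)
    positives = sample[~zeros]
    if q >= 1.0:
        raise DegenerateSampleError("all-zero sample: zero-inflated CDF undefined")
    if len(np.unique(positives)) < 2:
        raise DegenerateSampleError(
            "fewer than 2 distinct positive values; cannot fit positive-part KDE"
        )
    return ZeroInflatedCdf(q, fit_kde(positives, method=bandwidth_method))


def clip_probability(f, n: int) -> np.ndarray | float:
    """Clip F into [1/(2(n+1)), 1 - 1/(2(n+1))] so scores stay finite."""
    eps = 1.0 / (2.0 * (n + 1))
    out = np.clip(np.asarray(f, dtype=float), eps, 1.0 - eps)
    return out if out.ndim else float(out)


def sdi_from_sample(
    sample,
    target_value,
    variable_kind: str = "water_balance",
    zero_threshold: float = 0.0,
    bandwidth_method: str = "cv",
) -> np.ndarray | float:
    """Standardized score of ``target_value`` against a climatological sample.

    Precipitation uses the zero-inflated pathway; water balance and soil
    moisture use the plain KDE.  The probability is clipped before the normal
    score so out-of-range targets map to a large finite score, never infinity.
    """
    sample = np.asarray(sample, dtype=float)
    if variable_kind == "precipitation":
        model = fit_zero_inflated(sample, zero_threshold, bandwidth_method)
        f = zero_inflated_cdf(model, target_value)
    elif variable_kind in ("water_balance", "soil_moisture"):
        if np.ptp(sample) == 0.0:
            raise DegenerateSampleError("constant sample; KDE undefined")
        f = kde_cdf(fit_kde(sample, method=bandwidth_method), target_value)
    else:
        raise InvalidParameterError(f"unknown variable kind {variable_kind!r}")
    return probability_to_sdi(clip_probability(f, len(sample)))
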
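"""Run configuration: every tunable knob in one declarative place.

The defaults reproduce the published pipeline; a YAML file with any subset of
the keys overrides them.  ``Settings.config_hash()`` gives a short digest that
the CLI logs so runs can be matched to their configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import InvalidParameterError

__all__ = ["Settings"]


@dataclass(frozen=True)
class Settings:
    #: fraction of a rolling window that must be non-missing for the
    #: aggregate to be reported (windows shorter than k are always missing)
    completeness: float = 0.9
    #: minimum number of contributing years for a climatological sample
    min_sample_size: int = 30
    #: precipitation at or below this value counts as a "zero" day (mm)
    wet_day_threshold: float = 0.0
    #: "cv" (least-squares cross-validation) or "silverman"
    bandwidth_method: str = "cv"
    #: number of log-spaced points in the CV bandwidth search grid
    cv_grid_points: int = 101
    #: grid spans [h_silverman / span, h_silverman * span]
    cv_grid_span: float = 10.0
    #: Hargreaves-Samani multiplier, kept as printed in the source equation
    hargreaves_coefficient: float = 0.00023
    #: floor PET at zero when the mean temperature term goes negative
    pet_floor_negative: bool = True
    #: pool Feb 29 with Feb 28 into one climatological sample
    feb29_pooling: bool = True
    #: pool +/- this many neighbouring calendar days into each sample
    day_pooling_window: int = 0
    #: decimal places written to output CSV files
    float_decimals: int = 4
    #: nRMSE denominator: "sd", "mean" or "range" of the observations
    nrmse_normalization: str = "sd"
    #: rolling correlation windows: trailing (False) or centered (True)
    rolling_window_centered: bool = False
    #: growing-season month span for correlation fields (inclusive)
    season_months: tuple[int, int] = (5, 9)
    #: drought-area fraction counts category-or-worse (vs exactly-category)
    fraction_or_worse: bool = True
    #: out-of-range input values raise (True) or warn-and-blank (False)
    strict_io: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.completeness <= 1.0:
            raise InvalidParameterError("completeness must be in (0, 1]")
        if self.min_sample_size < 2:
            raise InvalidParameterError("min_sample_size must be >= 2")
        if self.bandwidth_method not in ("cv", "silverman"):
            raise InvalidParameterError(
                f"unknown bandwidth_method {self.bandwidth_method!r}"
            )
        if self.nrmse_normalization not in ("sd", "mean", "range"):
            raise InvalidParameterError(
                f"unknown nrmse_normalization {self.nrmse_normalization!r}"
            )
        if self.day_pooling_window < 0:
            raise InvalidParameterError("day_pooling_window must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Settings":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise InvalidParameterError(f"config file {path} must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        if "season_months" in raw:
            raw["season_months"] = tuple(raw["season_months"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["season_months"] = list(data["season_months"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def config_hash(self) -> str:
        data = dataclasses.asdict(self)
        data["season_months"] = list(data["season_months"])
        blob = json.dumps(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
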
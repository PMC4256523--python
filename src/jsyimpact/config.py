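"""Scenario configuration for the synthetic-data generator.

A scenario describes one state split into administrative divisions, each
containing several districts, observed over a span of calendar years by a
set of mortality data sources of differing reliability, together with a
maternal-health cash-transfer program (JSY) whose uptake rises over the
period.  Defaults emulate the Madhya Pradesh setting: a state MMR of
roughly 370 falling by about 12% over 2005-2010, institutional delivery
rising from ~24% to ~56%, and the JSY share of institutional deliveries
rising from 14% to 80%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml


class ConfigError(ValueError):
    """Raised when a scenario configuration violates its invariants."""


@dataclass(frozen=True)
class SourceSpec:
    """One mortality data source.

    Parameters
    ----------
    source_id : label used in the observations table.
    level : geographic level the source reports at
        (``district``, ``division`` or ``state``).
    bias : multiplicative factor on the expected reported deaths
        (generative analogue of the model's source effect).
        ``bias < 1`` means the source under-counts deaths.
    coverage : probability that any unit-year is actually reported.
    reports_mmr_directly : if True the source publishes an MMR plus its
        denominator instead of a death count.
    """

    source_id: str
    level: str = "district"
    bias: float = 1.0
    coverage: float = 1.0
    reports_mmr_directly: bool = False

    def __post_init__(self) -> None:
        if self.level not in ("district", "division", "state"):
            raise ConfigError(f"unknown source level {self.level!r}")
        if not self.bias > 0:
            raise ConfigError("source bias must be > 0")
        if not (0 < self.coverage <= 1):
            raise ConfigError("source coverage must be in (0, 1]")


@dataclass(frozen=True)
class TrendConfig:
    """Linear and non-linear components of the secular log-MMR trend."""

    slope_mean: float = -0.007       # state-mean log-MMR change per year
    slope_sd: float = 0.012          # inter-district slope spread
    division_slope_sd: float = 0.004
    nonlinear_scale: float = 0.008   # sd of RW2 second differences


@dataclass(frozen=True)
class UptakeConfig:
    """Program uptake curves and the reporting bias of the district bulletin.

    ``inst_prop_*`` is the proportion of all deliveries occurring in an
    institution; ``jsy_share_*`` is the JSY-supported share of those
    institutional deliveries.  The bulletin over-reports institutional
    delivery: its reported proportion is the true proportion divided by a
    per-district correction factor drawn uniformly from
    ``(factor_low, factor_high)`` (survey/bulletin ratio), while a
    one-year survey benchmark reports the truth.
    """

    inst_prop_start: float = 0.239
    inst_prop_end: float = 0.559
    jsy_share_start: float = 0.14
    jsy_share_end: float = 0.80
    district_sd: float = 0.15        # logit-scale inter-district level spread
    district_growth_sd: float = 0.15  # logit-scale spread of uptake growth/year
    benchmark_year: int = 2007
    factor_low: float = 0.34
    factor_high: float = 0.97
    expenditure_per_delivery_lakh: float = 0.03
    expenditure_noise_cv: float = 0.05
    anc3_start: float = 30.0         # percent of women with >= 3 ANC visits
    anc3_end: float = 60.0
    anc3_district_sd: float = 5.0


_DEFAULT_COVARIATE_EFFECTS = {"tfr": 0.15, "hdi": -1.2}

#: Fixed centring constants so the baseline is interpretable as the
#: state-mean log MMR regardless of the covariate draw.
COVARIATE_CENTERS = {"tfr": 3.5, "hdi": 0.5}


def _default_sources() -> tuple[SourceSpec, ...]:
    return (
        SourceSpec("bulletin", level="district", bias=0.85, coverage=0.9),
        SourceSpec("ahs", level="division", bias=1.0, coverage=1.0),
        SourceSpec("srs", level="state", bias=1.0, coverage=1.0),
    )


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of one synthetic study scenario.

    The default scenario is 12 districts nested in 3 divisions observed
    2005-2010 by three sources: a biased, incomplete district bulletin, a
    complete division-level survey, and an unbiased state-level envelope
    source.
    """

    n_districts: int = 12
    n_divisions: int = 3
    year_start: int = 2005
    year_end: int = 2010
    population_per_district: float = 1_200_000.0
    population_spread: float = 0.25      # relative half-width of district sizes
    crude_birth_rate: float = 25.0       # births per 1,000 persons per year
    stillbirth_rate: float = 15.0        # per 1,000 total births
    baseline_log_mmr_mean: float = math.log(371.0)
    district_intercept_sd: float = 0.18
    division_intercept_sd: float = 0.10
    covariate_effects: dict = field(
        default_factory=lambda: dict(_DEFAULT_COVARIATE_EFFECTS)
    )
    trend: TrendConfig = field(default_factory=TrendConfig)
    program_effect: float = -0.223       # log-MMR per unit JSY delivery proportion
    uptake: UptakeConfig = field(default_factory=UptakeConfig)
    sources: Sequence[SourceSpec] = field(default_factory=_default_sources)
    overdispersion: float = 25.0         # negative-binomial size parameter
    seed: int = 20050

    def __post_init__(self) -> None:
        if not (self.n_districts >= self.n_divisions >= 1):
            raise ConfigError("need n_districts >= n_divisions >= 1")
        if self.year_end - self.year_start + 1 < 3:
            raise ConfigError("year span must cover at least 3 years")
        if not self.population_per_district > 0:
            raise ConfigError("population must be > 0")
        if not self.overdispersion > 0:
            raise ConfigError("overdispersion must be > 0")
        if not (0 <= self.stillbirth_rate < 1000):
            raise ConfigError("stillbirth rate must be in [0, 1000)")
        ids = [s.source_id for s in self.sources]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate source_id")

    @property
    def years(self) -> list[int]:
        return list(range(self.year_start, self.year_end + 1))

    @property
    def n_years(self) -> int:
        return self.year_end - self.year_start + 1

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sources"] = [asdict(s) for s in self.sources]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if "trend" in d and isinstance(d["trend"], dict):
            d["trend"] = TrendConfig(**d["trend"])
        if "uptake" in d and isinstance(d["uptake"], dict):
            d["uptake"] = UptakeConfig(**d["uptake"])
        if "sources" in d:
            d["sources"] = tuple(
                SourceSpec(**s) if isinstance(s, dict) else s for s in d["sources"]
            )
        try:
            return cls(**d)
        except TypeError as exc:  # unknown field names
            raise ConfigError(str(exc)) from exc


def load_scenario(path) -> ScenarioConfig:
    """Read a scenario from a YAML (or JSON) file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return ScenarioConfig()
    if not isinstance(data, dict):
        raise ConfigError("scenario file must contain a mapping")
    return ScenarioConfig.from_dict(data)


def save_scenario(config: ScenarioConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
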
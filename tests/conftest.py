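import numpy as np
import pytest

from jsyimpact.config import ScenarioConfig, SourceSpec, TrendConfig, UptakeConfig
from jsyimpact.synth import (
    generate_observations,
    generate_program_panel,
    generate_truth,
)


@pytest.fixture(scope="session")
def default_truth():
    return generate_truth(ScenarioConfig(seed=101))


@pytest.fixture(scope="session")
def default_observations(default_truth):
    return generate_observations(default_truth)


@pytest.fixture(scope="session")
def default_panel(default_truth):
    return generate_program_panel(default_truth)


def frozen_scenario(**overrides) -> ScenarioConfig:
    """Small fast scenario for fitting tests."""
    base = dict(
        seed=11,
        n_districts=6,
        n_divisions=2,
        year_start=2005,
        year_end=2010,
    )
    base.update(overrides)
    return ScenarioConfig(**base)


def tiny_scenario(**overrides) -> ScenarioConfig:
    """Very small two-source scenario (<= 20 observations)."""
    base = dict(
        seed=11,
        n_districts=3,
        n_divisions=1,
        year_start=2005,
        year_end=2008,
        sources=(
            SourceSpec("bulletin", "district", bias=0.9, coverage=0.75),
            SourceSpec("srs", "state", bias=1.0, coverage=1.0),
        ),
    )
    base.update(overrides)
    return ScenarioConfig(**base)


def impact_scenario(program_effect: float, seed: int) -> ScenarioConfig:
    """Scenario where the impact regression is correctly specified:

    no covariate effects on MMR and no district-specific mortality
    trends, so log MMR is exactly year effects + district intercepts +
    the program term.
    """
    return ScenarioConfig(
        seed=seed,
        program_effect=program_effect,
        covariate_effects={"tfr": 0.0, "hdi": 0.0},
        trend=TrendConfig(
            slope_mean=-0.01, slope_sd=0.0, division_slope_sd=0.0,
            nonlinear_scale=0.008,
        ),
    )
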
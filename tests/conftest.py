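"""Shared fixtures: a small synthetic study that exercises every stage.

The "small" configuration uses a 20 x 15 one-degree grid enclosing the
Germany response box and the default five-year span, so mortality,
flattening and the experiment protocol behave exactly as at full size
while staying fast.
"""

import logging

import numpy as np
import pytest

from esnmort import (
    ESNConfig,
    ExperimentPlan,
    SyntheticClimateSpec,
    SyntheticResponseSpec,
    generate_mortality_series,
    generate_temperature_series,
)

# the synthetic generator logs expected out-of-range normalization warnings
logging.getLogger("esnmort.preprocess").setLevel(logging.ERROR)

SMALL_GRID = dict(lon_range=(0.0, 19.0), lat_range=(42.0, 56.0))


@pytest.fixture(scope="session")
def small_climate() -> SyntheticClimateSpec:
    return SyntheticClimateSpec(seed=11, **SMALL_GRID)


@pytest.fixture(scope="session")
def small_response() -> SyntheticResponseSpec:
    return SyntheticResponseSpec(seed=12)


@pytest.fixture(scope="session")
def small_temps(small_climate):
    return generate_temperature_series(small_climate)


@pytest.fixture(scope="session")
def small_mortality(small_temps, small_response):
    return generate_mortality_series(small_temps, small_response)


@pytest.fixture(scope="session")
def small_plan() -> ExperimentPlan:
    return ExperimentPlan(ensemble_size=3, base_seed=7)


@pytest.fixture()
def tiny_config() -> ESNConfig:
    return ESNConfig(reservoir_size=40, seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
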
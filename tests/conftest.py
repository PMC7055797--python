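"""Shared fixtures: scaled-down growth/passage setups for fast unit tests.

The miniature setup keeps the structure of the standard protocol (100-fold
expansion per cycle, 100-fold dilution) but at a carrying capacity of 1e6
cells so that multi-passage tests run in milliseconds.
"""

import numpy as np
import pytest

from snapsim.growth_dynamics import GrowthParams
from snapsim.passage_simulator import PassageProtocol, Scenario
from snapsim.strain_model import FitnessScheme, default_rates


@pytest.fixture
def scheme():
    return FitnessScheme()


@pytest.fixture
def rates():
    return default_rates()


@pytest.fixture
def growth():
    return GrowthParams()


@pytest.fixture
def mini_growth():
    # capacity r0/e = 1e6 cells
    return GrowthParams(r0=100.0, e=1e-4)


@pytest.fixture
def mini_protocol():
    return PassageProtocol(
        dilution_factor=100.0,
        bottleneck_size=1e4,
        initial_population=1e4,
        target_generations=60.0,
    )


@pytest.fixture
def mini_scenario(mini_growth, mini_protocol):
    return Scenario(growth=mini_growth, protocol=mini_protocol, replicates=1, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
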
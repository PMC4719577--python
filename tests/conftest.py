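import logging

import pytest

from tfcircuits.config import Config
from tfcircuits.pipeline import default_scenario
from tfcircuits.simulate import SimConfig, simulate_cohort

logging.getLogger("tfcircuits").setLevel(logging.ERROR)


@pytest.fixture
def cfg():
    return Config()


@pytest.fixture(scope="session")
def small_cohort():
    """One moderately sized cohort with the standard planted scenario."""
    cohort = simulate_cohort(SimConfig(seed=7))
    return default_scenario(cohort)
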
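import numpy as np
import pytest

from adadose import (
    TrialConfig,
    build_scenario_table,
    default_candidates,
)
from adadose.dose_response import DEFAULT_GRID


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID


@pytest.fixture(scope="session")
def scenarios():
    """The 16-scenario truth table (ids 1..16; index id-1)."""
    return build_scenario_table()


@pytest.fixture(scope="session")
def candidates():
    return default_candidates()


@pytest.fixture(scope="session")
def config():
    return TrialConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
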
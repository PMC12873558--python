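import numpy as np
import pytest

from smolsurv import SimulationConfig, SmolHead, assemble_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small Scenario-I cohort shared across tests."""
    return assemble_cohort(SimulationConfig(n=120, scenario="I", seed=7))


@pytest.fixture(scope="session")
def head():
    return SmolHead.create(L=10, p=3, t_max=30.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
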
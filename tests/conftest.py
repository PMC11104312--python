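import numpy as np
import pytest

from bandit_aif import AgentParams, sample_schedule, simulate_agent
from bandit_aif.model_space import nested_model_table


@pytest.fixture(scope="session")
def model_table():
    return nested_model_table()


@pytest.fixture(scope="session")
def model9(model_table):
    return model_table[8]


@pytest.fixture(scope="session")
def schedule():
    return sample_schedule(1)


@pytest.fixture(scope="session")
def typical_params():
    # mid-range values for the full model
    return AgentParams(2.5, 4.5, 0.5, 0.38, 0.78)


@pytest.fixture(scope="session")
def session_behavior(typical_params, schedule):
    return simulate_agent(typical_params, schedule, seed=42, subject_id="S1")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
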
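import numpy as np
import pytest

from critlearn import (
    BaseAgent, make_run_schedules, simulate_agent_session,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def base_trials():
    """A moderate Base-agent session reused by conditioning/analysis tests."""
    rng = np.random.default_rng(99)
    agent = BaseAgent(sigma_m=1.5)
    schedules = make_run_schedules(30, rng, freeze=True)
    return simulate_agent_session(agent, schedules, rng, record_latents=False)
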
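import numpy as np
import pytest
from hypothesis import settings

from aimdp.task import AgentConfig, build_agent_model, make_default_contingencies

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def spec():
    return make_default_contingencies()


@pytest.fixture
def cfg():
    return AgentConfig()


@pytest.fixture
def agent(spec, cfg):
    """(model, beliefs) for a naive agent on the default task."""
    return build_agent_model(spec, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
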
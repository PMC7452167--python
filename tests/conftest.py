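import numpy as np
import pytest

from coopbots import Condition, HumanModelParams, SessionConfig, run_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_params():
    return HumanModelParams()


@pytest.fixture(scope="session")
def no_bot_session():
    """One full default no-bot session, shared across read-only tests."""
    return run_session(SessionConfig(condition=Condition.NO_BOT, seed=11))


@pytest.fixture(scope="session")
def disengaged_session():
    return run_session(SessionConfig(condition=Condition.DISENGAGED_INT, seed=12))


@pytest.fixture(scope="session")
def engaged_session():
    return run_session(SessionConfig(condition=Condition.ENGAGED_INT, seed=13))


@pytest.fixture(scope="session")
def mixed_session():
    return run_session(SessionConfig(condition=Condition.SINGLE_MIXED, seed=14))


@pytest.fixture(scope="session")
def tft_session():
    return run_session(SessionConfig(condition=Condition.TFT, seed=15))
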
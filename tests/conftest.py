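import numpy as np
import pytest

from edsched.domain import load_tables
from edsched.dqn import train


@pytest.fixture(scope="session")
def tables():
    return load_tables()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def trained_agent():
    """A reduced-budget trained DQN scheduler, shared across tests.

    25 episodes of the normal-load scenario at the default hyperparameters;
    the full 1000-episode schedule changes nothing material about the
    assertions made against this fixture but costs ~30x the wall time.
    """
    return train(episodes=25, seed=7).scheduler
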
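import numpy as np
import pytest

from dcopnet import DCOPNet, ModelConfig, make_episode, DEFAULT_CLASSES


@pytest.fixture(scope="session")
def episode():
    """One fixed synthetic 64x64 episode (class A, seed 0)."""
    return make_episode(DEFAULT_CLASSES["A"], seed=0)


@pytest.fixture(scope="session")
def model():
    """An untrained network with default (seeded) initialization."""
    return DCOPNet(ModelConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
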
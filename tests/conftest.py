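import numpy as np
import pytest

from attractorchoice.params import NetworkConfig
from attractorchoice.network import build_network


@pytest.fixture(scope="session")
def small_config() -> NetworkConfig:
    """A miniature network for structural and contract tests."""
    return NetworkConfig(n_pyramidal=40, n_selective=10, n_interneurons=10)


@pytest.fixture(scope="session")
def small_network(small_config):
    return build_network(small_config, rng_seed=7)


@pytest.fixture(scope="session")
def full_network():
    """The default-size network (wired once per test session)."""
    return build_network(NetworkConfig(), rng_seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
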
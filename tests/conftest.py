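import numpy as np
import pytest

from nnetseg.arch import ArchitectureConfig, build_model
from nnetseg.phantom import PhantomConfig, generate_batch

TINY = dict(depth=3, base_channels=8, input_size=64)


@pytest.fixture(scope="session")
def tiny_config():
    return ArchitectureConfig(**TINY)


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    return build_model(tiny_config, seed=0)


@pytest.fixture(scope="session")
def phantom_batch():
    """24 small phantoms shared by the cheaper pipeline tests."""
    return generate_batch(24, PhantomConfig(size=64, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
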
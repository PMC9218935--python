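import numpy as np
import pytest

from halfunet.architectures import ArchitectureConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_cfg():
    """A faithful miniature configuration for exhaustive checks."""
    return ArchitectureConfig(base_channels=4, depth=3, input_shape=(1, 16, 16))


@pytest.fixture
def tiny2_cfg():
    return ArchitectureConfig(base_channels=4, depth=2, input_shape=(1, 16, 16))
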
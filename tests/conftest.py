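import numpy as np
import pytest

from tiptrack.simulate import SimulationConfig


@pytest.fixture
def config():
    """Default imaging world: 160 nm pixels, 100 ms frames, 120 nm PSF."""
    return SimulationConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
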
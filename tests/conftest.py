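import numpy as np
import pytest

from cardiofuse import phantom as ph
from cardiofuse.training import scaled_phantom_config


@pytest.fixture(scope="session")
def base_config():
    """Small-grid phantom config shared by read-only tests."""
    return scaled_phantom_config(48, n_frames=12)


@pytest.fixture(scope="session")
def base_sample(base_config):
    """Aligned (canonical-orientation) phantom; treat as read-only."""
    return ph.make_phantom(base_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
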
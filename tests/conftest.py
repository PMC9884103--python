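import numpy as np
import pytest

from msiaudit.radiometry import ChannelSpec
from msiaudit.synthetic import make_illuminants, make_sensor, sample_reflectance_library


@pytest.fixture(scope="session")
def lights():
    return make_illuminants()


@pytest.fixture(scope="session")
def sensor():
    return make_sensor()


@pytest.fixture(scope="session")
def channel_spec():
    return ChannelSpec()


@pytest.fixture(scope="session")
def small_library():
    """Three well-separated classes for fast rendering tests."""
    return sample_reflectance_library(n_classes=3, separability=0.08, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
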
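import numpy as np
import pytest
from hypothesis import settings

from plastipop import default_fixture_params

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixture_params():
    """Default strain pair and global parameters."""
    return default_fixture_params()


@pytest.fixture(scope="session")
def strains(fixture_params):
    return fixture_params[0]


@pytest.fixture(scope="session")
def global_params(fixture_params):
    return fixture_params[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
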
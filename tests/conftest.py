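import numpy as np
import pytest
from hypothesis import settings

from specdiff import lin200, log200

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def lin200_dict():
    return lin200()


@pytest.fixture(scope="session")
def log200_dict():
    return log200()


@pytest.fixture()
def rng():
    return np.random.default_rng(20250704)
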
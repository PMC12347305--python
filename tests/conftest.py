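import numpy as np
import pytest

from torsionfold.fragments import generate_synthetic_library
from torsionfold.io_formats import load_parameter_set, load_topology


@pytest.fixture(scope="session")
def topology():
    return load_topology()


@pytest.fixture(scope="session")
def params():
    return load_parameter_set()


@pytest.fixture(scope="session")
def small_library():
    """Seeded 17-fragment library with a fixed 10/5/2 class mix."""
    return generate_synthetic_library(10, 5, 2, noise_deg=5.0, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
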
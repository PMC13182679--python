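import numpy as np
import pytest

from gammaplan import GridSpec, PhantomSpec, make_case, packaged_beam_data
from gammaplan.planner import crop_case


@pytest.fixture(scope="session")
def beam():
    return packaged_beam_data()


@pytest.fixture(scope="session")
def sphere_case():
    """0.9 cc spherical target cropped to its working grid."""
    return crop_case(make_case(PhantomSpec("sphere", 0.9, seed=0)))


@pytest.fixture
def small_grid():
    return GridSpec((21, 21, 21))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
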
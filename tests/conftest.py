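import numpy as np
import pytest

from csfpolar import CSFParams, make_stimulus_space
from csfpolar.qcsf import PosteriorGrid


@pytest.fixture(scope="session")
def default_space():
    return make_stimulus_space()


@pytest.fixture(scope="session")
def small_grid():
    """Coarse posterior grid; keeps exhaustive EIG tables cheap."""
    return PosteriorGrid.uniform(shape=(8, 8, 6))


@pytest.fixture
def typical_params():
    return CSFParams(peak_cs=50.0, peak_sf=1.5, bandwidth_oct=2.9)


@pytest.fixture
def rng():
    return np.random.default_rng(20240712)
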
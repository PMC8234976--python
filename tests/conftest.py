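import numpy as np
import pytest

from uvnitro import reference_design
from uvnitro.synth import default_grid, default_library


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def library(grid):
    return default_library(grid)


@pytest.fixture(scope="session")
def design():
    """Reference 34-sample calibration / 20-sample prediction design."""
    return reference_design()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
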
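import numpy as np
import pytest

from ptikit.optics_otf import (
    DetectionSpec,
    compute_transfer_functions,
    sector_patterns,
)
from ptikit.tensor_core import GridSpec


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    """Tiny grid for fast unit tests."""
    return GridSpec((16, 24, 24), (0.2, 0.12, 0.12), 0.532, 1.515)


@pytest.fixture(scope="session")
def detection() -> DetectionSpec:
    return DetectionSpec(na_obj=1.47)


@pytest.fixture(scope="session")
def small_patterns(small_grid):
    return sector_patterns(small_grid, na_illu=1.4, source_stride=2)


@pytest.fixture(scope="session")
def small_tfset(small_patterns, detection, small_grid):
    return compute_transfer_functions(small_patterns, detection, small_grid)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def circular_angle_diff(a, b, period=np.pi):
    """Smallest absolute difference between axis angles of given period."""
    d = np.abs(np.asarray(a) - np.asarray(b)) % period
    return np.minimum(d, period - d)
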
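import numpy as np
import pytest

from depthqc import PointCloud


@pytest.fixture
def rng():
    return np.random.default_rng(20170502)


@pytest.fixture
def gauss2d(rng):
    """100 standard-normal points in 2D."""
    return PointCloud.from_array(rng.standard_normal((100, 2)))


@pytest.fixture
def gauss3d(rng):
    """60 standard-normal points in 3D (kept small for grid speed)."""
    return PointCloud.from_array(rng.standard_normal((60, 3)))


@pytest.fixture
def unit_square():
    return PointCloud.from_array(
        [[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]
    )
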
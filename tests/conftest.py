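import numpy as np
import pytest

import nanocluscol as nc


@pytest.fixture
def square_roi():
    """4 x 4 um square region, the standard calibration field."""
    return nc.RoiPolygon(np.array([[0, 0], [4000, 0], [4000, 4000], [0, 4000]],
                                  float))


@pytest.fixture
def big_square_roi():
    """10 x 10 um field for planted-cluster recovery."""
    return nc.RoiPolygon(np.array([[0, 0], [10000, 0], [10000, 10000],
                                   [0, 10000]], float))


@pytest.fixture
def ring():
    """Nuclear-envelope-like annulus, 4-5 um radius."""
    return nc.ring_roi((0.0, 0.0), 4000.0, 5000.0, 256)


@pytest.fixture
def coloc_scene(ring):
    """Two-channel scene with every channel-B parent shared with channel A."""
    return nc.simulate_two_channel(ring, seed=3, coloc_fraction=1.0)
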
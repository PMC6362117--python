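"""Shared fixtures: phantom atlases and deterministic RNGs.

Session-scoped because atlas construction, while fast, is used by most
modules; all randomness is seeded so the suite is reproducible.
"""

import numpy as np
import pytest

from medh import phantom


@pytest.fixture(scope="session")
def atlas116():
    """Default atlas: 64^3, 2 mm spacing, 116 regions (54 pairs + 8 midline)."""
    return phantom.make_atlas(seed=0)


@pytest.fixture(scope="session")
def small_atlas():
    """Small atlas for cheap unit tests: 48^3, 10 pairs + 2 midline."""
    return phantom.make_atlas(grid_shape=(48, 48, 48), n_region_pairs=10,
                              n_midline_regions=2, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def tumor_center(atlas, offset=(19.0, 3.0, -2.0)):
    """A world-space tumor centre in the right hemisphere of the atlas."""
    shape = np.asarray(atlas.t1.shape, dtype=float)
    c_mid = (shape - 1) / 2 * atlas.t1.spacing
    return tuple(c_mid + np.asarray(offset))
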
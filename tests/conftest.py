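import numpy as np
import pytest

from slmvpa import GridSpec, RegionSpec, make_ground_truth


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec((12, 12, 12))


@pytest.fixture(scope="session")
def amodal_gt(small_grid):
    """Ground truth with one amodal region, moderate mask fill."""
    return make_ground_truth(
        small_grid,
        [RegionSpec("amodal", (6, 6, 6), 2, 1.0)],
        fill_fraction=0.6,
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
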
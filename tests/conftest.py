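import numpy as np
import pytest

import haystack as hs


@pytest.fixture(scope="session")
def blob_space():
    """400 samples in 4 well-separated 2D blobs (generator truth in .group)."""
    return hs.make_coords(400, 2, structure="blobs", n_blobs=4, seed=7)


@pytest.fixture(scope="session")
def small_dataset(blob_space):
    """20 planted + 80 null features over the blob space."""
    return hs.make_activity(blob_space, n_planted=20, n_null=80, seed=7)


@pytest.fixture(scope="session")
def small_grid(blob_space):
    space = hs.scale_space(blob_space)
    return space, hs.build_grid_model(space, g=30, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
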
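import numpy as np
import pytest

from lmsf.synthetic import dense_blob_spec, make_scene, sparse_blob_spec


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def dense_scene():
    """512x512 dense-foreground blob scene with ground truth (seeded)."""
    return make_scene(dense_blob_spec(seed=0))


@pytest.fixture(scope="session")
def sparse_scene():
    """200x200 sparse bright blobs in a large empty field (seeded)."""
    return make_scene(sparse_blob_spec(seed=0))
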
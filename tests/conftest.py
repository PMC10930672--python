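import numpy as np
import pytest

from qsteato.datasynth import SyntheticSlideSpec, build_balanced_dataset, realize_tiles

TEST_SIDE = 32
TEST_SPEC = SyntheticSlideSpec(side_px=TEST_SIDE, n_confounders=1)


@pytest.fixture(scope="session")
def tiny_dataset():
    """120 synthetic 32-px tiles, 30 per grade (60 per binary class)."""
    manifest = build_balanced_dataset(30, TEST_SPEC, seed=42)
    X, y = realize_tiles(manifest, TEST_SPEC)
    return X, y, manifest


@pytest.fixture(scope="session")
def tiny_arrays(tiny_dataset):
    X, y, _ = tiny_dataset
    return X, y


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
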
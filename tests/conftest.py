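import numpy as np
import pytest

from mobilemfs.datasets import SyntheticSpec, generate_synthetic_arrays


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_synth():
    """9 classes x 20 images at 64 px — shared across data/train tests."""
    spec = SyntheticSpec(image_size=64, n_per_class=20, seed=7)
    images, labels, masks = generate_synthetic_arrays(spec)
    return spec, images, labels, masks


@pytest.fixture(scope="session")
def tiny_image_folder(tmp_path_factory):
    """A materialized synthetic image folder (9 classes x 6 images, 32 px)."""
    from mobilemfs.datasets import generate_synthetic_dataset

    root = tmp_path_factory.mktemp("leafdata")
    spec = SyntheticSpec(image_size=32, n_per_class=6, seed=11)
    manifest = generate_synthetic_dataset(spec, root)
    return root, manifest
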
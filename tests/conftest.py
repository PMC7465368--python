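import numpy as np
import pytest

from histofuse import SyntheticSpec, generate_dataset, scan_dataset
from histofuse.net import ArchitectureSpec


@pytest.fixture(scope="session")
def tiny_arch() -> ArchitectureSpec:
    """A miniature backbone that keeps training tests fast."""
    return ArchitectureSpec(input_side=32, stem_channels=16, growth_rate=8,
                            block_repeats=(1, 1, 1, 1), taps=(1, 2, 3, 4),
                            n_classes=2)


@pytest.fixture(scope="session")
def small_dataset_dir(tmp_path_factory):
    """2 classes x 3 patients x 4 images of 64x64 px, BreakHis layout."""
    root = tmp_path_factory.mktemp("synth") / "ds"
    spec = SyntheticSpec(n_classes=2, n_patients_per_class=3,
                         images_per_patient=4, image_size=(64, 64), seed=11)
    manifest = generate_dataset(spec, root)
    return root, spec, manifest


@pytest.fixture(scope="session")
def small_records(small_dataset_dir):
    root, _, _ = small_dataset_dir
    return scan_dataset(root, "breakhis")


@pytest.fixture(scope="session")
def small_patches(small_records):
    from histofuse import prepare_patches

    return prepare_patches(small_records, out_size=32)


@pytest.fixture(scope="session")
def separable_patches(tmp_path_factory):
    """Raw (un-normalized) patches from default-size textures: trivially
    separable, for training-loop tests."""
    from histofuse import prepare_patches

    root = tmp_path_factory.mktemp("synth_big") / "ds"
    spec = SyntheticSpec(n_patients_per_class=2, images_per_patient=2, seed=4)
    generate_dataset(spec, root)
    records = scan_dataset(root, "breakhis")
    return prepare_patches(records, out_size=32, normalize=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
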
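import numpy as np
import pandas as pd
import pytest

from tailmix.manifest import DatasetManifest, MANIFEST_COLUMNS
from tailmix.profiles import ClassSizeProfile
from tailmix.synthetic import JitterSpec, SyntheticSpec, render_images


def make_manifest(train_counts, test_per_class=5):
    """Manifest with given per-class training counts and a balanced test split."""
    rows = []
    for c, n in enumerate(train_counts):
        for i in range(n):
            rows.append((f"train/c{c}/im{i:04d}.png", c, f"class_{c}", "train"))
    for c in range(len(train_counts)):
        for i in range(test_per_class):
            rows.append((f"test/c{c}/im{i:04d}.png", c, f"class_{c}", "test"))
    return DatasetManifest(records=pd.DataFrame(rows, columns=MANIFEST_COLUMNS))


@pytest.fixture
def small_manifest():
    return make_manifest([10, 10, 10])


@pytest.fixture(scope="session")
def tiny_image_dataset():
    """Small rendered dataset shared across tests: 4 classes, 24x24 images."""
    spec = SyntheticSpec(
        profile=ClassSizeProfile(sizes=(40, 20, 10, 5)),
        image_size=(24, 24),
        test_per_class=10,
        jitter=JitterSpec(outlier_fraction=0.0),
        seed=7,
    )
    X_train, y_train, X_test, y_test, manifest = render_images(spec)
    return dict(
        spec=spec,
        X_train=X_train,
        y_train=y_train,
        X_test=X_test,
        y_test=y_test,
        manifest=manifest,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
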
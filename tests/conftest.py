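import numpy as np
import pytest

from histotile.backbone import FixtureBackbone
from histotile.synthetic import SyntheticSpec, generate_dataset
from histotile.types import Label, LabeledImage


@pytest.fixture(scope="session")
def fixture_backbone():
    return FixtureBackbone(seed=0)


@pytest.fixture(scope="session")
def small_dataset():
    """20 images/class of small stationary-texture synthetic data."""
    spec = SyntheticSpec(
        n_images_per_class=20, image_size=(64, 64), seed=42,
        class_separation=30.0, noise_sigma=10.0,
    )
    return generate_dataset(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_image(pixels, label=Label.BENIGN, source="mem://img"):
    """Wrap a raw array as a LabeledImage with a given label."""
    return LabeledImage(
        pixels=np.asarray(pixels, dtype=np.uint8),
        label=label,
        source_path=source,
    )


@pytest.fixture
def checker_image():
    """A deterministic 16×12 RGB gradient image."""
    h, w = 16, 12
    r = np.tile(np.arange(h, dtype=np.uint8)[:, None] * 15, (1, w))
    c = np.tile(np.arange(w, dtype=np.uint8)[None, :] * 20, (h, 1))
    pixels = np.stack([r, c, (r + c) // 2], axis=2).astype(np.uint8)
    return make_image(pixels, Label.MALIGNANT, "mem://checker")
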
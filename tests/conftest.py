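import numpy as np
import pytest

from esocad import GeneratorConfig, GrayImage, generate, preprocess_pipeline
from esocad.pipeline import extract_features


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_image(rng):
    """A 32x32 8-bit noise image."""
    return GrayImage(rng.integers(0, 256, size=(32, 32), dtype=np.uint8), id="noise32")


@pytest.fixture
def constant_image():
    return GrayImage(np.full((32, 32), 7, dtype=np.uint8), id="const7")


@pytest.fixture(scope="session")
def separable_feature_table():
    """Feature table of a clearly separated synthetic cohort (shared across tests)."""
    cfg = GeneratorConfig(n_per_class=30, separation=2.0, noise_sigma=5.0, seed=1)
    images = [(preprocess_pipeline(img), label) for img, label in generate(cfg)]
    return extract_features(images)
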
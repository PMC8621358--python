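import numpy as np
import pytest

from spikeseg import synthetic_data as sd
from spikeseg.io_formats import BinaryMask, ImageRecord


@pytest.fixture(scope="session")
def small_scene() -> sd.SceneTruth:
    """One deterministic small scene shared across read-only tests."""
    return sd.generate_scene(sd.SceneConfig(height=300, width=256, n_spikes=3, seed=11))


@pytest.fixture(scope="session")
def default_scene() -> sd.SceneTruth:
    """A default-size (595 x 512) scene for pipeline-level tests."""
    return sd.generate_scene(sd.SceneConfig(seed=7, n_spikes=3))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_image(rng: np.random.Generator, height: int = 32, width: int = 32) -> ImageRecord:
    return ImageRecord(rng.integers(0, 256, size=(height, width, 3), dtype=np.uint8))


def random_mask(rng: np.random.Generator, height: int = 32, width: int = 32) -> BinaryMask:
    return BinaryMask((rng.random((height, width)) < 0.3).astype(np.uint8))
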
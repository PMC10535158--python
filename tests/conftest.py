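import numpy as np
import pytest

from crustavision import synthetic as syn

IMAGE_SIZE = (160, 90)  # small frames keep rendering cheap in tests


@pytest.fixture(scope="session")
def small_video() -> syn.SyntheticVideo:
    """3-event synthetic video shared across tests (read-only)."""
    schedule = syn.random_schedule(520, 3, seed=7)
    return syn.generate_video(schedule, image_size=IMAGE_SIZE, seed=7)


@pytest.fixture(scope="session")
def rgb_image() -> np.ndarray:
    rng = np.random.default_rng(0)
    return rng.integers(0, 256, size=(90, 160, 3), dtype=np.uint8)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
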
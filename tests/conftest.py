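import numpy as np
import pytest
from hypothesis import settings

from brightseg import Image

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def step_image():
    """Ideal vertical 0|255 step, 64x64, boundary between columns 31 and 32."""
    px = np.where(np.arange(64)[None, :] < 32, 0, 255) * np.ones((64, 1), dtype=np.int64)
    return Image(pixels=px.astype(np.int64), bit_depth=8)


def random_image(rng, shape=(32, 32), bit_depth=8, smooth=0.0):
    arr = rng.integers(0, 2**bit_depth, size=shape).astype(np.float64)
    if smooth:
        from scipy import ndimage

        arr = ndimage.gaussian_filter(arr, smooth)
    return Image(pixels=np.clip(np.rint(arr), 0, 2**bit_depth - 1).astype(np.int64), bit_depth=bit_depth)
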
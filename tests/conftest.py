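import numpy as np
import pytest

from cthist import ImageVolume, RoiMask


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_roi(rng, shape=(9, 8, 7), spacing=(0.5, 0.5, 0.5), p_fg=0.4):
    """A random HU volume with a random nonempty mask."""
    data = rng.normal(200.0, 150.0, size=shape)
    mask = rng.random(shape) < p_fg
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    return ImageVolume(data, spacing), RoiMask(mask, spacing)
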
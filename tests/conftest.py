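import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_channel(seed, shape=(8, 8), levels=256):
    """Fixed-seed random channel, optionally quantized to fewer levels."""
    r = np.random.default_rng(seed)
    if levels >= 256:
        return r.integers(0, 256, size=shape).astype(np.uint8)
    vals = np.sort(r.choice(256, size=levels, replace=False))
    return vals[r.integers(0, levels, size=shape)].astype(np.uint8)


def bimodal_channel(seed, shape=(48, 48), modes=(60, 180), sd=10.0):
    """Two-Gaussian mixture channel, clipped to [0, 255]."""
    r = np.random.default_rng(seed)
    pick = r.random(shape) < 0.5
    vals = np.where(pick, r.normal(modes[0], sd, shape), r.normal(modes[1], sd, shape))
    return np.clip(np.round(vals), 0, 255).astype(np.uint8)


def two_valued_channel(seed, shape=(32, 32), lo=50, hi=200):
    r = np.random.default_rng(seed)
    return np.where(r.random(shape) < 0.5, lo, hi).astype(np.uint8)


def segmentation_like_mask(seed, shape=(40, 40)):
    """Random mask with the structure segmentation actually produces:
    blob-shaped objects, punched single-pixel holes, isolated specks."""
    from skimage.draw import disk

    r = np.random.default_rng(seed)
    mask = np.zeros(shape, dtype=np.uint8)
    for _ in range(int(r.integers(2, 8))):
        rad = r.uniform(3, 6)
        center = (r.uniform(rad, shape[0] - rad), r.uniform(rad, shape[1] - rad))
        rr, cc = disk(center, rad, shape=shape)
        mask[rr, cc] = 1
    for _ in range(int(r.integers(0, 5))):
        i, j = int(r.integers(1, shape[0] - 1)), int(r.integers(1, shape[1] - 1))
        if mask[i, j]:
            mask[i, j] = 0
    for _ in range(int(r.integers(0, 6))):
        i, j = int(r.integers(0, shape[0])), int(r.integers(0, shape[1]))
        if mask[max(0, i - 2) : i + 3, max(0, j - 2) : j + 3].sum() == 0:
            mask[i, j] = 1
    return mask
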
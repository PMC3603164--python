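"""White-slide background removal and local contrast equalization.

Stained tissue is textured, empty slide glass is not: the local intensity
range (max minus min over a small window) is zero exactly where a window is
constant, so multiplying the per-channel range images and binarizing marks
tissue with 1 and white space with 0.  The mask is median-filtered to drop
isolated noise pixels, multiplied into each color component, and the masked
components are then contrast-equalized with CLAHE (uniform target histogram)
so nuclei stand out from intercellular matter regardless of illumination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure

from ._validation import (
    require_channel,
    require_mask,
    require_odd_window,
    require_rgb,
    require_same_shape,
)
from .image_io import split_channels

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the background-removal and CLAHE stage.

    Attributes
    ----------
    range_window : int
        Side of the local-range window, odd, default 3.
    mask_median_window : int
        Side of the median filter applied to the binary tissue mask, odd,
        default 5 (removes isolated pixels and pixel pairs).
    clahe_clip_limit : float
        CLAHE clip limit as a fraction in (0, 1], default 0.01.
    clahe_tile : int or None
        Side in pixels of a CLAHE tile, default 5 (one tile per
        non-overlapping 5x5 neighbourhood).  ``None`` falls back to the
        conventional 8x8 tile grid (tile side = image side / 8), which is
        the pragmatic choice for very large images.
    """

    range_window: int = 3
    mask_median_window: int = 5
    clahe_clip_limit: float = 0.01
    clahe_tile: int | None = 5

    def __post_init__(self):
        require_odd_window(self.range_window, "range_window")
        require_odd_window(self.mask_median_window, "mask_median_window")
        if not (0.0 < self.clahe_clip_limit <= 1.0):
            raise ValueError("clahe_clip_limit must be in (0, 1]")
        if self.clahe_tile is not None and self.clahe_tile < 1:
            raise ValueError("clahe_tile must be >= 1 or None")


def local_range(ch: np.ndarray, window: int = 3) -> np.ndarray:
    """Per-pixel local max minus local min over a ``window x window`` patch.

    Borders are handled by replicate padding.  A value of 0 at a pixel means
    its whole window is constant.
    """
    ch = require_channel(ch)
    require_odd_window(window, "window")
    hi = ndi.maximum_filter(ch, size=window, mode="nearest")
    lo = ndi.minimum_filter(ch, size=window, mode="nearest")
    return (hi.astype(np.int16) - lo.astype(np.int16)).astype(np.uint8)


def background_mask(r, g, b, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Binary tissue mask: 1 where the product of the three local-range images
    is nonzero, 0 over constant (white-slide) regions, then median-filtered.
    """
    cfg = cfg or PreprocessConfig()
    r = require_channel(r, "red")
    g = require_channel(g, "green")
    b = require_channel(b, "blue")
    require_same_shape(r, g, b)
    jr = local_range(r, cfg.range_window)
    jg = local_range(g, cfg.range_window)
    jb = local_range(b, cfg.range_window)
    mask = ((jr > 0) & (jg > 0) & (jb > 0)).astype(np.uint8)
    mask = ndi.median_filter(mask, size=cfg.mask_median_window, mode="nearest")
    if not mask.any():
        logger.warning("background_mask: no foreground found (constant image?)")
    return mask


def apply_mask(mask, r, g, b):
    """Multiply the mask into each component; masked-out pixels become 0."""
    mask = require_mask(mask)
    require_same_shape(mask, r, g, b)
    m = mask.astype(np.uint8)
    return (r * m).astype(np.uint8), (g * m).astype(np.uint8), (b * m).astype(np.uint8)


def clahe(ch: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Contrast Limited Adaptive Histogram Equalization of one channel.

    Uses a uniform (flat) target histogram per tile; output stays in
    [0, 255].  A constant channel is returned unchanged (there is no
    contrast to amplify, and equalizing it would be undefined).
    """
    cfg = cfg or PreprocessConfig()
    ch = require_channel(ch)
    if ch.min() == ch.max():
        return ch.astype(np.uint8).copy()
    out = exposure.equalize_adapthist(
        ch.astype(np.uint8),
        kernel_size=cfg.clahe_tile,
        clip_limit=cfg.clahe_clip_limit,
    )
    return np.round(out * 255.0).astype(np.uint8)


@dataclass
class PreprocessResult:
    """Outputs of the preprocessing stage.

    ``masked`` are the background-suppressed components K_r, K_g, K_b;
    ``enhanced`` are the same components after CLAHE (thresholds are learned
    on these); ``mask`` is the binary tissue mask.
    """

    mask: np.ndarray
    masked: tuple
    enhanced: tuple


def preprocess_image(img: np.ndarray, cfg: PreprocessConfig | None = None) -> PreprocessResult:
    """Full preprocessing: split, background removal, masking, CLAHE."""
    cfg = cfg or PreprocessConfig()
    img = require_rgb(img)
    r, g, b = split_channels(img)
    mask = background_mask(r, g, b, cfg)
    kr, kg, kb = apply_mask(mask, r, g, b)
    enhanced = tuple(clahe(k, cfg) for k in (kr, kg, kb))
    return PreprocessResult(mask=mask, masked=(kr, kg, kb), enhanced=enhanced)
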
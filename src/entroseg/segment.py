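"""Per-channel thresholding, mask combination and RGB reconstruction.

Stained nuclei carry low red, low green and high blue intensities, so the
red and green components are binarized *below* their thresholds and the blue
component *above* its threshold; the three binary images are multiplied
(logical AND) into the nuclei mask BW, and the original color components are
multiplied by BW to reconstruct the segmented RGB image R.

Thresholds are learned on the preprocessed (masked + CLAHE) components but
applied to the original components; ``apply_on_enhanced=True`` switches to
thresholding the enhanced components instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from ._validation import require_channel, require_mask, require_rgb, require_same_shape
from .cclsc import EntropyConfig, ThresholdResult, find_threshold
from .image_io import merge_channels, split_channels
from .preprocess import PreprocessConfig, PreprocessResult, preprocess_image


class ThresholdTriple(NamedTuple):
    """Optimal thresholds of the red, green and blue components."""

    t_r: int
    t_g: int
    t_b: int


def binarize_channel(ch: np.ndarray, t: int, polarity: str) -> np.ndarray:
    """Binary object mask of one channel.

    ``polarity='below'`` marks intensity <= t (the object set {0..t});
    ``polarity='above'`` marks intensity > t.
    """
    ch = require_channel(ch)
    if not (0 <= t <= 255):
        raise ValueError(f"threshold must be in [0, 255], got {t}")
    if polarity == "below":
        return (ch <= t).astype(np.uint8)
    if polarity == "above":
        return (ch > t).astype(np.uint8)
    raise ValueError("polarity must be 'below' or 'above'")


def combine_masks(br, bg, bb) -> np.ndarray:
    """Element-wise AND (product) of the three channel masks."""
    br = require_mask(br, "red mask")
    bg = require_mask(bg, "green mask")
    bb = require_mask(bb, "blue mask")
    require_same_shape(br, bg, bb)
    return (br & bg & bb).astype(np.uint8)


def reconstruct_rgb(bw, r, g, b) -> np.ndarray:
    """Keep original intensities where BW=1, zero elsewhere."""
    bw = require_mask(bw)
    require_same_shape(bw, r, g, b)
    m = bw.astype(np.uint8)
    return merge_channels(
        (r * m).astype(np.uint8), (g * m).astype(np.uint8), (b * m).astype(np.uint8)
    )


@dataclass
class SegmentationResult:
    """Output of the segmentation stage."""

    rgb: np.ndarray
    thresholds: ThresholdTriple
    mask: np.ndarray
    channel_masks: tuple
    threshold_results: tuple
    preprocess: PreprocessResult


def segment_image(
    img: np.ndarray,
    pre_cfg: PreprocessConfig | None = None,
    ent_cfg: EntropyConfig | None = None,
    apply_on_enhanced: bool = False,
) -> SegmentationResult:
    """Full segmentation: preprocess, per-channel thresholds, combine, rebuild.

    Raises
    ------
    DegenerateImageError
        Propagated from threshold selection when a component carries no
        usable signal (e.g. a pure-white image with no foreground).
    """
    img = require_rgb(img)
    pre_cfg = pre_cfg or PreprocessConfig()
    ent_cfg = ent_cfg or EntropyConfig()
    pre = preprocess_image(img, pre_cfg)
    results: tuple[ThresholdResult, ...] = tuple(
        find_threshold(k, ent_cfg) for k in pre.enhanced
    )
    thresholds = ThresholdTriple(*(res.threshold for res in results))
    targets = split_channels(img) if not apply_on_enhanced else pre.enhanced
    b_r = binarize_channel(targets[0], thresholds.t_r, "below")
    b_g = binarize_channel(targets[1], thresholds.t_g, "below")
    b_b = binarize_channel(targets[2], thresholds.t_b, "above")
    bw = combine_masks(b_r, b_g, b_b)
    i_r, i_g, i_b = split_channels(img)
    rgb = reconstruct_rgb(bw, i_r, i_g, i_b)
    return SegmentationResult(
        rgb=rgb,
        thresholds=thresholds,
        mask=bw,
        channel_masks=(b_r, b_g, b_b),
        threshold_results=results,
        preprocess=pre,
    )
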
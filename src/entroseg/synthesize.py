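"""Synthetic stained-histology images with exact ground truth.

Emulates the color statistics of hematoxylin-type staining as the pipeline
expects them: dark bluish elliptical nuclei (low red, low green, blue above
the surrounding tissue) over a lighter pinkish background, optionally framed
by pure-white slide margin and sprinkled with single-pixel nucleus-colored
specks (salt noise) that postprocessing is expected to remove.  Every run is
fully reproducible from the seed, and the returned ground truth carries
centroids, radii, a label mask and the injected speck count.

What this generator does *not* emulate: chromatin texture, out-of-focus
blur, touching/overlapping nuclei (unless requested) and stain variation
across a slide.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from .errors import CapacityError


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic histology image generator.

    Defaults model a modest 128x128 field with a dozen well-separated
    nuclei.  ``nucleus_color_mean`` is dark bluish-purple (low red/green,
    high blue); ``background_color_mean`` is pinkish tissue whose blue lies
    *below* the nuclear blue so all three channel polarities used by the
    segmenter hold.  ``color_sd`` is the per-pixel Gaussian noise sd in
    intensity levels.
    """

    height: int = 128
    width: int = 128
    n_nuclei: int = 12
    radius_range: tuple = (4, 9)
    nucleus_color_mean: tuple = (60, 55, 160)
    background_color_mean: tuple = (210, 160, 130)
    color_sd: float = 10.0
    white_margin: int = 0
    n_specks: int = 0
    overlap_allowed: bool = False
    seed: int = 0
    max_attempts: int = 1000

    def __post_init__(self):
        if self.n_nuclei < 0 or self.n_specks < 0:
            raise ValueError("n_nuclei and n_specks must be >= 0")
        if self.radius_range[0] < 2 or self.radius_range[0] > self.radius_range[1]:
            raise ValueError("radius_range must satisfy 2 <= min <= max")
        for c in (*self.nucleus_color_mean, *self.background_color_mean):
            if not (0 <= c <= 255):
                raise ValueError("color means must be in [0, 255]")
        if self.white_margin < 0:
            raise ValueError("white_margin must be >= 0")


@dataclass
class GroundTruth:
    """Exact truth of one generated image."""

    centroids: list  # (row, col) per nucleus
    radii: list  # major semi-axis per nucleus, pixels
    label_mask: np.ndarray  # 0 background, i for nucleus i
    n_specks: int
    speck_positions: list = field(default_factory=list)

    @property
    def n_nuclei(self) -> int:
        return len(self.centroids)

    @property
    def mean_radius(self) -> float:
        return float(np.mean(self.radii)) if self.radii else 0.0


def _place_nuclei(cfg: SynthConfig, rng: np.random.Generator):
    """Rejection-sample centers/radii so disks of the major radii stay
    pairwise separated by more than the sum of radii (unless overlap is
    allowed)."""
    placed = []  # (row, col, major, minor, angle)
    margin = cfg.white_margin
    for _ in range(cfg.n_nuclei):
        for attempt in range(cfg.max_attempts):
            major = rng.uniform(*cfg.radius_range)
            minor = major * rng.uniform(0.65, 1.0)
            angle = rng.uniform(0.0, np.pi)
            pad = int(np.ceil(major)) + 1
            lo_r, hi_r = margin + pad, cfg.height - margin - pad
            lo_c, hi_c = margin + pad, cfg.width - margin - pad
            if lo_r >= hi_r or lo_c >= hi_c:
                raise CapacityError("image too small for the requested radii")
            row = rng.uniform(lo_r, hi_r)
            col = rng.uniform(lo_c, hi_c)
            if cfg.overlap_allowed or all(
                np.hypot(row - pr, col - pc) > major + pm + 1.0
                for pr, pc, pm, _, _ in placed
            ):
                placed.append((row, col, major, minor, angle))
                break
        else:
            raise CapacityError(
                f"could not place nucleus {len(placed) + 1} of {cfg.n_nuclei} "
                f"after {cfg.max_attempts} attempts"
            )
    return placed


def generate(cfg: SynthConfig | None = None, **overrides):
    """Generate one synthetic image and its ground truth.

    Keyword overrides are applied on top of ``cfg`` (or the defaults), e.g.
    ``generate(n_nuclei=20, seed=3)``.

    Returns
    -------
    (numpy.ndarray, GroundTruth)
        ``H x W x 3`` uint8 image and the exact truth.
    """
    cfg = replace(cfg or SynthConfig(), **overrides)
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.height, cfg.width

    img = rng.normal(
        np.asarray(cfg.background_color_mean, dtype=np.float64), cfg.color_sd, (h, w, 3)
    )
    label_mask = np.zeros((h, w), dtype=np.int32)
    placed = _place_nuclei(cfg, rng)
    centroids, radii = [], []
    for idx, (row, col, major, minor, angle) in enumerate(placed, start=1):
        rr, cc = draw_ellipse(row, col, major, minor, shape=(h, w), rotation=angle)
        img[rr, cc] = rng.normal(
            np.asarray(cfg.nucleus_color_mean, dtype=np.float64),
            cfg.color_sd,
            (rr.size, 3),
        )
        label_mask[rr, cc] = idx
        centroids.append((row, col))
        radii.append(major)

    speck_positions = []
    if cfg.n_specks:
        speck_color = np.asarray(cfg.nucleus_color_mean, dtype=np.float64)
        buffer = cfg.white_margin + 2
        for _ in range(cfg.n_specks):
            for attempt in range(cfg.max_attempts):
                r = int(rng.integers(buffer, h - buffer))
                c = int(rng.integers(buffer, w - buffer))
                window = label_mask[max(0, r - 3) : r + 4, max(0, c - 3) : c + 4]
                near_speck = any(
                    abs(r - sr) <= 3 and abs(c - sc) <= 3 for sr, sc in speck_positions
                )
                if window.max() == 0 and not near_speck:
                    img[r, c] = speck_color
                    speck_positions.append((r, c))
                    break
            else:
                raise CapacityError("could not place the requested specks")

    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    if cfg.white_margin:
        m = cfg.white_margin
        img[:m, :] = 255
        img[-m:, :] = 255
        img[:, :m] = 255
        img[:, -m:] = 255

    truth = GroundTruth(
        centroids=centroids,
        radii=radii,
        label_mask=label_mask,
        n_specks=len(speck_positions),
        speck_positions=speck_positions,
    )
    return img, truth
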
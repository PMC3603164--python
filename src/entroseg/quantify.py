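"""Nuclei counting: grayscale conversion, Otsu binarization, labeling.

The postprocessed segmentation R is converted to grayscale (luma weights),
binarized with Otsu's method (between-class-variance maximization over the
256-bin histogram, smallest maximizer on ties) and each connected component
of the foreground is counted as one nucleus.  Since R's background is
exactly 0, the foreground is the gray > T class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from ._validation import require_channel, require_mask, require_rgb
from .errors import DegenerateImageError


@dataclass
class NucleusObject:
    """One labeled connected component."""

    label: int
    centroid: tuple  # (row, col), 0-based
    area: int


@dataclass
class QuantReport:
    """Nuclei count and per-object geometry of one image."""

    count: int
    objects: list = field(default_factory=list)
    otsu_threshold: int | None = None
    count_pre_postprocess: int | None = None

    def to_dict(self):
        return {
            "count": self.count,
            "otsu_threshold": self.otsu_threshold,
            "count_pre_postprocess": self.count_pre_postprocess,
            "objects": [
                {
                    "label": o.label,
                    "centroid_row": o.centroid[0],
                    "centroid_col": o.centroid[1],
                    "area": o.area,
                }
                for o in self.objects
            ],
        }


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Luma conversion: round(0.299 R + 0.587 G + 0.114 B)."""
    img = require_rgb(img)
    gray = (
        0.299 * img[:, :, 0].astype(np.float64)
        + 0.587 * img[:, :, 1].astype(np.float64)
        + 0.114 * img[:, :, 2].astype(np.float64)
    )
    return np.round(gray).astype(np.uint8)


def otsu_threshold(ch: np.ndarray) -> int:
    """Otsu's threshold over the fixed 256-bin histogram.

    Returns the smallest t maximizing the between-class variance
    w0(t) w1(t) (mu0(t) - mu1(t))^2 over t in {0..254} with both classes
    non-empty.

    Raises
    ------
    DegenerateImageError
        If the channel holds fewer than two distinct values.
    """
    ch = require_channel(ch)
    hist = np.bincount(ch.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise DegenerateImageError("single-valued channel has no Otsu threshold")
    total = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)[:-1]
    w1 = total - w0
    cum_mean = np.cumsum(hist * levels)[:-1]
    grand_mean = cum_mean[-1] + hist[255] * 255.0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_mean / w0
        mu1 = (grand_mean - cum_mean) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[(w0 == 0) | (w1 == 0)] = -np.inf
    return int(np.argmax(sigma_b))  # argmax returns the first (smallest) maximizer


def count_nuclei(bw: np.ndarray, connectivity: int = 8, min_area: int = 0) -> QuantReport:
    """Label connected components of a binary mask and report count/geometry."""
    bw = require_mask(bw)
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = (
        ndi.generate_binary_structure(2, 1)
        if connectivity == 4
        else np.ones((3, 3), dtype=bool)
    )
    labels, n = ndi.label(bw, structure=structure)
    objects = []
    if n:
        areas = np.bincount(labels.ravel())[1:]
        centroids = ndi.center_of_mass(bw, labels, index=range(1, n + 1))
        for lab, (area, cen) in enumerate(zip(areas, centroids), start=1):
            if area < min_area:
                continue
            objects.append(
                NucleusObject(
                    label=lab, centroid=(float(cen[0]), float(cen[1])), area=int(area)
                )
            )
    return QuantReport(count=len(objects), objects=objects)


def quantify_image(img: np.ndarray, connectivity: int = 8, min_area: int = 0) -> QuantReport:
    """Grayscale + Otsu + connected-component count of a segmented image.

    An all-zero image (empty segmentation) yields an empty report rather
    than a degenerate-input error.
    """
    img = require_rgb(img)
    gray = to_grayscale(img)
    if gray.max() == 0:
        return QuantReport(count=0, objects=[], otsu_threshold=None)
    t = otsu_threshold(gray)
    fg = (gray > t).astype(np.uint8)
    report = count_nuclei(fg, connectivity=connectivity, min_area=min_area)
    report.otsu_threshold = t
    return report
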
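"""Lightweight shape/value checks shared by the pipeline modules."""

import numpy as np


def require_channel(arr, name="channel"):
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D raster, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError(f"{name} values must lie in [0, 255]")
    return arr


def require_rgb(arr, name="image"):
    arr = np.asarray(arr)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{name} must be H x W x 3, got shape {arr.shape}")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError(f"{name} values must lie in [0, 255]")
    return arr


def require_mask(arr, name="mask"):
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D raster, got shape {arr.shape}")
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 values")
    return arr


def require_same_shape(*arrays, names=None):
    shapes = [np.asarray(a).shape[:2] for a in arrays]
    if len(set(shapes)) > 1:
        label = " vs ".join(str(s) for s in shapes)
        raise ValueError(f"shape mismatch: {label}")


def require_odd_window(w, name="window"):
    if w < 3 or w % 2 == 0:
        raise ValueError(f"{name} must be an odd integer >= 3, got {w}")
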
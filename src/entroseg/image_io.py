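"""Read/write raster images and split/merge RGB color components.

All downstream stages operate on plain ``numpy`` arrays: an RGB image is an
``H x W x 3`` ``uint8`` array, a single color component ("channel") is an
``H x W`` ``uint8`` array, and a binary mask is an ``H x W`` array of 0/1.
Coordinates are (row, col), 0-based, origin at the top-left corner, and that
convention is used everywhere including reported centroids.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import tifffile
from PIL import Image

from ._validation import require_channel, require_rgb, require_same_shape
from .errors import UnsupportedFormatError

logger = logging.getLogger(__name__)

_PNG_EXTS = {".png"}
_TIFF_EXTS = {".tif", ".tiff"}


def read_image(path) -> np.ndarray:
    """Read a PNG or TIFF file as an 8-bit RGB array.

    Grayscale files are replicated across the three channels; 16-bit data is
    rescaled to 8-bit (with a logged warning); an alpha channel is dropped
    (with a logged warning).

    Parameters
    ----------
    path : path-like
        Location of a ``.png``, ``.tif`` or ``.tiff`` file.

    Returns
    -------
    numpy.ndarray
        ``H x W x 3`` ``uint8`` raster.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"image file not found: {path}")
    ext = os.path.splitext(path)[1].lower()
    if ext in _PNG_EXTS:
        arr = np.asarray(Image.open(path))
    elif ext in _TIFF_EXTS:
        arr = tifffile.imread(path)
    else:
        raise UnsupportedFormatError(
            f"unsupported image format {ext!r}; expected .png, .tif or .tiff"
        )
    return _coerce_rgb8(arr, path)


def _coerce_rgb8(arr: np.ndarray, origin: str) -> np.ndarray:
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.floating):
        raise UnsupportedFormatError(f"floating-point image data in {origin}")
    if arr.dtype != np.uint8:
        # Treat any wider integer raster as 16-bit sensor data.
        logger.warning("%s: rescaling 16-bit data to 8-bit", origin)
        arr = np.round(arr.astype(np.float64) * (255.0 / 65535.0))
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        logger.warning("%s: dropping alpha channel", origin)
        arr = arr[:, :, :3]
    elif arr.ndim == 3 and arr.shape[2] == 3:
        pass
    else:
        raise UnsupportedFormatError(
            f"cannot interpret raster of shape {arr.shape} in {origin}"
        )
    return np.ascontiguousarray(arr)


def write_image(path, pixels: np.ndarray) -> None:
    """Write an 8-bit grayscale or RGB array to PNG or TIFF (by extension)."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    arr = np.asarray(pixels, dtype=np.uint8)
    if ext in _PNG_EXTS:
        Image.fromarray(arr).save(path)
    elif ext in _TIFF_EXTS:
        tifffile.imwrite(path, arr)
    else:
        raise UnsupportedFormatError(
            f"unsupported image format {ext!r}; expected .png, .tif or .tiff"
        )


def split_channels(img: np.ndarray):
    """Split an RGB image into its red, green and blue component rasters."""
    img = require_rgb(img)
    r = np.ascontiguousarray(img[:, :, 0])
    g = np.ascontiguousarray(img[:, :, 1])
    b = np.ascontiguousarray(img[:, :, 2])
    return r, g, b


def merge_channels(r: np.ndarray, g: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Stack three component rasters back into an RGB image (inverse of split)."""
    r = require_channel(r, "red")
    g = require_channel(g, "green")
    b = require_channel(b, "blue")
    require_same_shape(r, g, b)
    return np.stack([r, g, b], axis=2)
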
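"""Raster input/output for fundus images, FOV masks and vessel maps.

All rasters are plain numpy arrays indexed (row, col) with the origin at the
top-left. Color images are H×W×3 uint8 in R,G,B order; binary maps are H×W
bool. Every format dialect (PNG, TIFF, PPM, GIF palette decoding, ...) is
confined to this module so the math core never sees a file.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import FormatError

logger = logging.getLogger(__name__)

SUPPORTED_EXTENSIONS = {".png", ".tif", ".tiff", ".ppm", ".pgm", ".gif", ".jpg", ".jpeg"}


def _read_raw(path: str | os.PathLike) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() not in SUPPORTED_EXTENSIONS:
        raise FormatError(f"unsupported image extension {path.suffix!r}: {path}")
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # decoder failure -> format error naming the file
        raise FormatError(f"could not decode image file {path}: {exc}") from exc
    if arr.ndim == 4:  # animated GIF: first frame
        arr = arr[0]
    return arr


def read_color_image(path: str | os.PathLike) -> np.ndarray:
    """Read an 8-bit RGB image as an H×W×3 uint8 array.

    Grayscale files are replicated to three channels (with a logged warning);
    an alpha channel, if present, is dropped.
    """
    arr = _read_raw(path)
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    if arr.ndim == 2:
        logger.warning("grayscale image %s replicated to 3 channels", path)
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"unexpected image layout {arr.shape} in {path}")
    return arr


def read_binary_map(path: str | os.PathLike, threshold: int = 127) -> np.ndarray:
    """Read a label image as a boolean map: pixel > ``threshold`` → True.

    Multi-channel files (e.g. palette GIFs decoded to RGB) use the first
    channel. The default threshold 127 is robust to compression ringing in
    labels stored as 0/255.
    """
    arr = _read_raw(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return arr > threshold


def write_binary_map(binmap: np.ndarray, path: str | os.PathLike) -> None:
    """Write a boolean map as a single-channel PNG with values 0/255.

    Round-trips bit-exactly through :func:`read_binary_map`.
    """
    binmap = np.asarray(binmap)
    out = np.where(binmap.astype(bool), 255, 0).astype(np.uint8)
    iio.imwrite(Path(path), out, extension=".png")
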
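"""Response enhancement (top-hat) and manual binarization."""

from __future__ import annotations

import logging

import numpy as np
import scipy.ndimage as ndi

from .errors import ContractError, ParameterError

logger = logging.getLogger(__name__)


def top_hat(img: np.ndarray, se_size: int = 11) -> np.ndarray:
    """White top-hat: the image minus its grayscale opening.

    The opening uses a flat square structuring element of side ``se_size``
    (odd) with reflective padding; subtracting it flattens the non-uniform
    background and keeps structures thinner than the element — the vessels.
    """
    img = np.asarray(img, dtype=np.float64)
    if se_size % 2 == 0 or se_size < 3:
        raise ParameterError("se_size must be odd and >= 3")
    if se_size >= min(img.shape):
        raise ParameterError("structuring element must be smaller than the image")
    opened = ndi.grey_opening(img, size=(se_size, se_size), mode="reflect")
    return img - opened


def binarize(resp: np.ndarray, fov: np.ndarray, threshold: float) -> np.ndarray:
    """Threshold a response map after min-max normalization over the FOV.

    A pixel is foreground iff it lies inside the FOV and its normalized
    response strictly exceeds ``threshold``. Normalizing over FOV pixels
    only keeps the dark rim from stretching the scale.
    """
    resp = np.asarray(resp, dtype=np.float64)
    fov = np.asarray(fov, dtype=bool)
    if resp.shape != fov.shape:
        raise ContractError(f"response shape {resp.shape} != FOV shape {fov.shape}")
    if not fov.any():
        raise ContractError("empty FOV")
    if not 0.0 <= threshold <= 1.0:
        raise ParameterError("threshold must lie in [0, 1]")
    vals = resp[fov]
    lo, hi = float(vals.min()), float(vals.max())
    if hi - lo < 1e-30:
        logger.warning("constant response inside FOV: returning an empty map")
        return np.zeros(resp.shape, dtype=bool)
    norm = (resp - lo) / (hi - lo)
    return fov & (norm > threshold)
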
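"""Preprocessing: green channel, FOV mask, CLAHE and masking.

Produces the masked, contrast-enhanced green-channel image that feeds the
vessel filter. Gray images are H×W float arrays in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage import color as skcolor
from skimage import exposure
from skimage.filters import threshold_otsu

from .errors import ContractError, MaskError, ParameterError

_EIGHT = np.ones((3, 3), bool)


@dataclass(frozen=True)
class ClaheParams:
    """Contrast-limited adaptive histogram equalization parameters.

    ``tiles_x`` × ``tiles_y`` is the tile grid; ``clip_limit`` is the
    histogram clip fraction in (0, 1]; ``n_bins`` the histogram resolution.
    """

    tiles_x: int = 8
    tiles_y: int = 8
    clip_limit: float = 0.01
    n_bins: int = 256

    def __post_init__(self) -> None:
        if self.tiles_x < 2 or self.tiles_y < 2:
            raise ParameterError("CLAHE tile grid must be at least 2x2")
        if not 0 < self.clip_limit <= 1:
            raise ParameterError("clip_limit must lie in (0, 1]")
        if self.n_bins < 16:
            raise ParameterError("n_bins must be >= 16")


def _check_color(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ContractError(f"expected an H×W×3 color image, got shape {img.shape}")
    return img


def extract_green(img: np.ndarray) -> np.ndarray:
    """Extract the green channel rescaled to [0, 1].

    The green band of a fundus photograph carries the strongest
    vessel/background contrast; red and blue are saturated or noisy.
    """
    img = _check_color(img)
    return img[:, :, 1].astype(np.float64) / 255.0


def compute_fov_mask(
    img: np.ndarray,
    method: str = "otsu",
    fixed_threshold: float = 15.0,
    erode_px: int = 0,
) -> np.ndarray:
    """Locate the circular field of view by thresholding CIELab luminosity.

    The image is converted to CIE L*a*b* (D65); the L plane (range [0, 100])
    is thresholded (Otsu by default, or a fixed level), interior holes are
    filled and only the largest 8-connected component is kept — the bright
    retinal disc on its dark border.
    """
    img = _check_color(img)
    lab = skcolor.rgb2lab(img)
    lum = lab[:, :, 0]
    if np.ptp(lum) < 1e-9:
        raise MaskError("no FOV found: luminosity plane is constant")
    if method == "otsu":
        thr = threshold_otsu(lum)
    elif method == "fixed":
        thr = float(fixed_threshold)
    else:
        raise ParameterError(f"unknown FOV method {method!r}")
    mask = lum > thr
    if not mask.any():
        raise MaskError("no FOV found: threshold left no foreground")
    mask = ndi.binary_fill_holes(mask)
    labels, n = ndi.label(mask, structure=_EIGHT)
    if n > 1:
        areas = np.bincount(labels.ravel())[1:]
        mask = labels == (int(np.argmax(areas)) + 1)
    if erode_px > 0:
        mask = ndi.binary_erosion(mask, structure=_EIGHT, iterations=erode_px)
        if not mask.any():
            raise MaskError("no FOV found: erosion removed the mask")
    return mask


def clahe(img: np.ndarray, params: ClaheParams | None = None) -> np.ndarray:
    """Tile-based histogram equalization with clipped histograms.

    Per-tile histograms are clipped at ``clip_limit`` × (tile pixels / bins),
    the excess redistributed uniformly, and the per-tile mappings blended
    bilinearly; output stays in [0, 1].
    """
    params = params or ClaheParams()
    img = np.asarray(img, dtype=np.float64)
    h, w = img.shape
    if h < params.tiles_y or w < params.tiles_x:
        raise ParameterError(
            f"image {h}x{w} smaller than the {params.tiles_y}x{params.tiles_x} tile grid"
        )
    kernel = (max(h // params.tiles_y, 1), max(w // params.tiles_x, 1))
    if np.ptp(img) < 1e-12:
        # one-bin histogram: equalization is the identity up to the mapping
        # convention; keep the input untouched
        return img.copy()
    out = exposure.equalize_adapthist(
        np.clip(img, 0.0, 1.0), kernel_size=kernel,
        clip_limit=params.clip_limit, nbins=params.n_bins,
    )
    return np.clip(out, 0.0, 1.0)


def apply_mask(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero every pixel outside the mask; pixels inside pass unchanged."""
    img = np.asarray(img, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if img.shape != mask.shape:
        raise ContractError(f"image shape {img.shape} != mask shape {mask.shape}")
    return img * mask
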
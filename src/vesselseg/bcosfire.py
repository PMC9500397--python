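"""Bar-selective COSFIRE filters (B-COSFIRE) for curvilinear structures.

A B-COSFIRE filter combines the responses of center-on difference-of-Gaussians
(DoG) sub-filters sampled at polar positions (rho_i, phi_i) around the filter
center. Each sub-response is blurred (positional tolerance growing with
rho_i), shifted so the sampled point lands on the center, and the shifted
responses are merged by a weighted geometric mean — an AND-type combination
that fires only where every sub-filter fires. The positions are read off
automatically from the DoG response of a synthetic prototype (a bar for the
vessel-selective symmetric filter, a half bar for the ending-selective
asymmetric one), which is what makes the filter "trainable" without labels.

Coordinate convention (global to the package): x = column rightward,
y = row upward (so the array row axis is -y), phi measured counterclockwise
from +x. A point at (rho, phi) therefore sits at column offset rho*cos(phi)
and row offset -rho*sin(phi) from the center.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import scipy.ndimage as ndi

from .errors import ConfigurationError, ContractError, ParameterError

TWO_PI = 2.0 * math.pi


# ---------------------------------------------------------------------------
# DoG sub-filters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoGParams:
    """Difference-of-Gaussians kernel: outer std ``sigma``, inner std 0.5*sigma.

    ``truncation`` is the kernel half-width in multiples of sigma.
    """

    sigma: float
    truncation: float = 3.0
    sign: str = "center_on"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ParameterError("sigma must be positive")
        if self.truncation < 3:
            raise ParameterError("truncation must be >= 3")
        if self.sign not in ("center_on", "as_printed"):
            raise ParameterError("sign must be 'center_on' or 'as_printed'")


def dog_kernel(params: DoGParams) -> np.ndarray:
    """Sample the DoG function on a square grid.

    The center-on form subtracts the wide (sigma) Gaussian from the narrow
    (0.5*sigma) one, giving a positive central region and a negative
    surround; ``sign='as_printed'`` flips the subtraction order. The sampled
    kernel is DC-corrected (its discrete mean subtracted) so that constant
    regions produce exactly zero response, as the continuous band-pass does.
    """
    sigma = params.sigma
    radius = int(math.ceil(params.truncation * sigma))
    ax = np.arange(-radius, radius + 1, dtype=np.float64)
    xx, yy = np.meshgrid(ax, ax)
    r2 = xx * xx + yy * yy
    s_in = 0.5 * sigma
    narrow = np.exp(-r2 / (2.0 * s_in * s_in)) / (2.0 * math.pi * s_in * s_in)
    wide = np.exp(-r2 / (2.0 * sigma * sigma)) / (2.0 * math.pi * sigma * sigma)
    k = narrow - wide
    if params.sign == "as_printed":
        k = -k
    return k - k.mean()


def dog_response(img: np.ndarray, params: DoGParams) -> np.ndarray:
    """Half-wave rectified DoG convolution with reflective boundary padding."""
    img = np.asarray(img, dtype=np.float64)
    kernel = dog_kernel(params)
    if kernel.shape[0] > min(img.shape):
        raise ContractError(
            f"DoG kernel {kernel.shape[0]}px exceeds image extent {min(img.shape)}px"
        )
    resp = ndi.convolve(img, kernel, mode="reflect")
    return np.maximum(resp, 0.0)


# ---------------------------------------------------------------------------
# Filter model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CosfireTuple:
    """One sub-filter: DoG std ``sigma``, radius ``rho`` and polar angle ``phi``."""

    sigma: float
    rho: float
    phi: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ParameterError("tuple sigma must be positive")
        if self.rho < 0:
            raise ParameterError("tuple rho must be >= 0")


@dataclass(frozen=True)
class CosfireFilter:
    """A configured B-COSFIRE filter.

    ``sigma0_prime`` and ``alpha`` set the blur rule sigma' = sigma0' +
    alpha*rho; ``weight_sigma`` is the std of the Gaussian tuple weighting
    omega_i = exp(-rho_i^2 / (2*weight_sigma^2)) (None → max(rho)/3);
    ``t`` is the response-threshold fraction in [0, 1].
    """

    tuples: tuple[CosfireTuple, ...]
    kind: str = "symmetric"
    sigma0_prime: float = 3.0
    alpha: float = 0.7
    weight_sigma: float | None = None
    t: float = 0.0
    dog_sign: str = "center_on"
    truncation: float = 3.0

    def __post_init__(self) -> None:
        if len(self.tuples) < 1:
            raise ContractError("a COSFIRE filter needs at least one tuple")
        if self.kind not in ("symmetric", "asymmetric"):
            raise ParameterError("kind must be 'symmetric' or 'asymmetric'")
        if not 0.0 <= self.t <= 1.0:
            raise ParameterError("t must lie in [0, 1]")

    @property
    def effective_weight_sigma(self) -> float:
        if self.weight_sigma is not None:
            return float(self.weight_sigma)
        rho_max = max(tp.rho for tp in self.tuples)
        return rho_max / 3.0 if rho_max > 0 else 1.0

    def weights(self) -> np.ndarray:
        ws = self.effective_weight_sigma
        rho = np.array([tp.rho for tp in self.tuples])
        return np.exp(-(rho**2) / (2.0 * ws * ws))


def rotate_filter(f: CosfireFilter, psi: float) -> CosfireFilter:
    """Rotate the filter's orientation preference by ``psi`` radians.

    Every tuple's phi becomes (phi + psi) mod 2*pi; center tuples (rho = 0)
    are rotation-invariant and keep phi = 0.
    """
    rotated = tuple(
        tp if tp.rho == 0 else replace(tp, phi=(tp.phi + psi) % TWO_PI)
        for tp in f.tuples
    )
    return replace(f, tuples=rotated)


# ---------------------------------------------------------------------------
# Prototypes and automatic configuration
# ---------------------------------------------------------------------------

def make_prototype(kind: str, bar_width: int, size: int) -> np.ndarray:
    """Synthetic prototype pattern: a bright bar (or half bar) on black.

    ``symmetric`` is a vertical bar of width ``bar_width`` spanning the full
    height; ``asymmetric`` is the same bar restricted to the lower half
    (a vessel ending). ``size`` must be odd so the support center is a pixel.
    """
    if bar_width < 1:
        raise ParameterError("bar_width must be >= 1")
    if size % 2 == 0:
        raise ParameterError("size must be odd")
    if size < 8 * bar_width:
        raise ParameterError("size must be at least 8x the bar width")
    if kind not in ("symmetric", "asymmetric"):
        raise ParameterError("kind must be 'symmetric' or 'asymmetric'")
    img = np.zeros((size, size), dtype=np.float64)
    c = size // 2
    c0 = c - (bar_width - 1) // 2
    img[:, c0 : c0 + bar_width] = 1.0
    if kind == "asymmetric":
        img[:c, :] = 0.0
    return img


def _circle_samples(resp: np.ndarray, center: tuple[int, int], rho: float) -> np.ndarray:
    """Bilinear samples of ``resp`` on the circle of radius rho, at 1° steps."""
    angles = np.deg2rad(np.arange(360, dtype=np.float64))
    rows = center[0] - rho * np.sin(angles)
    cols = center[1] + rho * np.cos(angles)
    return ndi.map_coordinates(resp, np.vstack([rows, cols]), order=1, mode="constant")


def _angular_maxima(values: np.ndarray, threshold: float, merge_deg: float = 10.0) -> list[int]:
    """Circular local maxima above ``threshold``, merged within ``merge_deg``.

    Of two maxima closer than ``merge_deg`` the larger wins; ties go to the
    smaller angle.
    """
    n = len(values)
    prev = np.roll(values, 1)
    nxt = np.roll(values, -1)
    cand = np.flatnonzero((values >= prev) & (values >= nxt) & (values > threshold))
    # collapse plateaus: keep only the first index of each run of equal values
    kept: list[int] = []
    for k in cand:
        if kept and (k - kept[-1]) % n == 1 and values[k] == values[kept[-1]]:
            continue
        kept.append(int(k))
    # greedy merge by value, tie -> smaller angle
    order = sorted(kept, key=lambda k: (-values[k], k))
    chosen: list[int] = []
    for k in order:
        if all(min((k - c) % n, (c - k) % n) >= merge_deg for c in chosen):
            chosen.append(k)
    return sorted(chosen)


def configure_filter(
    prototype: np.ndarray,
    sigma: float,
    rho_set: Sequence[float],
    config_threshold: float = 0.2,
    kind: str = "symmetric",
    *,
    sigma0_prime: float = 3.0,
    alpha: float = 0.7,
    weight_sigma: float | None = None,
    t: float = 0.0,
    dog_sign: str = "center_on",
    truncation: float = 3.0,
) -> CosfireFilter:
    """Automatically configure a filter from a prototype pattern.

    The prototype's DoG response is probed at the support center (rho = 0)
    and along circles of each radius in ``rho_set`` at 1° steps; angular
    local maxima exceeding ``config_threshold`` times the circle's peak
    become tuples. A full-height bar yields paired tuples at phi and
    phi + pi; a half bar yields single-sided tuples.
    """
    if len(rho_set) == 0:
        raise ParameterError("rho_set must be nonempty")
    resp = dog_response(prototype, DoGParams(sigma, truncation, dog_sign))
    peak = resp.max()
    if peak <= 1e-12:
        raise ConfigurationError("prototype produced no structure")
    center = (prototype.shape[0] // 2, prototype.shape[1] // 2)
    tuples: list[CosfireTuple] = []
    for rho in sorted(rho_set):
        if rho == 0:
            if resp[center] > config_threshold * peak:
                tuples.append(CosfireTuple(sigma, 0.0, 0.0))
            continue
        vals = _circle_samples(resp, center, float(rho))
        vmax = vals.max()
        if vmax <= 0:
            continue
        for k in _angular_maxima(vals, config_threshold * vmax):
            tuples.append(CosfireTuple(sigma, float(rho), math.radians(k)))
    if not tuples:
        raise ConfigurationError("prototype produced no structure")
    return CosfireFilter(
        tuples=tuple(tuples),
        kind=kind,
        sigma0_prime=sigma0_prime,
        alpha=alpha,
        weight_sigma=weight_sigma,
        t=t,
        dog_sign=dog_sign,
        truncation=truncation,
    )


# ---------------------------------------------------------------------------
# Blur, shift, and combination
# ---------------------------------------------------------------------------

def _weighted_max_blur(resp: np.ndarray, sigma_p: float) -> np.ndarray:
    """max over |x'|,|y'| <= 3*sigma' of resp(shifted) * unit-peak Gaussian.

    Because resp >= 0 and the Gaussian factorizes with positive factors, the
    2-D weighted maximum separates into two 1-D passes. Out-of-image reads
    are zero.
    """
    radius = int(math.ceil(3.0 * sigma_p))
    offsets = np.arange(-radius, radius + 1)
    g = np.exp(-(offsets.astype(np.float64) ** 2) / (2.0 * sigma_p * sigma_p))

    def pass_axis(arr: np.ndarray, axis: int) -> np.ndarray:
        out = np.zeros_like(arr)
        n = arr.shape[axis]
        for off, w in zip(offsets, g):
            # out[i] = max(out[i], w * arr[i + off])
            lo_src, hi_src = max(off, 0), min(n + off, n)
            if lo_src >= hi_src:
                continue
            lo_dst, hi_dst = lo_src - off, hi_src - off
            src = [slice(None)] * arr.ndim
            dst = [slice(None)] * arr.ndim
            src[axis] = slice(lo_src, hi_src)
            dst[axis] = slice(lo_dst, hi_dst)
            np.maximum(out[tuple(dst)], w * arr[tuple(src)], out=out[tuple(dst)])
        return out

    return pass_axis(pass_axis(resp, 0), 1)


def _shift_displacement(tp: CosfireTuple) -> tuple[int, int]:
    """Row/col source displacement moving the point (rho, phi) onto the center.

    out[r, c] reads from [r - round(rho*sin(phi)), c + round(rho*cos(phi))]
    (shifts are rounded to whole pixels, the convention of the reference
    B-COSFIRE implementation).
    """
    return -int(np.rint(tp.rho * math.sin(tp.phi))), int(np.rint(tp.rho * math.cos(tp.phi)))


def _shift_padded(blur_pad: np.ndarray, pad: int, shape: tuple[int, int], tp: CosfireTuple) -> np.ndarray:
    """Crop the shifted view out of a blur computed on a zero-padded domain.

    The blur must be evaluated beyond the image frame: a pixel whose shifted
    read falls outside the frame still collects response from in-image
    pixels inside its tolerance window.
    """
    dr, dc = _shift_displacement(tp)
    h, w = shape
    return blur_pad[pad + dr : pad + dr + h, pad + dc : pad + dc + w]


def blur_shift_response(
    resp: np.ndarray,
    tp: CosfireTuple,
    sigma0_prime: float = 3.0,
    alpha: float = 0.7,
) -> np.ndarray:
    """Blur a DoG response with sigma' = sigma0' + alpha*rho, then shift it.

    ``resp`` must be the rectified DoG response for ``tp.sigma``. The blur is
    a Gaussian-weighted dilation (unit-peak weights) giving positional
    tolerance that grows with the tuple's radius; the shift moves the
    sampled point onto the filter center. Reads outside the frame see zero.
    """
    resp = np.asarray(resp, dtype=np.float64)
    sigma_p = sigma0_prime + alpha * tp.rho
    pad = int(math.ceil(tp.rho)) + 1
    blur_pad = _weighted_max_blur(np.pad(resp, pad), sigma_p)
    return _shift_padded(blur_pad, pad, resp.shape, tp)


def _blur_cache(
    img: np.ndarray, f: CosfireFilter
) -> dict[tuple[float, float], tuple[np.ndarray, int]]:
    """One DoG response per distinct sigma, one blur per distinct (sigma, rho).

    Both are invariant under filter rotation, so the cache is shared across
    all orientations. Each blur is computed on a domain zero-padded by the
    tuple radius so any rotation's shift stays in range.
    """
    dogs: dict[float, np.ndarray] = {}
    blurred: dict[tuple[float, float], tuple[np.ndarray, int]] = {}
    for tp in f.tuples:
        if tp.sigma not in dogs:
            dogs[tp.sigma] = dog_response(img, DoGParams(tp.sigma, f.truncation, f.dog_sign))
        key = (tp.sigma, tp.rho)
        if key not in blurred:
            sigma_p = f.sigma0_prime + f.alpha * tp.rho
            pad = int(math.ceil(tp.rho)) + 1
            blurred[key] = (_weighted_max_blur(np.pad(dogs[tp.sigma], pad), sigma_p), pad)
    return blurred


def _response_from_cache(
    f: CosfireFilter,
    cache: dict[tuple[float, float], tuple[np.ndarray, int]],
    shape: tuple[int, int],
) -> np.ndarray:
    weights = f.weights()
    wsum = weights.sum()
    acc = np.ones(shape, dtype=np.float64)
    for tp, w in zip(f.tuples, weights):
        blur_pad, pad = cache[(tp.sigma, tp.rho)]
        acc *= np.power(_shift_padded(blur_pad, pad, shape, tp), w / wsum)
    if f.t > 0:
        acc[acc < f.t * acc.max()] = 0.0
    return acc


def filter_response(img: np.ndarray, f: CosfireFilter) -> np.ndarray:
    """Weighted geometric mean of the blurred, shifted DoG responses.

    r_S = (prod_i s_i^{omega_i})^{1 / sum_i omega_i}, then values below
    t * max(r_S) are suppressed. A zero in any sub-response zeroes the
    output there (AND behavior).
    """
    img = np.asarray(img, dtype=np.float64)
    return _response_from_cache(f, _blur_cache(img, f), img.shape)


def rotation_tolerant_response(
    img: np.ndarray,
    f: CosfireFilter,
    n_orientations: int = 12,
    full_circle: bool = False,
) -> np.ndarray:
    """Pointwise maximum of the response over equally spaced orientations.

    Orientations are psi = k*pi/n_orientations; ``full_circle`` doubles the
    count to span [0, 2*pi), needed for the asymmetric (vessel-ending)
    filter whose prototype is not invariant under a half turn.
    """
    if n_orientations < 1:
        raise ParameterError("n_orientations must be >= 1")
    img = np.asarray(img, dtype=np.float64)
    cache = _blur_cache(img, f)
    count = 2 * n_orientations if full_circle else n_orientations
    out = None
    for k in range(count):
        resp = _response_from_cache(
            rotate_filter(f, k * math.pi / n_orientations), cache, img.shape
        )
        out = resp if out is None else np.maximum(out, resp)
    return out


def _minmax_normalize(resp: np.ndarray, fov: np.ndarray | None) -> np.ndarray:
    region = resp if fov is None else resp[fov]
    lo, hi = float(region.min()), float(region.max())
    if hi - lo < 1e-30:
        out = np.zeros_like(resp)
    else:
        out = np.clip((resp - lo) / (hi - lo), 0.0, 1.0)
    if fov is not None:
        out = out * fov
    return out


def combined_vessel_response(
    img: np.ndarray,
    f_sym: CosfireFilter,
    f_asym: CosfireFilter | None = None,
    n_orientations: int = 12,
    fov: np.ndarray | None = None,
) -> np.ndarray:
    """Sum of the rotation-tolerant symmetric and asymmetric responses.

    The symmetric filter sweeps [0, pi); the asymmetric (ending-selective)
    filter sweeps the full circle with 2*n_orientations rotations. Each map
    is min-max normalized to [0, 1] over the FOV before summing, so the
    combined range is [0, 2].
    """
    r_sym = _minmax_normalize(
        rotation_tolerant_response(img, f_sym, n_orientations), fov
    )
    if f_asym is None:
        return r_sym
    r_asym = _minmax_normalize(
        rotation_tolerant_response(img, f_asym, n_orientations, full_circle=True), fov
    )
    return r_sym + r_asym
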
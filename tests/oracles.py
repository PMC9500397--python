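"""Independent brute-force reference implementations used only by tests.

Each oracle re-derives a quantity directly from its defining formula —
per-pixel loops, explicit windows, BFS — sharing no code path with the
optimized implementations it checks.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def naive_dog_kernel(sigma: float, truncation: float = 3.0) -> np.ndarray:
    radius = int(math.ceil(truncation * sigma))
    n = 2 * radius + 1
    k = np.empty((n, n))
    s_in = 0.5 * sigma
    for i in range(n):
        for j in range(n):
            r2 = (i - radius) ** 2 + (j - radius) ** 2
            k[i, j] = math.exp(-r2 / (2 * s_in * s_in)) / (2 * math.pi * s_in * s_in) - math.exp(
                -r2 / (2 * sigma * sigma)
            ) / (2 * math.pi * sigma * sigma)
    return k - k.mean()


def naive_dog_response(img: np.ndarray, sigma: float, truncation: float = 3.0) -> np.ndarray:
    """Rectified DoG correlation with symmetric (edge-repeating) padding."""
    k = naive_dog_kernel(sigma, truncation)
    radius = k.shape[0] // 2
    padded = np.pad(img, radius, mode="symmetric")
    h, w = img.shape
    out = np.empty((h, w))
    for r in range(h):
        for c in range(w):
            out[r, c] = float(np.sum(padded[r : r + 2 * radius + 1, c : c + 2 * radius + 1] * k))
    return np.maximum(out, 0.0)


def naive_blur_shift(
    resp: np.ndarray, sigma: float, rho: float, phi: float, sigma0_prime: float, alpha: float
) -> np.ndarray:
    """Literal evaluation of the blur-and-shift: per pixel, a full 2-D window
    maximum of the shifted response weighted by a unit-peak Gaussian."""
    sigma_p = sigma0_prime + alpha * rho
    radius = int(math.ceil(3.0 * sigma_p))
    offs = np.arange(-radius, radius + 1)
    gy, gx = np.meshgrid(offs, offs, indexing="ij")
    g = np.exp(-(gx**2 + gy**2) / (2.0 * sigma_p * sigma_p))
    # integer-pixel shift: the response at (rho, phi) moves onto the center
    sr = -int(np.rint(rho * math.sin(phi)))
    sc = int(np.rint(rho * math.cos(phi)))
    h, w = resp.shape
    pad = radius + max(abs(sr), abs(sc)) + 1
    padded = np.pad(resp, pad, mode="constant")
    out = np.empty((h, w))
    for r in range(h):
        for c in range(w):
            rr, cc = r + sr + pad, c + sc + pad
            win = padded[rr - radius : rr + radius + 1, cc - radius : cc + radius + 1]
            out[r, c] = float(np.max(win * g))
    return out


def naive_filter_response(img: np.ndarray, f) -> np.ndarray:
    """Re-derivation of the full filter output from the defining equations:
    DoG responses, blurred and shifted per tuple, combined by the weighted
    geometric mean, thresholded at fraction t of the maximum."""
    ws = f.effective_weight_sigma
    weights = [math.exp(-tp.rho**2 / (2.0 * ws * ws)) for tp in f.tuples]
    wsum = sum(weights)
    acc = np.ones_like(img, dtype=np.float64)
    for tp, w in zip(f.tuples, weights):
        c = naive_dog_response(img, tp.sigma, f.truncation)
        s = naive_blur_shift(c, tp.sigma, tp.rho, tp.phi, f.sigma0_prime, f.alpha)
        acc = acc * np.power(s, w / wsum)
    if f.t > 0:
        acc[acc < f.t * acc.max()] = 0.0
    return acc


def naive_top_hat(img: np.ndarray, se_size: int) -> np.ndarray:
    """Sliding-window min then max with edge-repeating padding."""
    radius = se_size // 2

    def erode(arr):
        padded = np.pad(arr, radius, mode="symmetric")
        out = np.empty_like(arr)
        for r in range(arr.shape[0]):
            for c in range(arr.shape[1]):
                out[r, c] = padded[r : r + se_size, c : c + se_size].min()
        return out

    def dilate(arr):
        padded = np.pad(arr, radius, mode="symmetric")
        out = np.empty_like(arr)
        for r in range(arr.shape[0]):
            for c in range(arr.shape[1]):
                out[r, c] = padded[r : r + se_size, c : c + se_size].max()
        return out

    return img - dilate(erode(img))


def bfs_component_count(binmap: np.ndarray, connectivity: int = 8) -> int:
    """Flood-fill component count."""
    if connectivity == 8:
        moves = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        moves = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    h, w = binmap.shape
    seen = np.zeros_like(binmap, dtype=bool)
    count = 0
    for r in range(h):
        for c in range(w):
            if binmap[r, c] and not seen[r, c]:
                count += 1
                queue = deque([(r, c)])
                seen[r, c] = True
                while queue:
                    rr, cc = queue.popleft()
                    for dr, dc in moves:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and binmap[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            queue.append((nr, nc))
    return count


def loop_confusion(pred: np.ndarray, gold: np.ndarray, fov: np.ndarray) -> tuple[int, int, int, int]:
    tp = fp = tn = fn = 0
    for r in range(pred.shape[0]):
        for c in range(pred.shape[1]):
            if not fov[r, c]:
                continue
            if pred[r, c] and gold[r, c]:
                tp += 1
            elif pred[r, c]:
                fp += 1
            elif gold[r, c]:
                fn += 1
            else:
                tn += 1
    return tp, fp, tn, fn


def mcc_four_product(tp: int, fp: int, tn: int, fn: int) -> float:
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return (tp * tn - fp * fn) / denom
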
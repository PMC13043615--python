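"""Slow, independent reference implementations used by the test suite.

Everything here is deliberately written pixel-by-pixel (or with explicit
dense kernels) so it shares no code path with the package implementations
it is used to check.
"""

from __future__ import annotations

import numpy as np

# Classic Sobel derivative kernels, hard-coded (correlation convention,
# x = column axis increasing rightwards, y = row axis increasing downwards).
SOBEL_X_3 = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
SOBEL_Y_3 = SOBEL_X_3.T
_SMOOTH_7 = np.array([1, 6, 15, 20, 15, 6, 1], dtype=float)
_DERIV_7 = np.array([-1, -4, -5, 0, 5, 4, 1], dtype=float)
SOBEL_X_7 = np.outer(_SMOOTH_7, _DERIV_7)
SOBEL_Y_7 = np.outer(_DERIV_7, _SMOOTH_7)


def reflect_pad(img: np.ndarray, p: int) -> np.ndarray:
    return np.pad(img, p, mode="symmetric")  # (d c b a | a b c d)


def gaussian_weights(ksize: int) -> np.ndarray:
    """Dense 2-D Gaussian weight matrix with the ksize-derived sigma rule."""
    sigma = 0.3 * ((ksize - 1) * 0.5 - 1.0) + 0.8
    x = np.arange(ksize, dtype=float) - (ksize - 1) / 2.0
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    k /= k.sum()
    return np.outer(k, k)


def slow_filter(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Per-pixel correlation with reflected borders; no separability tricks."""
    k = kernel.shape[0]
    p = k // 2
    pad = reflect_pad(np.asarray(img, dtype=float), p)
    h, w = img.shape
    out = np.empty((h, w), dtype=float)
    for i in range(h):
        for j in range(w):
            out[i, j] = np.sum(pad[i : i + k, j : j + k] * kernel)
    return out


def slow_adaptive_threshold(
    img: np.ndarray, blur_kernel: int = 15, window: int = 35, offset_c: float = 1.0
) -> np.ndarray:
    """Reference inverse-binary adaptive threshold (values {0, 255})."""
    blurred = slow_filter(img, gaussian_weights(blur_kernel))
    mu = slow_filter(blurred, gaussian_weights(window))
    return np.where(blurred < mu + offset_c, 255.0, 0.0)


def slow_orientation_channel(
    img: np.ndarray, k: int, percentile: float = 75.0
) -> np.ndarray:
    """Reference magnitude-gated folded gradient-orientation channel."""
    sx = {3: SOBEL_X_3, 7: SOBEL_X_7}[k]
    sy = {3: SOBEL_Y_3, 7: SOBEL_Y_7}[k]
    gx = slow_filter(img, sx)
    gy = slow_filter(img, sy)
    h, w = img.shape
    mag = np.sqrt(gx**2 + gy**2)
    thr = np.percentile(mag, percentile)
    out = np.zeros((h, w), dtype=float)
    for i in range(h):
        for j in range(w):
            if mag[i, j] > thr:
                theta = np.arctan2(gy[i, j], gx[i, j])
                while theta >= np.pi / 2:
                    theta -= np.pi
                while theta < -np.pi / 2:
                    theta += np.pi
                out[i, j] = (theta + np.pi / 2) / np.pi * 255.0
    return out


def flood_fill_count(binary: np.ndarray) -> int:
    """Number of 8-connected foreground components, by explicit BFS."""
    fg = np.asarray(binary) > 0
    seen = np.zeros_like(fg)
    h, w = fg.shape
    count = 0
    for si in range(h):
        for sj in range(w):
            if fg[si, sj] and not seen[si, sj]:
                count += 1
                stack = [(si, sj)]
                seen[si, sj] = True
                while stack:
                    i, j = stack.pop()
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            ni, nj = i + di, j + dj
                            if 0 <= ni < h and 0 <= nj < w and fg[ni, nj] and not seen[ni, nj]:
                                seen[ni, nj] = True
                                stack.append((ni, nj))
    return count


def slow_combined_loss(pred_hwc: np.ndarray, truth: np.ndarray, lam: float, eps: float = 1e-6) -> float:
    """Sum-over-pixels reference for the combined CE + soft Dice loss."""
    h, w, c = pred_hwc.shape
    ce = 0.0
    for i in range(h):
        for j in range(w):
            ce -= np.log(max(pred_hwc[i, j, truth[i, j]], 1e-12))
    ce /= h * w
    dice_sum = 0.0
    for cls in range(c):
        inter = 0.0
        psum = 0.0
        ysum = 0.0
        for i in range(h):
            for j in range(w):
                y = 1.0 if truth[i, j] == cls else 0.0
                inter += pred_hwc[i, j, cls] * y
                psum += pred_hwc[i, j, cls]
                ysum += y
        dice_sum += (2.0 * inter + eps) / (psum + ysum + eps)
    return lam * ce + 1.0 - dice_sum / c
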
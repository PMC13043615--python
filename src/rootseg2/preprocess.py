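"""Robust input channels for two-stage root tissue segmentation.

Laser-ablation tomography (LAT) images of root cross-sections share one
reliable property across species and acquisition protocols: cell walls are
brighter than the cell lumens they enclose.  The preprocessing here turns an
RGB section image into three contrast- and colour-invariant channels that
exploit exactly that property:

``B_adp``
    inverse-binary adaptive threshold of the blurred grayscale image — a
    pixel is foreground (255) when it is darker than the Gaussian-weighted
    mean of its 35x35 neighbourhood plus a small offset, so lumens and flat
    background light up while walls stay 0.
``theta_f^k`` (k = 3 and k = 7)
    Sobel gradient orientation at two scales, folded into [-pi/2, pi/2) and
    mapped onto the 0-255 range, kept only where the gradient magnitude
    exceeds the 75th percentile over the whole image; everywhere else 0.

Stage 1 (tissue vs. background) consumes ``(B_adp, theta_f3, theta_f7)``;
stage 2 (tissue typing) swaps the first channel for the stage-1 prediction
``B_out``.  All channels live on the 0-255 scale so the stack is analogous
to an RGB image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "PreprocParams",
    "StageInput",
    "to_gray",
    "gaussian_kernel1d",
    "sobel_kernels",
    "adaptive_threshold_channel",
    "gradient_orientation_channel",
    "stage1_input",
    "stage2_input",
]

#: Border rule shared by the blur, the local weighted mean and the Sobel
#: filters (and by the slow reference implementations in the test suite):
#: symmetric reflection, i.e. (d c b a | a b c d).
BORDER_MODE = "reflect"

# ITU-R BT.601 luminance weights.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class PreprocParams:
    """Constants of the channel construction.

    Defaults are the published operating point: 15x15 Gaussian blur, 35x35
    Gaussian-weighted local mean with offset C = 1, Sobel scales {3, 7} and a
    75th-percentile magnitude gate.  ``sigma_rule`` maps an odd kernel size
    to the Gaussian sigma; the default is the convention of mainstream
    adaptive-threshold implementations, sigma = 0.3*((k-1)*0.5 - 1) + 0.8.
    """

    blur_kernel: int = 15
    window: int = 35
    offset_C: float = 1.0
    sobel_sizes: tuple[int, ...] = (3, 7)
    magnitude_percentile: float = 75.0

    def __post_init__(self) -> None:
        for name in ("blur_kernel", "window"):
            k = getattr(self, name)
            _check_odd(k, name)
        for k in self.sobel_sizes:
            _check_odd(k, "sobel_sizes entry")
        if not 0.0 < self.magnitude_percentile < 100.0:
            raise ValueError(
                f"magnitude_percentile must lie in (0, 100), got {self.magnitude_percentile}"
            )

    @staticmethod
    def sigma_rule(ksize: int) -> float:
        return 0.3 * ((ksize - 1) * 0.5 - 1.0) + 0.8

    def to_dict(self) -> dict:
        return {
            "blur_kernel": self.blur_kernel,
            "window": self.window,
            "offset_C": self.offset_C,
            "sobel_sizes": list(self.sobel_sizes),
            "magnitude_percentile": self.magnitude_percentile,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocParams":
        d = dict(d)
        if "sobel_sizes" in d:
            d["sobel_sizes"] = tuple(int(k) for k in d["sobel_sizes"])
        return cls(**d)


@dataclass
class StageInput:
    """Ordered 3-channel stack on the 0-255 scale.

    Stage 1 order is (B_adp, theta_f3, theta_f7); stage 2 replaces the first
    channel with the stage-1 binary output B_out.
    """

    channels: np.ndarray  # (3, H, W) float32
    stage: int
    channel_names: tuple[str, str, str] = field(default=("B_adp", "theta_f3", "theta_f7"))

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float32)
        if self.channels.ndim != 3 or self.channels.shape[0] != 3:
            raise ValueError(f"expected (3, H, W) channel stack, got {self.channels.shape}")
        if self.stage not in (1, 2):
            raise ValueError(f"stage must be 1 or 2, got {self.stage}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]


def _check_odd(k: int, name: str) -> None:
    if int(k) != k or k < 3 or k % 2 == 0:
        raise ValueError(f"{name} must be an odd integer >= 3, got {k!r}")


def _validate_gray(img: np.ndarray, min_size: int = 3) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"grayscale image must be 2-D, got shape {img.shape}")
    h, w = img.shape
    if h < min_size or w < min_size:
        raise ValueError(
            f"image {h}x{w} is smaller than the required {min_size}x{min_size} neighbourhood"
        )
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    return img


def to_gray(rgb: np.ndarray) -> np.ndarray:
    """Collapse an (H, W, 3) image to BT.601 luminance, float64, same H x W."""
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(
            f"expected an (H, W, 3) RGB image, got shape {rgb.shape}; "
            "grayscale inputs should be passed directly as 2-D arrays"
        )
    return rgb @ _LUMA


def gaussian_kernel1d(ksize: int, sigma: float | None = None) -> np.ndarray:
    """Sampled, normalised 1-D Gaussian of odd length ``ksize``."""
    _check_odd(ksize, "ksize")
    if sigma is None:
        sigma = PreprocParams.sigma_rule(ksize)
    x = np.arange(ksize, dtype=np.float64) - (ksize - 1) / 2.0
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def _gaussian_filter(img: np.ndarray, ksize: int) -> np.ndarray:
    k = gaussian_kernel1d(ksize)
    out = ndimage.correlate1d(img, k, axis=0, mode=BORDER_MODE)
    return ndimage.correlate1d(out, k, axis=1, mode=BORDER_MODE)


def adaptive_threshold_channel(img: np.ndarray, params: PreprocParams | None = None) -> np.ndarray:
    """Inverse-binary adaptive threshold channel ``B_adp`` (values {0, 255}).

    The grayscale image is blurred with a ``blur_kernel`` Gaussian, then each
    blurred pixel is compared against the Gaussian-weighted mean of its
    ``window`` x ``window`` neighbourhood: pixels strictly below the local
    mean plus ``offset_C`` become 255, the rest 0.  Borders use reflected
    padding.  A constant image is therefore all-255 (v < v + 1 everywhere).
    """
    params = params or PreprocParams()
    img = _validate_gray(img, min_size=params.window)
    blurred = _gaussian_filter(img, params.blur_kernel)
    mu_local = _gaussian_filter(blurred, params.window)
    out = np.where(blurred < mu_local + params.offset_C, 255.0, 0.0)
    return out.astype(np.float32)


def _pascal_row(n: int) -> np.ndarray:
    row = np.array([1.0])
    for _ in range(n):
        row = np.convolve(row, [1.0, 1.0])
    return row


def sobel_kernels(k: int) -> tuple[np.ndarray, np.ndarray]:
    """Separable Sobel derivative kernels ``(S_x, S_y)`` of size k x k.

    Built from binomial smoothing rows: the smoothing profile is the binomial
    row of order k-1 and the derivative profile is the binomial row of order
    k-3 convolved with [-1, 0, 1] (so k = 3 gives the classic [[−1,0,1],
    [−2,0,2],[−1,0,1]] and k = 7 gives deriv [-1,-4,-5,0,5,4,1] with smooth
    [1,6,15,20,15,6,1]).  Applied by correlation; x is the column axis.
    """
    _check_odd(k, "sobel kernel size")
    smooth = _pascal_row(k - 1)
    deriv = np.convolve(_pascal_row(k - 3), [1.0, 0.0, -1.0])[::-1]
    sx = np.outer(smooth, deriv)  # d/dx: derivative along columns
    sy = np.outer(deriv, smooth)  # d/dy: derivative along rows
    return sx, sy


def gradient_orientation_channel(
    img: np.ndarray, k: int, params: PreprocParams | None = None
) -> np.ndarray:
    """Magnitude-gated Sobel orientation channel ``theta_f^k`` in [0, 255).

    Gradients are computed on the *raw* grayscale image (not the blurred one
    used for thresholding).  The orientation arctan2(g_y, g_x) is folded
    modulo pi into [-pi/2, pi/2) — edge orientation is direction-less — and
    linearly mapped to (theta + pi/2)/pi * 255.  Pixels whose gradient
    magnitude does not strictly exceed the ``magnitude_percentile``-th
    percentile (computed over all pixels) are set to 0.
    """
    params = params or PreprocParams()
    if k not in params.sobel_sizes:
        raise ValueError(f"kernel size {k} not in configured sobel_sizes {params.sobel_sizes}")
    img = _validate_gray(img, min_size=k)
    sx, sy = sobel_kernels(k)
    gx = ndimage.correlate(img, sx, mode=BORDER_MODE)
    gy = ndimage.correlate(img, sy, mode=BORDER_MODE)
    theta = np.arctan2(gy, gx)
    mag = np.hypot(gx, gy)
    m_thr = np.percentile(mag, params.magnitude_percentile)
    folded = np.mod(theta + np.pi / 2.0, np.pi) - np.pi / 2.0
    values = (folded + np.pi / 2.0) / np.pi * 255.0
    out = np.where(mag > m_thr, values, 0.0)
    return out.astype(np.float32)


def stage1_input(img: np.ndarray, params: PreprocParams | None = None) -> StageInput:
    """Build the stage-1 stack (B_adp, theta_f3, theta_f7) from a gray image."""
    params = params or PreprocParams()
    ks = sorted(params.sobel_sizes)
    channels = np.stack(
        [adaptive_threshold_channel(img, params)]
        + [gradient_orientation_channel(img, k, params) for k in ks]
    )
    names = ("B_adp",) + tuple(f"theta_f{k}" for k in ks)
    return StageInput(channels=channels, stage=1, channel_names=names)


def stage2_input(
    binary_out: np.ndarray, img: np.ndarray, params: PreprocParams | None = None
) -> StageInput:
    """Build the stage-2 stack (B_out, theta_f3, theta_f7).

    ``binary_out`` is the hard {0, 255} stage-1 mask (argmax of the stage-1
    probabilities with foreground mapped to 255) at the same resolution as
    ``img``.
    """
    params = params or PreprocParams()
    binary_out = np.asarray(binary_out, dtype=np.float32)
    img = _validate_gray(img, min_size=max(params.sobel_sizes))
    if binary_out.shape != img.shape:
        raise ValueError(
            f"binary output shape {binary_out.shape} does not match image shape {img.shape}"
        )
    if not np.isin(binary_out, (0.0, 255.0)).all():
        raise ValueError("binary_out must contain only the values 0 and 255")
    ks = sorted(params.sobel_sizes)
    channels = np.stack(
        [binary_out] + [gradient_orientation_channel(img, k, params) for k in ks]
    )
    names = ("B_out",) + tuple(f"theta_f{k}" for k in ks)
    return StageInput(channels=channels, stage=2, channel_names=names)
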
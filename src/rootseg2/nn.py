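"""Minimal convolutional network engine on numpy.

Explicit forward/backward layers (3x3 and 1x1 convolutions, 2x2 max
pooling, nearest-neighbour upsampling, ReLU) plus an Adam optimizer.
Everything runs in float32 and is deterministic for a fixed seed and
thread configuration.

Internally tensors are channels-last (N, H, W, C): patch gathering for the
convolutions then reduces to nine contiguous strided copies followed by a
single GEMM, which is what keeps CPU training at interactive speed.  The
public model interface (see models.TinyUNet) speaks channels-first.

This engine exists to train the desk-scale U-Nets of this package; it makes
no attempt at being a general autodiff framework.
"""

from __future__ import annotations

import numpy as np

try:  # optional JIT for the patch gather/scatter hot loops
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is normally present
    _HAVE_NUMBA = False

__all__ = ["Conv2d", "GroupNorm", "ReLU", "MaxPool2", "Upsample2", "Adam"]


if _HAVE_NUMBA:

    @njit(cache=True)
    def _gather_nb(xp, k, h, w, cols):  # pragma: no cover - jitted
        n, _, _, c = xp.shape
        for b in range(n):
            for i in range(h):
                for j in range(w):
                    t = 0
                    for di in range(k):
                        for dj in range(k):
                            for ch in range(c):
                                cols[b, i, j, t, ch] = xp[b, i + di, j + dj, ch]
                            t += 1

    @njit(cache=True)
    def _scatter_nb(dcols, k, h, w, dxp):  # pragma: no cover - jitted
        n, _, _, c = dxp.shape
        for b in range(n):
            for i in range(h):
                for j in range(w):
                    t = 0
                    for di in range(k):
                        for dj in range(k):
                            for ch in range(c):
                                dxp[b, i + di, j + dj, ch] += dcols[b, i, j, t, ch]
                            t += 1


class Layer:
    """Base class: forward caches what backward needs; grads live on the layer."""

    params: dict
    grads: dict

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


def _gather_patches(xp: np.ndarray, k: int, h: int, w: int) -> np.ndarray:
    """Padded (N, h+k-1, w+k-1, C) -> (N*h*w, k*k*C) patch matrix."""
    n, _, _, c = xp.shape
    cols = np.empty((n, h, w, k * k, c), dtype=np.float32)
    if _HAVE_NUMBA:
        _gather_nb(xp, k, h, w, cols)
    else:
        for i in range(k):
            for j in range(k):
                cols[:, :, :, i * k + j, :] = xp[:, i : i + h, j : j + w, :]
    return cols.reshape(n * h * w, k * k * c)


def _scatter_patches(dcols: np.ndarray, k: int, n: int, h: int, w: int, c: int) -> np.ndarray:
    """Transpose of the gather: accumulate (N*h*w, k*k*C) back onto the pad."""
    p = k // 2
    dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=np.float32)
    dcols = dcols.reshape(n, h, w, k * k, c)
    if _HAVE_NUMBA:
        _scatter_nb(dcols, k, h, w, dxp)
    else:
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, i * k + j, :]
    return np.ascontiguousarray(dxp[:, p : p + h, p : p + w, :])


class Conv2d(Layer):
    """k x k convolution, stride 1, zero 'same' padding, He-initialised.

    The weight is stored as (k, k, C_in, C_out) so its matrix view
    (k*k*C_in, C_out) is reshape-free.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        std = np.sqrt(2.0 / (c_in * k * k))
        w = rng.normal(0.0, std, size=(k, k, c_in, c_out)).astype(np.float32)
        self.params = {"W": w, "b": np.zeros(c_out, dtype=np.float32)}
        self.grads = {"W": np.zeros_like(w), "b": np.zeros_like(self.params["b"])}
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        wmat = self.params["W"].reshape(-1, self.c_out)
        if self.k == 1:
            cols = x.reshape(-1, c)
        else:
            p = self.k // 2
            xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
            cols = _gather_patches(xp, self.k, h, w)
        y = cols @ wmat
        y += self.params["b"]
        self._cache = (cols, (n, h, w))
        return y.reshape(n, h, w, self.c_out)

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        cols, (n, h, w) = self._cache
        self._cache = None
        dy2 = dy.reshape(-1, self.c_out)
        self.grads["W"][...] = (cols.T @ dy2).reshape(self.params["W"].shape)
        self.grads["b"][...] = dy2.sum(axis=0)
        if not need_dx:  # first layer: nothing upstream wants the gradient
            return None
        wmat = self.params["W"].reshape(-1, self.c_out)
        dcols = dy2 @ wmat.T
        if self.k == 1:
            return dcols.reshape(n, h, w, self.c_in)
        return _scatter_patches(dcols, self.k, n, h, w, self.c_in)


class GroupNorm(Layer):
    """Group normalisation over (H, W, C_group) per sample, affine per channel.

    Batch-size independent, which matters at the small batches used here;
    stabilises training the way the batch-norm layers of standard U-Net
    backbones do.
    """

    def __init__(self, channels: int, groups: int = 4, eps: float = 1e-5):
        if channels % groups:
            groups = 1
        self.c, self.g, self.eps = channels, groups, eps
        self.params = {
            "gamma": np.ones(channels, dtype=np.float32),
            "beta": np.zeros(channels, dtype=np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        cg = c // self.g
        m = h * w * cg
        xg = x.reshape(n, h * w, self.g, cg)
        mu = xg.mean(axis=(1, 3), keepdims=True)
        xc = xg - mu
        var = (np.einsum("nsgc,nsgc->ng", xc, xc) / m).reshape(n, 1, self.g, 1)
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xc *= inv
        xhat = xc.reshape(n, h, w, c)
        self._cache = (xhat, inv, (n, h, w, c))
        return xhat * self.params["gamma"] + self.params["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, (n, h, w, c) = self._cache
        self._cache = None
        cg = c // self.g
        m = h * w * cg
        self.grads["gamma"][...] = np.einsum("nhwc,nhwc->c", dy, xhat)
        self.grads["beta"][...] = dy.sum(axis=(0, 1, 2))
        dxhat = (dy * self.params["gamma"]).reshape(n, h * w, self.g, cg)
        xh = xhat.reshape(n, h * w, self.g, cg)
        m1 = (np.einsum("nsgc->ng", dxhat) / m).reshape(n, 1, self.g, 1)
        m2 = (np.einsum("nsgc,nsgc->ng", dxhat, xh) / m).reshape(n, 1, self.g, 1)
        dxhat -= m1
        dxhat -= xh * m2
        dxhat *= inv
        return dxhat.reshape(n, h, w, c)


class ReLU(Layer):
    def __init__(self):
        self.params, self.grads = {}, {}
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        # in-place: the incoming buffer is this layer's private input
        np.maximum(x, np.float32(0.0), out=x)
        self._mask = x > 0
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        np.multiply(dy, self._mask, out=dy)
        self._mask = None
        return dy


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; input H, W must be even."""

    def __init__(self):
        self.params, self.grads = {}, {}
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"pooling needs even spatial size, got {h}x{w}")
        quads = np.stack(
            [x[:, 0::2, 0::2, :], x[:, 0::2, 1::2, :],
             x[:, 1::2, 0::2, :], x[:, 1::2, 1::2, :]], axis=3,
        )  # (N, h/2, w/2, 4, C)
        idx = quads.argmax(axis=3)
        out = np.take_along_axis(quads, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        self._cache = (idx, (n, h, w, c))
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, (n, h, w, c) = self._cache
        self._cache = None
        dquads = np.zeros((n, h // 2, w // 2, 4, c), dtype=np.float32)
        np.put_along_axis(dquads, idx[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
        dx = np.empty((n, h, w, c), dtype=np.float32)
        dx[:, 0::2, 0::2, :] = dquads[:, :, :, 0, :]
        dx[:, 0::2, 1::2, :] = dquads[:, :, :, 1, :]
        dx[:, 1::2, 0::2, :] = dquads[:, :, :, 2, :]
        dx[:, 1::2, 1::2, :] = dquads[:, :, :, 3, :]
        return dx


class Upsample2(Layer):
    """Nearest-neighbour x2 upsampling."""

    def __init__(self):
        self.params, self.grads = {}, {}

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = dy.shape
        return (
            dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4)).astype(np.float32)
        )


class Adam:
    """Adam with additive (coupled) weight decay, matching the common default."""

    def __init__(self, layers, lr: float, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for li, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                if self.wd and k == "W":
                    g = g + self.wd * p
                m = self.m[li][k]
                v = self.v[li][k]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
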
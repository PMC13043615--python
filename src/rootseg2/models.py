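"""U-Net segmentation models and the combined cross-entropy + Dice loss.

Both pipeline stages use the same encoder-decoder architecture with skip
connections, differing only in the number of output channels (2 for
tissue-vs-background, 9 for tissue typing).  The training objective is

    L = lambda * L_CE + L_Dice

with L_CE the per-pixel mean cross-entropy (natural log) and L_Dice the
soft Dice loss averaged over classes,

    L_Dice = 1 - (1/C) sum_c (2 * sum(y_c p_c) + eps) / (sum y_c + sum p_c + eps),

computed on probabilities, not hard labels.  The smoothing constant eps
appears in numerator and denominator so a class absent from both the
prediction and the truth contributes a perfect (zero-loss) term rather
than 0/0; with every class present eps is negligible and the expression
reduces to the plain soft Dice.

The default encoder is ``tiny`` — a small three-level U-Net intended for
desk-scale training on CPU.  A pretrained ResNet-34 encoder (the published
full-scale configuration) is not available in this build and is rejected
with an explanatory error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import Adam, Conv2d, GroupNorm, MaxPool2, ReLU, Upsample2
from .preprocess import PreprocParams

__all__ = [
    "ModelSpec",
    "TinyUNet",
    "build_unet",
    "softmax",
    "combined_loss",
    "loss_and_grad",
    "Checkpoint",
]

DICE_EPS = 1e-6


@dataclass(frozen=True)
class ModelSpec:
    """Architecture contract: 3 input channels, 2 or 9 output classes."""

    n_out: int
    encoder: str = "tiny"
    pretrained: bool = False
    in_channels: int = 3
    widths: tuple[int, int, int, int] = (8, 16, 32, 64)
    strict: bool = True

    def __post_init__(self) -> None:
        if self.strict and self.n_out not in (2, 9):
            raise ValueError(f"n_out must be 2 or 9, got {self.n_out}")
        if self.in_channels != 3:
            raise ValueError("the pipeline contract fixes in_channels at 3")
        if self.encoder == "resnet34":
            raise NotImplementedError(
                "the resnet34 encoder (pretrained full-scale configuration) is not "
                "available in this build; use encoder='tiny'"
            )
        if self.encoder != "tiny":
            raise ValueError(f"unknown encoder {self.encoder!r}")

    def to_dict(self) -> dict:
        return {
            "n_out": self.n_out,
            "encoder": self.encoder,
            "pretrained": self.pretrained,
            "in_channels": self.in_channels,
            "widths": list(self.widths),
            "strict": self.strict,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        d["widths"] = tuple(d.get("widths", (8, 16, 32, 64)))
        return cls(**d)


class TinyUNet:
    """Small U-Net: three 2x downsamplings, skip connections, 1x1 head.

    Each block is conv -> group norm -> ReLU.  The ~105 px receptive field
    is sized to cover the stele radius of a 256 px root section, so
    stele-interior pixels see the endodermis boundary as context.  Spatial
    input size must be divisible by 8.  ``forward`` returns raw class
    scores (N, n_out, H, W); apply :func:`softmax` for probabilities.
    """

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        w0, w1, w2, w3 = spec.widths

        def block(c_in, c_out):
            return Conv2d(c_in, c_out, 3, rng), GroupNorm(c_out), ReLU()

        self.e1a, self.n1a, self.r1a = block(spec.in_channels, w0)
        self.e1b, self.n1b, self.r1b = block(w0, w0)
        self.pool1 = MaxPool2()
        self.e2a, self.n2a, self.r2a = block(w0, w1)
        self.e2b, self.n2b, self.r2b = block(w1, w1)
        self.pool2 = MaxPool2()
        self.e3a, self.n3a, self.r3a = block(w1, w2)
        self.e3b, self.n3b, self.r3b = block(w2, w2)
        self.pool3 = MaxPool2()
        self.b1, self.nb1, self.rb1 = block(w2, w3)
        self.b2, self.nb2, self.rb2 = block(w3, w3)
        self.up3 = Upsample2()
        self.d3a, self.nd3a, self.rd3a = block(w3 + w2, w2)
        self.d3b, self.nd3b, self.rd3b = block(w2, w2)
        self.up2 = Upsample2()
        self.d2a, self.nd2a, self.rd2a = block(w2 + w1, w1)
        self.d2b, self.nd2b, self.rd2b = block(w1, w1)
        self.up1 = Upsample2()
        self.d1a, self.nd1a, self.rd1a = block(w1 + w0, w0)
        self.d1b, self.nd1b, self.rd1b = block(w0, w0)
        self.head = Conv2d(w0, spec.n_out, 1, rng)
        self._split = (w3, w2, w1, w0)

    @property
    def layers(self) -> list:
        return [
            self.e1a, self.n1a, self.r1a, self.e1b, self.n1b, self.r1b, self.pool1,
            self.e2a, self.n2a, self.r2a, self.e2b, self.n2b, self.r2b, self.pool2,
            self.e3a, self.n3a, self.r3a, self.e3b, self.n3b, self.r3b, self.pool3,
            self.b1, self.nb1, self.rb1, self.b2, self.nb2, self.rb2,
            self.up3, self.d3a, self.nd3a, self.rd3a, self.d3b, self.nd3b, self.rd3b,
            self.up2, self.d2a, self.nd2a, self.rd2a, self.d2b, self.nd2b, self.rd2b,
            self.up1, self.d1a, self.nd1a, self.rd1a, self.d1b, self.nd1b, self.rd1b,
            self.head,
        ]

    def _block(self, conv, norm, relu, x):
        return relu.forward(norm.forward(conv.forward(x)))

    def _block_back(self, conv, norm, relu, dy):
        return conv.backward(norm.backward(relu.backward(dy)))

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != self.spec.in_channels:
            raise ValueError(f"expected (N, {self.spec.in_channels}, H, W), got {x.shape}")
        if x.shape[2] % 8 or x.shape[3] % 8:
            raise ValueError(f"spatial size must be divisible by 8, got {x.shape[2:]}")
        x = np.ascontiguousarray(x.transpose(0, 2, 3, 1))  # engine is channels-last
        blk = self._block
        a1 = blk(self.e1b, self.n1b, self.r1b, blk(self.e1a, self.n1a, self.r1a, x))
        a2 = blk(self.e2b, self.n2b, self.r2b,
                 blk(self.e2a, self.n2a, self.r2a, self.pool1.forward(a1)))
        a3 = blk(self.e3b, self.n3b, self.r3b,
                 blk(self.e3a, self.n3a, self.r3a, self.pool2.forward(a2)))
        bb = blk(self.b2, self.nb2, self.rb2,
                 blk(self.b1, self.nb1, self.rb1, self.pool3.forward(a3)))
        c3 = np.concatenate([self.up3.forward(bb), a3], axis=3)
        d3 = blk(self.d3b, self.nd3b, self.rd3b, blk(self.d3a, self.nd3a, self.rd3a, c3))
        c2 = np.concatenate([self.up2.forward(d3), a2], axis=3)
        d2 = blk(self.d2b, self.nd2b, self.rd2b, blk(self.d2a, self.nd2a, self.rd2a, c2))
        c1 = np.concatenate([self.up1.forward(d2), a1], axis=3)
        d1 = blk(self.d1b, self.nd1b, self.rd1b, blk(self.d1a, self.nd1a, self.rd1a, c1))
        z = self.head.forward(d1)
        return np.ascontiguousarray(z.transpose(0, 3, 1, 2))

    def backward(self, dz: np.ndarray) -> None:
        w3, w2, w1, w0 = self._split
        back = self._block_back
        dz = np.ascontiguousarray(np.asarray(dz, dtype=np.float32).transpose(0, 2, 3, 1))
        dd1 = self.head.backward(dz)
        dc1 = back(self.d1a, self.nd1a, self.rd1a,
                   back(self.d1b, self.nd1b, self.rd1b, dd1))
        dup1, da1_skip = dc1[..., :w1], dc1[..., w1:]
        dd2 = self.up1.backward(dup1)
        dc2 = back(self.d2a, self.nd2a, self.rd2a,
                   back(self.d2b, self.nd2b, self.rd2b, dd2))
        dup2, da2_skip = dc2[..., :w2], dc2[..., w2:]
        dd3 = self.up2.backward(dup2)
        dc3 = back(self.d3a, self.nd3a, self.rd3a,
                   back(self.d3b, self.nd3b, self.rd3b, dd3))
        dup3, da3_skip = dc3[..., :w3], dc3[..., w3:]
        dbb = self.up3.backward(dup3)
        dp3 = back(self.b1, self.nb1, self.rb1, back(self.b2, self.nb2, self.rb2, dbb))
        da3 = self.pool3.backward(dp3) + da3_skip
        dp2 = back(self.e3a, self.n3a, self.r3a, back(self.e3b, self.n3b, self.r3b, da3))
        da2 = self.pool2.backward(dp2) + da2_skip
        dp1 = back(self.e2a, self.n2a, self.r2a, back(self.e2b, self.n2b, self.r2b, da2))
        da1 = self.pool1.backward(dp1) + da1_skip
        de1b = back(self.e1b, self.n1b, self.r1b, da1)
        self.e1a.backward(self.n1a.backward(self.r1a.backward(de1b)), need_dx=False)

    # -- parameter plumbing -------------------------------------------------
    def named_params(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                out[f"l{i:02d}.{k}"] = v
        return out

    def load_params(self, params: dict[str, np.ndarray]) -> None:
        own = self.named_params()
        if set(own) != set(params):
            raise ValueError("checkpoint parameter names do not match this architecture")
        for i, layer in enumerate(self.layers):
            for k in layer.params:
                src = np.asarray(params[f"l{i:02d}.{k}"], dtype=np.float32)
                if src.shape != layer.params[k].shape:
                    raise ValueError(f"shape mismatch for l{i:02d}.{k}")
                layer.params[k][...] = src

    def checksum(self) -> float:
        return float(sum(np.abs(v).sum() for v in self.named_params().values()))

    def make_optimizer(self, lr: float, weight_decay: float) -> Adam:
        return Adam(self.layers, lr=lr, weight_decay=weight_decay)


def build_unet(spec: ModelSpec, seed: int = 0) -> TinyUNet:
    """Instantiate a U-Net with reproducible (seeded) weight initialisation."""
    return TinyUNet(spec, seed=seed)


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _one_hot(mask: np.ndarray, n_classes: int) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() >= n_classes:
        raise ValueError(f"mask values must lie in [0, {n_classes}), got max {mask.max()}")
    return np.eye(n_classes, dtype=np.float32)[mask]


def combined_loss(
    pred: np.ndarray, truth: np.ndarray, lam: float = 0.1, eps: float = DICE_EPS
) -> float:
    """lambda * cross-entropy + soft Dice loss for one image.

    ``pred`` is an (H, W, C) probability map (rows sum to 1); ``truth`` an
    (H, W) integer class mask.  Returns a python float.
    """
    pred = np.asarray(pred, dtype=np.float64)
    if pred.ndim != 3:
        raise ValueError(f"pred must be (H, W, C), got shape {pred.shape}")
    if pred.shape[0] == 0 or pred.shape[1] == 0:
        raise ValueError("empty image")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    c = pred.shape[2]
    y = _one_hot(truth, c).astype(np.float64)
    if not np.allclose(pred.sum(axis=2), 1.0, atol=1e-4):
        raise ValueError("pred probabilities must sum to 1 over classes")
    hw = pred.shape[0] * pred.shape[1]
    ce = -np.sum(y * np.log(np.maximum(pred, 1e-12))) / hw
    inter = (pred * y).sum(axis=(0, 1))
    sums = pred.sum(axis=(0, 1)) + y.sum(axis=(0, 1))
    dice = (2.0 * inter + eps) / (sums + eps)
    l_dice = 1.0 - dice.mean()
    return float(lam * ce + l_dice)


def loss_and_grad(
    logits: np.ndarray, mask: np.ndarray, lam: float = 0.1, eps: float = DICE_EPS
) -> tuple[float, np.ndarray]:
    """Batched combined loss and its gradient w.r.t. the logits.

    ``logits`` is (N, C, H, W); ``mask`` is (N, H, W) integer classes.  The
    batch loss is the mean of per-image losses (cross-entropy is a mean
    over pixels; Dice sums run over each image separately).
    """
    logits = np.asarray(logits)
    if logits.dtype not in (np.float32, np.float64):
        logits = logits.astype(np.float32)
    dtype = logits.dtype  # float64 inputs keep full precision (gradient checks)
    n, c, h, w = logits.shape
    p = softmax(logits, axis=1)
    y = _one_hot(mask, c).transpose(0, 3, 1, 2).astype(dtype)
    hw = h * w

    ce = -np.sum(y * np.log(np.maximum(p, 1e-12))) / (n * hw)

    inter = (p * y).sum(axis=(2, 3))  # (N, C)
    sums = p.sum(axis=(2, 3)) + y.sum(axis=(2, 3))
    dice = (2.0 * inter + eps) / (sums + eps)
    l_dice = float(np.mean(1.0 - dice.mean(axis=1)))
    loss = float(lam * ce + l_dice)

    # d(CE)/dz has the standard softmax form; Dice needs the chain rule
    # through the softmax: dz = p * (g - sum_c p_c g_c) with g = dL/dp.
    denom = (sums + eps)[:, :, None, None]
    g_dice = -(2.0 * y * denom - (2.0 * inter + eps)[:, :, None, None]) / (c * denom**2) / n
    dz_dice = p * (g_dice - (p * g_dice).sum(axis=1, keepdims=True))
    dz = lam * (p - y) / (n * hw) + dz_dice
    return loss, dz.astype(dtype)


@dataclass
class Checkpoint:
    """Self-describing model archive: weights + specs needed for inference."""

    params: dict
    model_spec: ModelSpec
    preproc: PreprocParams
    stage: int | str  # 1, 2 or "rgb"
    train_meta: dict = field(default_factory=dict)

    def build_model(self) -> TinyUNet:
        net = build_unet(self.model_spec, seed=0)
        net.load_params(self.params)
        return net

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        meta = json.dumps(
            {
                "model_spec": self.model_spec.to_dict(),
                "preproc": self.preproc.to_dict(),
                "stage": self.stage,
                "train_meta": self.train_meta,
            }
        )
        np.savez_compressed(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                            **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"checkpoint not found: {path}")
        try:
            with np.load(path) as z:
                meta = json.loads(bytes(z["__meta__"]).decode())
                params = {k: z[k] for k in z.files if k != "__meta__"}
        except (KeyError, ValueError, json.JSONDecodeError) as e:
            raise ValueError(f"corrupt or incompatible checkpoint {path}: {e}") from e
        return cls(
            params=params,
            model_spec=ModelSpec.from_dict(meta["model_spec"]),
            preproc=PreprocParams.from_dict(meta["preproc"]),
            stage=meta["stage"],
            train_meta=meta.get("train_meta", {}),
        )
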
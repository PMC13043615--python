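"""Shared fixtures: synthetic datasets and desk-scale trained models.

Training fixtures are session-scoped so the expensive runs happen once.
The small 96-px harness supports transfer/fine-tuning/ordering properties;
the full 256-px desk fixture backs the end-to-end learning checks.
"""

import numpy as np
import pytest

from rootseg2.metrics import confusion, evaluate_masks, iou_dice
from rootseg2.synthetic import SyntheticSpec, generate_batch
from rootseg2.train import (
    TrainConfig,
    predict_rgb,
    predict_stage1,
    predict_stage2,
    train_rgb_baseline,
    train_stage,
)
from rootseg2.vocab import N_CLASSES

HARNESS_SIZE = 96


def harness_cfg(epochs: int, seed: int = 0) -> TrainConfig:
    return TrainConfig.desk(crop=64, eval_size=HARNESS_SIZE, epochs=epochs, seed=seed)


@pytest.fixture(scope="session")
def family_a():
    spec = SyntheticSpec.for_family("A", image_size=HARNESS_SIZE, seed=11)
    return {
        "spec": spec,
        "train": generate_batch(spec, 16, seed=100),
        "test": generate_batch(spec, 6, seed=200),
    }


@pytest.fixture(scope="session")
def family_b():
    spec = SyntheticSpec.for_family("B", image_size=HARNESS_SIZE, seed=12)
    return {
        "spec": spec,
        "train": generate_batch(spec, 16, seed=300),
        "test": generate_batch(spec, 6, seed=400),
    }


@pytest.fixture(scope="session")
def stage1_a(family_a):
    ckpt, _ = train_stage(1, family_a["train"], cfg=harness_cfg(30))
    return ckpt


@pytest.fixture(scope="session")
def stage2_a(family_a):
    ckpt, _ = train_stage(2, family_a["train"], cfg=harness_cfg(100))
    return ckpt


@pytest.fixture(scope="session")
def rgb_binary_a(family_a):
    ckpt, _ = train_rgb_baseline(family_a["train"], n_out=2, cfg=harness_cfg(30))
    return ckpt


@pytest.fixture(scope="session")
def transfer_models(family_a):
    """Per-seed (stage1, stage2, rgb9) triples trained under identical configs."""
    triples = []
    for seed in (0, 1, 2):
        s1, _ = train_stage(1, family_a["train"], cfg=harness_cfg(12, seed))
        s2, _ = train_stage(2, family_a["train"], cfg=harness_cfg(30, seed))
        rgb, _ = train_rgb_baseline(family_a["train"], n_out=N_CLASSES, cfg=harness_cfg(30, seed))
        triples.append({"s1": s1, "s2": s2, "rgb": rgb})
    return triples


@pytest.fixture(scope="session")
def desk_models():
    """Full desk-scale run: 60 family-A 256-px samples, 30 epochs per stage."""
    spec = SyntheticSpec.for_family("A", image_size=256, seed=11)
    samples = generate_batch(spec, 60, seed=100)
    train, test = samples[:48], samples[48:]
    cfg = TrainConfig.desk(epochs=30, seed=0)
    ck1, hist1 = train_stage(1, train, cfg=cfg)
    ck2, hist2 = train_stage(2, train, cfg=cfg)
    return {"ck1": ck1, "ck2": ck2, "test": test, "hist1": hist1, "hist2": hist2}


# -- metric helpers shared by learning tests --------------------------------

def binary_dice(ckpt1, samples) -> float:
    vals = []
    for s in samples:
        pred, _ = predict_stage1(s.image, ckpt1)
        m = iou_dice(confusion((pred > 0).astype(int), s.binary_mask.astype(int), 2))
        vals.append(m["dice"][1])
    return float(np.mean(vals))


def rgb_binary_dice(ckpt, samples) -> float:
    vals = []
    for s in samples:
        pred = predict_rgb(s.image, ckpt)
        m = iou_dice(confusion((pred > 0).astype(int), s.binary_mask.astype(int), 2))
        vals.append(m["dice"][1])
    return float(np.mean(vals))


def twostage_mean_dice(ckpt1, ckpt2, samples, binary_from_truth=False) -> float:
    preds = []
    for s in samples:
        override = s.binary_mask.astype(np.float32) * 255.0 if binary_from_truth else None
        preds.append(predict_stage2(s.image, ckpt1, ckpt2, binary_override=override))
    df = evaluate_masks(preds, [s.mask for s in samples], N_CLASSES)
    return float(df[df["sample"] == "__mean__"]["mean_dice"].iloc[0])


def rgb_mean_dice(ckpt, samples) -> float:
    preds = [predict_rgb(s.image, ckpt) for s in samples]
    df = evaluate_masks(preds, [s.mask for s in samples], N_CLASSES)
    return float(df[df["sample"] == "__mean__"]["mean_dice"].iloc[0])
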
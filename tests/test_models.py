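"""U-Net construction and the combined cross-entropy + Dice objective."""

import numpy as np
import pytest

from rootseg2.models import (
    ModelSpec,
    build_unet,
    combined_loss,
    loss_and_grad,
    softmax,
)

from oracles import slow_combined_loss


def test_forward_pass_shape_and_finiteness():
    net = build_unet(ModelSpec(n_out=9), seed=0)
    out = net.forward(np.zeros((1, 3, 64, 64), dtype=np.float32))
    assert out.shape == (1, 9, 64, 64)
    assert np.isfinite(out).all()


def test_softmax_yields_valid_probability_map():
    net = build_unet(ModelSpec(n_out=2), seed=1)
    rng = np.random.default_rng(0)
    p = softmax(net.forward(rng.normal(0, 1, (2, 3, 32, 32)).astype(np.float32)), axis=1)
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-5)
    assert p.min() >= 0.0 and p.max() <= 1.0


def test_same_seed_gives_identical_initial_weights():
    a = build_unet(ModelSpec(n_out=9), seed=7)
    b = build_unet(ModelSpec(n_out=9), seed=7)
    c = build_unet(ModelSpec(n_out=9), seed=8)
    assert a.checksum() == b.checksum()
    assert a.checksum() != c.checksum()


def test_model_spec_contract():
    with pytest.raises(ValueError, match="n_out"):
        ModelSpec(n_out=5)
    assert ModelSpec(n_out=5, strict=False).n_out == 5
    with pytest.raises(NotImplementedError, match="resnet34"):
        ModelSpec(n_out=9, encoder="resnet34")


def test_loss_zero_at_exact_one_hot_match():
    rng = np.random.default_rng(0)
    truth = rng.integers(0, 9, (12, 12))
    pred = np.eye(9)[truth].astype(float)
    assert combined_loss(pred, truth, lam=0.1) == pytest.approx(0.0, abs=1e-6)


def test_dice_loss_is_one_on_disjoint_one_hot():
    truth = np.array([[0, 0], [1, 1]])
    pred = np.eye(2)[1 - truth].astype(float)  # both classes present, disjoint
    assert combined_loss(pred, truth, lam=0.0) == pytest.approx(1.0, abs=1e-5)


def test_combined_loss_matches_brute_force_oracle():
    rng = np.random.default_rng(1)
    pred = rng.random((8, 8, 3))
    pred /= pred.sum(axis=2, keepdims=True)
    truth = rng.integers(0, 3, (8, 8))
    ours = combined_loss(pred, truth, lam=0.1)
    oracle = slow_combined_loss(pred, truth, lam=0.1)
    assert ours == pytest.approx(oracle, abs=1e-6)


def test_lambda_zero_reduces_to_pure_dice():
    rng = np.random.default_rng(2)
    pred = rng.random((6, 6, 4))
    pred /= pred.sum(axis=2, keepdims=True)
    truth = rng.integers(0, 4, (6, 6))
    full = combined_loss(pred, truth, lam=0.1)
    dice_only = combined_loss(pred, truth, lam=0.0)
    hw = 36
    ce = -np.mean([np.log(pred[i, j, truth[i, j]]) for i in range(6) for j in range(6)])
    assert full == pytest.approx(dice_only + 0.1 * ce, abs=1e-9)
    assert 0.0 <= dice_only <= 1.0


def test_loss_nonnegative_and_dice_bounded_on_random_maps():
    rng = np.random.default_rng(3)
    for _ in range(20):
        c = int(rng.integers(2, 9))
        pred = rng.random((7, 5, c))
        pred /= pred.sum(axis=2, keepdims=True)
        truth = rng.integers(0, c, (7, 5))
        dice_loss = combined_loss(pred, truth, lam=0.0)
        assert -1e-9 <= dice_loss <= 1.0 + 1e-9
        assert combined_loss(pred, truth, lam=0.1) >= dice_loss - 1e-12


def test_analytic_gradient_matches_finite_differences():
    rng = np.random.default_rng(0)
    logits = rng.normal(0, 1, (1, 2, 4, 4)).astype(np.float64)
    mask = rng.integers(0, 2, (1, 4, 4))
    _, dz = loss_and_grad(logits, mask, lam=0.1)
    eps = 1e-6
    num = np.zeros_like(logits)
    for idx in np.ndindex(logits.shape):
        lp, lm = logits.copy(), logits.copy()
        lp[idx] += eps
        lm[idx] -= eps
        num[idx] = (loss_and_grad(lp, mask, 0.1)[0] - loss_and_grad(lm, mask, 0.1)[0]) / (2 * eps)
    assert np.abs(num - dz).max() < 1e-4


def test_one_optimizer_step_decreases_loss_on_a_sample():
    rng = np.random.default_rng(4)
    net = build_unet(ModelSpec(n_out=9), seed=4)
    x = rng.normal(0, 1, (1, 3, 32, 32)).astype(np.float32)
    y = rng.integers(0, 9, (1, 32, 32))
    loss0, dz = loss_and_grad(net.forward(x), y, lam=0.1)
    net.backward(dz)
    net.make_optimizer(lr=1e-3, weight_decay=1e-3).step()
    loss1, _ = loss_and_grad(net.forward(x), y, lam=0.1)
    assert loss1 < loss0


def test_combined_loss_input_validation():
    with pytest.raises(ValueError, match="empty"):
        combined_loss(np.zeros((0, 4, 2)), np.zeros((0, 4), dtype=int))
    pred = np.full((4, 4, 2), 0.5)
    with pytest.raises(ValueError, match="lambda"):
        combined_loss(pred, np.zeros((4, 4), dtype=int), lam=-1.0)
    with pytest.raises(ValueError, match="sum to 1"):
        combined_loss(np.full((4, 4, 2), 0.7), np.zeros((4, 4), dtype=int))
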
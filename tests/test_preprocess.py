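"""Channel construction: oracle equivalence, analytic values, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from rootseg2.preprocess import (
    PreprocParams,
    adaptive_threshold_channel,
    gradient_orientation_channel,
    sobel_kernels,
    stage1_input,
    stage2_input,
    to_gray,
)

from oracles import slow_adaptive_threshold, slow_orientation_channel

SEEDS = list(range(10))


def random_image(seed, size=48, lo=0, hi=255):
    rng = np.random.default_rng(seed)
    return rng.uniform(lo, hi, (size, size))


# -- grayscale conversion ---------------------------------------------------

def test_to_gray_matches_weighted_sum_oracle():
    rng = np.random.default_rng(0)
    rgb = rng.uniform(0, 255, (8, 8, 3))
    expected = np.empty((8, 8))
    for i in range(8):
        for j in range(8):
            r, g, b = rgb[i, j]
            expected[i, j] = 0.299 * r + 0.587 * g + 0.114 * b
    assert np.abs(to_gray(rgb) - expected).max() < 1e-9


def test_to_gray_preserves_flat_and_black_images():
    flat = np.full((5, 5, 3), 137.0)
    assert np.allclose(to_gray(flat), 137.0)
    assert np.allclose(to_gray(np.zeros((4, 4, 3))), 0.0)


def test_to_gray_rejects_wrong_channel_count():
    with pytest.raises(ValueError, match="RGB"):
        to_gray(np.zeros((5, 5, 4)))


# -- adaptive threshold channel --------------------------------------------

def test_constant_image_thresholds_to_all_foreground():
    for v in (0.0, 42.0, 255.0):
        out = adaptive_threshold_channel(np.full((40, 40), v))
        assert (out == 255).all()


def test_adaptive_threshold_rejects_too_small_images():
    with pytest.raises(ValueError, match="35"):
        adaptive_threshold_channel(np.zeros((20, 20)))


def test_bright_disk_interior_dark_background_bright():
    yy, xx = np.mgrid[0:64, 0:64]
    img = np.where(np.hypot(yy - 32, xx - 32) < 18, 255.0, 0.0)
    out = adaptive_threshold_channel(img)
    oracle = slow_adaptive_threshold(img)
    assert np.array_equal(out, oracle)
    # disk interior is locally bright -> 0; far background is flat -> 255
    assert out[32, 32] == 0
    assert out[2, 2] == 255


@pytest.mark.parametrize("seed", SEEDS)
def test_adaptive_threshold_matches_per_pixel_oracle(seed):
    img = random_image(seed)
    out = adaptive_threshold_channel(img)
    oracle = slow_adaptive_threshold(img)
    assert np.array_equal(out, oracle)


# -- gradient orientation channels -----------------------------------------

def test_sobel_kernels_are_the_classic_matrices():
    sx3, sy3 = sobel_kernels(3)
    assert np.array_equal(sx3, [[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]])
    assert np.array_equal(sy3, np.asarray(sx3).T)
    sx7, _ = sobel_kernels(7)
    assert np.array_equal(sx7[0], np.array([-1, -4, -5, 0, 5, 4, 1]))


def test_constant_image_gives_all_zero_orientation():
    for k in (3, 7):
        out = gradient_orientation_channel(np.full((40, 40), 99.0), k)
        assert (out == 0).all()


def test_vertical_step_edge_orientation_is_midscale():
    img = np.zeros((40, 40))
    img[:, 20:] = 200.0  # intensity increases left -> right
    out = gradient_orientation_channel(img, 3)
    surviving = out[out > 0]
    assert len(surviving) > 0
    assert np.allclose(surviving, 127.5)


@pytest.mark.parametrize("seed", SEEDS)
@pytest.mark.parametrize("k", [3, 7])
def test_orientation_channel_matches_per_pixel_oracle(seed, k):
    img = random_image(seed, size=32)
    out = gradient_orientation_channel(img, k)
    oracle = slow_orientation_channel(img, k)
    assert np.allclose(out, oracle, atol=1e-4)
    assert np.array_equal(np.round(out).astype(np.uint8), np.round(oracle).astype(np.uint8))


@pytest.mark.parametrize("a", [0.5, 2.0, 10.0])
@pytest.mark.parametrize("b", [-20.0, 30.0])
def test_orientation_invariant_to_affine_intensity(a, b):
    for seed in range(5):
        img = random_image(seed, size=40)
        for k in (3, 7):
            ref = gradient_orientation_channel(img, k)
            out = gradient_orientation_channel(a * img + b, k)
            assert np.allclose(out, ref, atol=1e-6)


def test_orientation_rotates_with_the_image():
    # Rotating the image 90 deg shifts every surviving orientation by pi/2
    # (mod pi), i.e. by 127.5 on the 0-255 scale; the survivor set rotates.
    img = random_image(3, size=40)
    for k in (3, 7):
        base = gradient_orientation_channel(img, k)
        rot = gradient_orientation_channel(np.rot90(img), k)
        base_r = np.rot90(base)
        surv = base_r > 0
        assert np.array_equal(surv, rot > 0)
        expected = (base_r[surv] + 127.5) % 255.0
        assert np.allclose(np.minimum(np.abs(rot[surv] - expected),
                                      255.0 - np.abs(rot[surv] - expected)), 0, atol=1e-3)


def test_orientation_rejects_bad_kernel_sizes():
    img = random_image(0)
    with pytest.raises(ValueError):
        gradient_orientation_channel(img, 4)
    with pytest.raises(ValueError):
        gradient_orientation_channel(img, 5)  # not in configured sobel_sizes
    with pytest.raises(ValueError):
        PreprocParams(sobel_sizes=(2, 7))


@settings(max_examples=20, deadline=None, derandomize=True)
@given(img=hnp.arrays(np.float64, (36, 36), elements=st.floats(0, 255, width=32)))
def test_channel_ranges_hold_for_arbitrary_images(img):
    binary = adaptive_threshold_channel(img)
    assert set(np.unique(binary)) <= {0.0, 255.0}
    orient = gradient_orientation_channel(img, 3)
    assert orient.min() >= 0.0 and orient.max() < 255.0


def test_channel_output_ranges():
    for seed in range(5):
        img = random_image(seed)
        binary = adaptive_threshold_channel(img)
        assert set(np.unique(binary)) <= {0.0, 255.0}
        for k in (3, 7):
            orient = gradient_orientation_channel(img, k)
            assert orient.min() >= 0.0 and orient.max() < 255.0 + 1e-6


# -- stage input assembly ---------------------------------------------------

def test_stage1_input_composes_component_channels():
    img = random_image(1, size=48)
    si = stage1_input(img)
    assert si.stage == 1 and si.channels.shape == (3, 48, 48)
    assert np.array_equal(si.channels[0], adaptive_threshold_channel(img))
    assert np.array_equal(si.channels[1], gradient_orientation_channel(img, 3))
    assert np.array_equal(si.channels[2], gradient_orientation_channel(img, 7))


def test_stage1_input_of_constant_image():
    si = stage1_input(np.full((40, 40), 50.0))
    assert (si.channels[0] == 255).all()
    assert (si.channels[1] == 0).all() and (si.channels[2] == 0).all()


def test_stage2_input_takes_binary_first_channel():
    img = random_image(2, size=48)
    b = (adaptive_threshold_channel(img)).astype(np.float32)
    si = stage2_input(b, img)
    assert si.stage == 2
    assert np.array_equal(si.channels[0], b)
    si0 = stage2_input(np.zeros((48, 48)), img)  # degenerate but legal
    assert (si0.channels[0] == 0).all()


def test_stage2_input_rejects_bad_binaries():
    img = random_image(2, size=48)
    with pytest.raises(ValueError, match="shape"):
        stage2_input(np.zeros((40, 40)), img)
    with pytest.raises(ValueError, match="0 and 255"):
        stage2_input(np.full((48, 48), 3.0), img)
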
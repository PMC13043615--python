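"""Synthetic root generator: determinism, anatomy, registration, datasets."""

import numpy as np
import pytest

from rootseg2.io import read_mask, write_mask
from rootseg2.preprocess import sobel_kernels, to_gray
from rootseg2.synthetic import SyntheticSpec, generate, generate_batch, generate_dataset, load_dataset
from rootseg2.traits import measure_traits
from rootseg2.vocab import CLASS_INDEX, N_CLASSES

from scipy import ndimage


def test_same_spec_and_seed_is_bit_identical():
    spec = SyntheticSpec.for_family("A", seed=5)
    a, b = generate(spec), generate(spec)
    assert np.array_equal(a.image, b.image)
    assert np.array_equal(a.mask, b.mask)


def test_no_lacunae_and_noise_free_walls_brighter_than_lumens():
    spec = SyntheticSpec.for_family(
        "A", seed=2, aerenchyma_lacunae=(0, 0), noise_sd=0.0,
        illumination_gradient=0.0, hue_jitter=0.0,
    )
    s = generate(spec)
    assert (s.mask == CLASS_INDEX["aerenchyma"]).sum() == 0
    gray = to_gray(s.image)
    # cortex contains bright walls; metaxylem lumens are wall-free cavities
    assert gray[s.mask == CLASS_INDEX["cortex"]].mean() > gray[s.mask == CLASS_INDEX["metaxylem"]].mean()
    assert gray[s.mask != 0].mean() > gray[s.mask == 0].mean()


def test_family_a_batch_is_plausible():
    batch = generate_batch(SyntheticSpec.for_family("A", seed=0), 20)
    classes_seen = set()
    for s in batch:
        frac = s.binary_mask.mean()
        assert 0.05 < frac < 0.9
        classes_seen |= set(np.unique(s.mask).tolist())
    assert classes_seen == set(range(N_CLASSES))


def test_mask_boundaries_coincide_with_intensity_edges():
    s = generate(SyntheticSpec.for_family("A", seed=9))
    gray = to_gray(s.image)
    sx, sy = sobel_kernels(3)
    mag = np.hypot(ndimage.correlate(gray, sx), ndimage.correlate(gray, sy))
    boundary = ndimage.binary_dilation(s.mask) != ndimage.binary_erosion(s.mask)
    assert mag[boundary].mean() > mag.mean()


def test_truth_traits_match_mask_measurement_within_two_px():
    for seed in range(4):
        s = generate(SyntheticSpec.for_family("A", seed=seed))
        m = measure_traits(s.mask)
        t = s.truth_traits
        assert abs(m.root_diameter_px - t.root_diameter_px) <= 2.0
        assert abs(m.stele_diameter_px - t.stele_diameter_px) <= 2.0
        assert abs(m.cortex_width_px - t.cortex_width_px) <= 2.0


def test_impossible_geometry_is_rejected():
    with pytest.raises(ValueError, match="wall_intensity"):
        SyntheticSpec(wall_intensity=50.0, lumen_intensity=60.0)
    with pytest.raises(ValueError, match="impossible|fit"):
        generate(SyntheticSpec.for_family("A", stele_fraction=(0.78, 0.79),
                                          cortex_cell_size=40.0))


def test_background_only_sample_when_radius_zero():
    s = generate(SyntheticSpec.for_family("A", seed=1, root_radius=(0.0, 0.0)))
    assert (s.mask == 0).all()
    assert s.truth_traits is None


def test_mask_palette_roundtrips_through_indexed_png(tmp_path):
    s = generate(SyntheticSpec.for_family("B", seed=3))
    p = tmp_path / "mask.png"
    write_mask(p, s.mask)
    assert np.array_equal(read_mask(p), s.mask)


def test_families_differ_by_configured_radius_offset():
    spec_a = SyntheticSpec.for_family("A")
    spec_b = SyntheticSpec.for_family("B")
    expected_offset = np.mean(spec_a.root_radius) - np.mean(spec_b.root_radius)
    assert expected_offset > 0
    radii_a = [generate_batch(spec_a, 12, seed=1)[i].geometry["root_radius_px"] for i in range(12)]
    radii_b = [generate_batch(spec_b, 12, seed=1)[i].geometry["root_radius_px"] for i in range(12)]
    observed = np.mean(radii_a) - np.mean(radii_b)
    # sample means over 12 draws from uniform ranges: allow generous slack
    assert abs(observed - expected_offset) < 8.0
    assert np.mean(spec_b.stele_fraction) > np.mean(spec_a.stele_fraction)


def test_generate_dataset_layout_split_and_reproducibility(tmp_path):
    spec = SyntheticSpec.for_family("A", image_size=96, seed=4)
    m1 = generate_dataset(spec, 10, tmp_path / "d1", split=(0.8, 0.2))
    splits = [s["split"] for s in m1["samples"]]
    assert splits.count("train") == 8 and splits.count("test") == 2
    ids = [s["id"] for s in m1["samples"]]
    assert len(set(ids)) == 10
    m2 = generate_dataset(spec, 10, tmp_path / "d2", split=(0.8, 0.2))
    assert m1["samples"] == m2["samples"]
    train = load_dataset(tmp_path / "d1", split="train")
    test = load_dataset(tmp_path / "d1", split="test")
    assert len(train) == 8 and len(test) == 2
    assert {t["id"] for t in train}.isdisjoint({t["id"] for t in test})
    assert (tmp_path / "d1" / "traits.csv").exists()


def test_generate_dataset_rejects_bad_fractions(tmp_path):
    spec = SyntheticSpec.for_family("A", image_size=96)
    with pytest.raises(ValueError, match="sum to 1"):
        generate_dataset(spec, 4, tmp_path / "bad", split=(0.5, 0.4))
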
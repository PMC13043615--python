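"""Annotation assist: region templates, label merging, uncertainty ranking."""

import numpy as np
import pandas as pd
import pytest

from rootseg2.annotate import (
    AnnotationTemplate,
    export_template,
    merge_labels,
    predictive_entropy,
)
from rootseg2.preprocess import PreprocParams, adaptive_threshold_channel, to_gray
from rootseg2.synthetic import SyntheticSpec, generate
from rootseg2.vocab import CLASS_INDEX

from oracles import flood_fill_count


def test_two_disjoint_squares_become_two_regions():
    binary = np.zeros((64, 64), dtype=np.uint8)
    binary[5:15, 5:15] = 255
    binary[40:60, 40:60] = 255
    tpl = export_template(binary, min_region_area=10)
    assert tpl.n_regions == 2
    assert sorted(tpl.region_table["area_px"]) == [100, 400]


def test_single_disk_region_area_matches_pixel_count():
    yy, xx = np.mgrid[0:64, 0:64]
    disk = (np.hypot(yy - 32, xx - 32) < 20).astype(np.uint8) * 255
    tpl = export_template(disk)
    assert tpl.n_regions == 1
    assert tpl.region_table["area_px"].iloc[0] == int((disk > 0).sum())


def test_region_count_matches_flood_fill_oracle():
    rng = np.random.default_rng(0)
    blobs = (rng.random((48, 48)) < 0.35).astype(np.uint8) * 255
    tpl = export_template(blobs, min_region_area=1)
    assert tpl.n_regions == flood_fill_count(blobs)


def test_small_regions_merge_into_nearest_neighbour():
    binary = np.zeros((40, 40), dtype=np.uint8)
    binary[5:25, 5:25] = 255  # big region
    binary[5:25, 26] = 255  # touching sliver column merges into it
    binary[30:32, 30:32] = 255  # isolated speckle, area 4
    tpl = export_template(binary, min_region_area=30)
    assert tpl.n_regions == 1


def test_all_zero_mask_yields_empty_template_not_failure():
    tpl = export_template(np.zeros((32, 32), dtype=np.uint8))
    assert tpl.n_regions == 0
    assert len(tpl.region_table) == 0
    assert (merge_labels(tpl, {}) == 0).all()


def test_template_roundtrips_through_png_and_csv(tmp_path):
    binary = np.zeros((48, 48), dtype=np.uint8)
    binary[4:20, 4:20] = 255
    binary[30:44, 30:44] = 255
    tpl = export_template(binary, min_region_area=5)
    tpl.save(tmp_path / "sample")
    loaded = AnnotationTemplate.load(tmp_path / "sample")
    assert np.array_equal(loaded.region_map, tpl.region_map)
    assert list(loaded.region_table["id"]) == list(tpl.region_table["id"])


def test_assigning_all_regions_one_class_recolors_binary():
    binary = np.zeros((32, 32), dtype=np.uint8)
    binary[4:12, 4:12] = 255
    binary[20:30, 20:30] = 255
    tpl = export_template(binary, min_region_area=5)
    mask = merge_labels(tpl, {rid: "cortex" for rid in tpl.region_table["id"]})
    assert np.array_equal(mask > 0, binary > 0)
    assert set(np.unique(mask)) == {0, CLASS_INDEX["cortex"]}


def test_unknown_class_or_region_is_rejected_with_details():
    binary = np.zeros((32, 32), dtype=np.uint8)
    binary[4:20, 4:20] = 255
    tpl = export_template(binary)
    with pytest.raises(ValueError, match="phloem"):
        merge_labels(tpl, {1: "phloem"})
    with pytest.raises(ValueError, match=r"\[99\]"):
        merge_labels(tpl, {99: "cortex"})


def test_merge_accepts_edited_csv_table():
    binary = np.zeros((32, 32), dtype=np.uint8)
    binary[4:20, 4:20] = 255
    tpl = export_template(binary)
    table = pd.DataFrame({"id": [1], "class": ["epidermis"]})
    mask = merge_labels(tpl, table)
    assert set(np.unique(mask)) == {0, CLASS_INDEX["epidermis"]}


def test_structure_seeded_template_tiles_foreground_exactly():
    s = generate(SyntheticSpec.for_family("A", image_size=256, seed=6))
    # cell seeding wants minimal smoothing and a window of about one cell,
    # unlike the heavily blurred network channel
    pp = PreprocParams(blur_kernel=3, window=9)
    structure = adaptive_threshold_channel(to_gray(s.image), pp)
    tpl = export_template(s.binary_mask * 255, structure=structure, min_region_area=4)
    # regions tile the foreground exactly: support preserved, ids partition it
    assert np.array_equal(tpl.region_map > 0, s.binary_mask > 0)
    assert tpl.n_regions > 5
    # labelling effort: one decision per region vs one per foreground pixel
    assert tpl.n_regions <= int(s.binary_mask.sum())


def test_rank_candidates_orders_by_entropy_oracle(stage1_a, stage2_a, family_a, family_b):
    from rootseg2.annotate import rank_candidates
    from rootseg2.train import predict_stage2

    images = [family_a["test"][0].image, family_b["test"][0].image,
              family_a["test"][1].image]
    ranked = rank_candidates(images, stage1_a, stage2_a,
                             sample_ids=["a0", "b0", "a1"])
    # independent oracle: recompute entropies pixel-by-pixel and sort
    oracle = {}
    for sid, img in zip(["a0", "b0", "a1"], images):
        _, probs = predict_stage2(img, stage1_a, stage2_a, return_probs=True)
        ent = 0.0
        c, h, w = probs.shape
        for i in range(h):
            for j in range(w):
                p = probs[:, i, j]
                ent += -np.sum(p * np.log(np.maximum(p, 1e-12)))
        oracle[sid] = ent / (h * w)
    expected = sorted(oracle, key=oracle.get, reverse=True)
    assert list(ranked["sample"]) == expected
    assert np.allclose(sorted(ranked["mean_entropy"], reverse=True),
                       [oracle[s] for s in expected], atol=1e-5)


def test_predictive_entropy_analytic_extremes():
    uniform = np.full((9, 8, 8), 1.0 / 9.0)
    assert predictive_entropy(uniform) == pytest.approx(np.log(9), abs=1e-9)
    onehot = np.zeros((9, 8, 8))
    onehot[2] = 1.0
    assert predictive_entropy(onehot) == pytest.approx(0.0, abs=1e-9)
    mixed = np.zeros((9, 4, 4))
    mixed[0] = 0.5
    mixed[1] = 0.5
    assert predictive_entropy(mixed) == pytest.approx(np.log(2), abs=1e-9)
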
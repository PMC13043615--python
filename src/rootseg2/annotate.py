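"""AI-assisted annotation: region templates, label merging, sample ranking.

The stage-1 model already knows where tissue is; what an expert must supply
is *which* tissue each region is.  This module turns a binary mask into an
editable region template (a region-id map plus a CSV table with one row per
region and an empty class column), merges the filled-in table back into a
9-class training mask, and ranks unlabelled images by predictive entropy so
annotation effort goes to the most uncertain samples first.

Region decomposition is connected components (8-connectivity) of the binary
foreground, with regions smaller than ``min_region_area`` merged into their
closest neighbour.  When a cell-structure channel is supplied (typically the
adaptive-threshold channel, whose foreground marks cell lumens), the
components of that structure *within* the mask seed a nearest-seed tiling of
the whole foreground, so the template regions follow the visible cell
boundaries — labelling then costs one decision per cell instead of one per
pixel, and the foreground support is preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .vocab import CLASS_INDEX, CLASS_NAMES

__all__ = [
    "AnnotationTemplate",
    "export_template",
    "merge_labels",
    "predictive_entropy",
    "rank_candidates",
]

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class AnnotationTemplate:
    """Connected-region decomposition of a binary mask, ready for labelling."""

    region_map: np.ndarray  # (H, W) int, 0 = background, regions 1..K
    region_table: pd.DataFrame  # id, area_px, centroid_row, centroid_col, class
    source: str = ""

    @property
    def n_regions(self) -> int:
        return int(self.region_map.max())

    def save(self, prefix: str | Path) -> None:
        from .io import write_region_map

        prefix = Path(prefix)
        write_region_map(prefix.with_name(prefix.name + "_regions.png"), self.region_map)
        self.region_table.to_csv(prefix.with_name(prefix.name + "_regions.csv"), index=False)

    @classmethod
    def load(cls, prefix: str | Path) -> "AnnotationTemplate":
        from .io import read_region_map

        prefix = Path(prefix)
        region_map = read_region_map(prefix.with_name(prefix.name + "_regions.png"))
        table = pd.read_csv(prefix.with_name(prefix.name + "_regions.csv"))
        return cls(region_map=region_map, region_table=table, source=str(prefix))


def _merge_small_regions(labels: np.ndarray, min_area: int) -> np.ndarray:
    """Reassign regions below ``min_area`` to their closest neighbouring region."""
    n = labels.max()
    if n == 0:
        return labels
    areas = np.bincount(labels.ravel(), minlength=n + 1)
    small = [r for r in range(1, n + 1) if 0 < areas[r] < min_area]
    for r in sorted(small, key=lambda r: areas[r]):
        if (labels == r).sum() == 0:
            continue
        mask_r = labels == r
        ring = ndimage.binary_dilation(mask_r, structure=_EIGHT) & ~mask_r
        neigh = labels[ring]
        neigh = neigh[neigh > 0]
        if len(neigh):
            labels[mask_r] = np.bincount(neigh).argmax()
            continue
        # isolated speckle: nearest region by centroid distance, if any exists
        others = [o for o in range(1, n + 1) if o != r and (labels == o).any()]
        if not others:
            continue
        cr = np.array(ndimage.center_of_mass(mask_r))
        cents = ndimage.center_of_mass(labels > 0, labels, others)
        d = [np.hypot(*(cr - np.array(c))) for c in cents]
        labels[mask_r] = others[int(np.argmin(d))]
    return labels


def _relabel(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros(labels.max() + 1, dtype=np.int32)
    lut[ids] = np.arange(1, len(ids) + 1)
    return lut[labels]


def export_template(
    binary: np.ndarray,
    min_region_area: int = 30,
    structure: np.ndarray | None = None,
    source: str = "",
) -> AnnotationTemplate:
    """Decompose a {0, 255} (or boolean) binary mask into labelling regions.

    Without ``structure``: 8-connected components of the foreground, with
    sub-``min_region_area`` regions merged into their closest neighbour.
    With ``structure`` (a second binary channel marking cell lumens, e.g.
    the adaptive-threshold output): components of structure-and-foreground
    seed a nearest-seed tiling of the whole foreground.  An all-empty mask
    yields an empty (zero-region) template rather than an error.
    """
    fg = np.asarray(binary) > 0
    if fg.ndim != 2:
        raise ValueError(f"binary mask must be 2-D, got {np.asarray(binary).shape}")
    if not fg.any():
        table = pd.DataFrame(columns=["id", "area_px", "centroid_row", "centroid_col", "class"])
        return AnnotationTemplate(
            region_map=np.zeros(fg.shape, dtype=np.int32), region_table=table, source=source
        )

    if structure is None:
        labels, _ = ndimage.label(fg, structure=_EIGHT)
    else:
        seeds = (np.asarray(structure) > 0) & fg
        seed_labels, n_seed = ndimage.label(seeds, structure=_EIGHT)
        if n_seed == 0:
            labels, _ = ndimage.label(fg, structure=_EIGHT)
        else:
            seed_labels = _merge_small_regions(seed_labels, min_region_area)
            seed_labels = _relabel(seed_labels)
            # every foreground pixel takes the label of the nearest seed pixel
            _, (ir, ic) = ndimage.distance_transform_edt(seed_labels == 0, return_indices=True)
            labels = np.where(fg, seed_labels[ir, ic], 0).astype(np.int32)
    labels = _merge_small_regions(labels, min_region_area)
    labels = _relabel(labels)

    ids = np.arange(1, labels.max() + 1)
    areas = np.bincount(labels.ravel(), minlength=labels.max() + 1)[1:]
    cents = ndimage.center_of_mass(labels > 0, labels, ids) if len(ids) else []
    table = pd.DataFrame(
        {
            "id": ids,
            "area_px": areas.astype(int),
            "centroid_row": [round(c[0], 2) for c in cents],
            "centroid_col": [round(c[1], 2) for c in cents],
            "class": ["" for _ in ids],
        }
    )
    return AnnotationTemplate(region_map=labels, region_table=table, source=source)


def merge_labels(template: AnnotationTemplate, assignments) -> np.ndarray:
    """Fill expert class assignments into the template; returns a 9-class mask.

    ``assignments`` maps region id to class name (dict, or a DataFrame with
    ``id`` and ``class`` columns, e.g. the edited region CSV).  Unassigned
    regions become background.  Unknown class names or region ids are
    rejected with the offending entries listed.
    """
    if isinstance(assignments, pd.DataFrame):
        pairs = [
            (int(r["id"]), str(r["class"]))
            for _, r in assignments.iterrows()
            if isinstance(r.get("class"), str) and r["class"].strip()
        ]
    else:
        pairs = [(int(k), str(v)) for k, v in assignments.items()]

    n = template.n_regions
    bad_ids = [rid for rid, _ in pairs if not 1 <= rid <= n]
    bad_classes = sorted({c for _, c in pairs if c not in CLASS_INDEX})
    if bad_ids or bad_classes:
        raise ValueError(
            f"invalid assignments: unknown region ids {bad_ids or 'none'}, "
            f"unknown classes {bad_classes or 'none'} (valid: {list(CLASS_NAMES)})"
        )
    lut = np.zeros(n + 1, dtype=np.uint8)
    for rid, cname in pairs:
        lut[rid] = CLASS_INDEX[cname]
    return lut[template.region_map]


def predictive_entropy(probs: np.ndarray) -> float:
    """Mean per-pixel entropy (nats) of a (C, H, W) class-probability map.

    Ranges from 0 (one-hot everywhere) to ln(C) (uniform everywhere).
    """
    probs = np.asarray(probs, dtype=np.float64)
    ent = -np.sum(probs * np.log(np.maximum(probs, 1e-12)), axis=0)
    return float(ent.mean())


def rank_candidates(images, ckpt1, ckpt2, sample_ids=None) -> pd.DataFrame:
    """Order images for annotation by mean per-pixel predictive entropy.

    Uses the stage-2 class probabilities; higher entropy (more model
    uncertainty) ranks earlier.  Deterministic for fixed checkpoints.
    """
    from .train import predict_stage2

    images = list(images)
    if sample_ids is None:
        sample_ids = [f"sample_{i:04d}" for i in range(len(images))]
    rows = []
    for sid, img in zip(sample_ids, images):
        _, probs = predict_stage2(img, ckpt1, ckpt2, return_probs=True)
        rows.append({"sample": sid, "mean_entropy": predictive_entropy(probs)})
    df = pd.DataFrame(rows).sort_values("mean_entropy", ascending=False, kind="stable")
    return df.reset_index(drop=True)
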
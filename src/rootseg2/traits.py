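"""Phenotypic trait measurement from multi-class tissue masks.

Root diameter, stele diameter and cortex width are measured the way a
researcher measures them with a ruler tool: four intersecting lines through
the root centre at 0°, 45°, 90° and 135°, a chord per line, and the mean of
the four chords as the final value.  The stele is measured as a region —
the union of stele tissue, metaxylem and vascular-bundle classes, i.e.
everything interior to the endodermis — and the cortex width is half the
difference of the two diameters, which keeps it robust to aerenchyma
lacunae inside the cortex.

A chord is the distance between the outermost intersections of the line
with the region; internal gaps (lacunae, vessels) are ignored, exactly as a
manual ruler measurement would ignore them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .vocab import STELE_COMPOSITE

__all__ = ["TraitRecord", "measure_traits", "trait_agreement", "MEASURE_ANGLES_DEG"]

MEASURE_ANGLES_DEG: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)

TRAIT_COLUMNS = ("root_diameter_px", "stele_diameter_px", "cortex_width_px")


@dataclass
class TraitRecord:
    """Traits of one root sample, in pixels and optionally physical units."""

    root_diameter_px: float
    stele_diameter_px: float | None
    cortex_width_px: float | None
    center: tuple[float, float]
    scale_um_per_px: float | None = None
    per_line_chords: dict = field(default_factory=dict)

    @property
    def root_diameter_um(self) -> float | None:
        if self.scale_um_per_px is None:
            return None
        return self.root_diameter_px * self.scale_um_per_px

    @property
    def stele_diameter_um(self) -> float | None:
        if self.scale_um_per_px is None or self.stele_diameter_px is None:
            return None
        return self.stele_diameter_px * self.scale_um_per_px

    @property
    def cortex_width_um(self) -> float | None:
        if self.scale_um_per_px is None or self.cortex_width_px is None:
            return None
        return self.cortex_width_px * self.scale_um_per_px

    def to_dict(self) -> dict:
        d = {
            "root_diameter_px": self.root_diameter_px,
            "stele_diameter_px": self.stele_diameter_px,
            "cortex_width_px": self.cortex_width_px,
            "center_row": self.center[0],
            "center_col": self.center[1],
        }
        if self.scale_um_per_px is not None:
            d.update(
                scale_um_per_px=self.scale_um_per_px,
                root_diameter_um=self.root_diameter_um,
                stele_diameter_um=self.stele_diameter_um,
                cortex_width_um=self.cortex_width_um,
            )
        return d


def _line_chord(
    region: np.ndarray, center: tuple[float, float], angle_deg: float, step: float
) -> float:
    """Extent of ``region`` along the line through ``center`` at ``angle_deg``.

    Samples the line at ``step``-pixel resolution with nearest-pixel lookup;
    returns the distance between the outermost region hits (0 if none).
    """
    h, w = region.shape
    a = np.deg2rad(angle_deg)
    dr, dc = np.sin(a), np.cos(a)
    t_max = float(np.hypot(h, w))
    t = np.arange(-t_max, t_max + step, step)
    rows = np.rint(center[0] + t * dr).astype(int)
    cols = np.rint(center[1] + t * dc).astype(int)
    ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    hits = np.zeros_like(t, dtype=bool)
    hits[ok] = region[rows[ok], cols[ok]]
    if not hits.any():
        return 0.0
    th = t[hits]
    return float(th.max() - th.min())


def measure_traits(
    mask: np.ndarray,
    scale: float | None = None,
    stele_classes: tuple[int, ...] = STELE_COMPOSITE,
    angles_deg: tuple[float, ...] = MEASURE_ANGLES_DEG,
    step: float = 0.25,
) -> TraitRecord:
    """Measure root diameter, stele diameter and cortex width of one mask.

    ``mask`` is a 9-class (or binary) label image; class 0 is background.
    ``scale`` is microns per pixel and only converts units.  Raises if the
    mask contains no foreground.  If none of the stele classes are present,
    the stele and cortex fields are ``None`` (absent, not zero).
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    fg = mask != 0
    if not fg.any():
        raise ValueError("mask contains no foreground pixels; traits are undefined")
    rows, cols = np.nonzero(fg)
    center = (float(rows.mean()), float(cols.mean()))

    stele = np.isin(mask, stele_classes)
    have_stele = bool(stele.any())

    root_chords = [_line_chord(fg, center, a, step) for a in angles_deg]
    stele_chords = (
        [_line_chord(stele, center, a, step) for a in angles_deg] if have_stele else []
    )

    root_d = float(np.mean(root_chords))
    stele_d = float(np.mean(stele_chords)) if have_stele else None
    cortex_w = (root_d - stele_d) / 2.0 if have_stele else None
    return TraitRecord(
        root_diameter_px=root_d,
        stele_diameter_px=stele_d,
        cortex_width_px=cortex_w,
        center=center,
        scale_um_per_px=scale,
        per_line_chords={"root": root_chords, "stele": stele_chords},
    )


def measure_directory(mask_paths, scale: float | None = None) -> pd.DataFrame:
    """Measure every mask file in an iterable of paths; one row per sample."""
    from .io import read_mask

    records = []
    for p in mask_paths:
        p = Path(p)
        rec = measure_traits(read_mask(p), scale=scale)
        row = {"sample": p.stem}
        row.update(rec.to_dict())
        records.append(row)
    if not records:
        raise ValueError("no masks found to measure")
    return pd.DataFrame.from_records(records)


def trait_agreement(
    auto: pd.DataFrame,
    reference: pd.DataFrame,
    out_dir: str | Path | None = None,
    traits: tuple[str, ...] = TRAIT_COLUMNS,
) -> pd.DataFrame:
    """Agreement statistics (R², mean bias, RMSE) between two trait tables.

    Tables are matched on their ``sample`` column.  Optionally writes a CSV
    and a per-trait scatter plot under ``out_dir``.
    """
    for df, name in ((auto, "auto"), (reference, "reference")):
        if "sample" not in df.columns:
            raise ValueError(f"{name} table lacks a 'sample' identifier column")
    merged = auto.merge(reference, on="sample", suffixes=("_auto", "_ref"))
    if len(merged) < 3:
        raise ValueError(
            f"need at least 3 matched samples for agreement statistics, got {len(merged)}"
        )
    rows = []
    for trait in traits:
        a = merged[f"{trait}_auto"].to_numpy(dtype=float)
        r = merged[f"{trait}_ref"].to_numpy(dtype=float)
        keep = np.isfinite(a) & np.isfinite(r)
        a, r = a[keep], r[keep]
        if len(a) < 3:
            rows.append({"trait": trait, "n": len(a), "r2": np.nan, "bias": np.nan, "rmse": np.nan})
            continue
        res = stats.linregress(r, a)
        rows.append(
            {
                "trait": trait,
                "n": int(len(a)),
                "r2": float(res.rvalue**2),
                "bias": float(np.mean(a - r)),
                "rmse": float(np.sqrt(np.mean((a - r) ** 2))),
                "slope": float(res.slope),
                "intercept": float(res.intercept),
            }
        )
    report = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.to_csv(out_dir / "trait_agreement.csv", index=False)
        _scatter_plot(merged, traits, out_dir / "trait_agreement.png")
    return report


def _scatter_plot(merged: pd.DataFrame, traits, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(traits), figsize=(4 * len(traits), 4))
    axes = np.atleast_1d(axes)
    for ax, trait in zip(axes, traits):
        r = merged[f"{trait}_ref"]
        a = merged[f"{trait}_auto"]
        ax.scatter(r, a, s=12, alpha=0.7)
        lo = float(min(r.min(), a.min()))
        hi = float(max(r.max(), a.max()))
        ax.plot([lo, hi], [lo, hi], "k--", lw=1)
        ax.set_xlabel(f"reference {trait}")
        ax.set_ylabel(f"automated {trait}")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
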
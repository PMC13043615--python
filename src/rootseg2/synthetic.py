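"""Procedural generation of LAT-like root cross-section images.

The generator emulates what laser-ablation tomography sections of cereal
roots look like at a coarse scale: a bright-walled, dark-lumened cellular
mosaic organised in concentric tissues — epidermis, a sclerenchyma band,
a cortex of large cells (optionally interrupted by wedge-shaped aerenchyma
lacunae), a thin endodermis, and a central stele containing fine stele
tissue, peripheral vascular bundles and large circular metaxylem vessels.
Cell walls are always brighter than intracellular space, which is the
physical premise the preprocessing channels rely on.

Every sample carries an exact 9-class mask, the derived binary
(tissue vs. background) mask, and analytic ground-truth traits (root and
stele diameter, cortex width) computed from the geometry before any noise
is applied.  Two parameter families, A and B, stand in for two species:
family B has a smaller root, a proportionally larger stele, smaller cortex
cells, fewer lacunae and a different colour cast, so cross-family transfer
is a meaningful test of species generalisation.

What the generator deliberately does not model: real lumen debris,
out-of-plane blur, torn or folded sections, and the full 4096x3000
resolution of the instrument — images default to 256 px so that the
preprocessing constants (which are defined in pixels) remain meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from . import io as rio
from .traits import MEASURE_ANGLES_DEG, TraitRecord
from .vocab import CLASS_INDEX, CLASS_NAMES

__all__ = ["SyntheticSpec", "LabeledSample", "generate", "generate_batch", "generate_dataset", "load_dataset"]

_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic morphology family.

    Ranges are (low, high) tuples sampled per image; scalars are fixed.
    Lengths are in pixels at the configured ``image_size``; intensities on
    the 0-255 scale.  ``wall_intensity`` must exceed ``lumen_intensity``.
    """

    image_size: int = 256
    root_radius: tuple[float, float] = (78.0, 98.0)
    ellipticity: tuple[float, float] = (0.88, 1.0)
    stele_fraction: tuple[float, float] = (0.36, 0.44)
    n_cortex_cell_layers: int | None = None
    cortex_cell_size: float = 13.0
    stele_cell_size: float = 6.0
    scler_cell_size: float = 4.0
    epi_cell_size: float = 8.0
    endo_cell_size: float = 5.0
    epi_thickness: tuple[float, float] = (4.5, 6.0)
    scler_thickness: tuple[float, float] = (4.0, 6.0)
    endo_thickness: tuple[float, float] = (3.5, 5.0)
    aerenchyma_lacunae: tuple[int, int] = (2, 5)
    lacuna_angle_deg: tuple[float, float] = (18.0, 38.0)
    n_metaxylem: tuple[int, int] = (3, 5)
    metaxylem_radius: tuple[float, float] = (7.5, 10.0)
    n_vascular: tuple[int, int] = (7, 10)
    vascular_radius: tuple[float, float] = (3.5, 5.0)
    wall_thickness: float = 1.7
    wall_intensity: float = 205.0
    lumen_intensity: float = 62.0
    background_intensity: float = 16.0
    noise_sd: float = 6.0
    illumination_gradient: float = 0.25
    hue_jitter: float = 12.0
    base_color: tuple[float, float, float] = (1.0, 0.70, 0.32)
    family: str = "A"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wall_intensity <= self.lumen_intensity:
            raise ValueError(
                "wall_intensity must exceed lumen_intensity "
                f"({self.wall_intensity} <= {self.lumen_intensity})"
            )
        if self.image_size < 64:
            raise ValueError("image_size must be at least 64 pixels")
        lo, hi = self.root_radius
        if lo > hi or hi >= self.image_size / 2:
            raise ValueError(f"root_radius range {self.root_radius} does not fit the image")
        if not (0 < self.stele_fraction[0] <= self.stele_fraction[1] < 0.8):
            raise ValueError(f"stele_fraction range {self.stele_fraction} is not plausible")

    @classmethod
    def for_family(cls, family: str, image_size: int = 256, seed: int = 0, **overrides) -> "SyntheticSpec":
        """Preset for morphology family ``A`` (millet-like) or ``B`` (sorghum-like)."""
        s = image_size / 256.0
        scaled = dict(
            image_size=image_size,
            seed=seed,
            epi_cell_size=max(4.0, 8.0 * s),
            endo_cell_size=max(3.0, 5.0 * s),
            epi_thickness=(max(3.0, 4.5 * s), max(3.5, 6.0 * s)),
            scler_thickness=(max(2.8, 4.0 * s), max(3.2, 6.0 * s)),
            endo_thickness=(max(2.5, 3.5 * s), max(3.0, 5.0 * s)),
            vascular_radius=(max(2.5, 3.5 * s), max(3.0, 5.0 * s)),
            wall_thickness=max(1.4, 1.7 * s),
        )
        if family == "A":
            base = cls(
                family="A",
                root_radius=(78.0 * s, 98.0 * s),
                cortex_cell_size=max(6.0, 13.0 * s),
                stele_cell_size=max(3.5, 6.0 * s),
                scler_cell_size=max(3.0, 4.0 * s),
                metaxylem_radius=(max(4.5, 7.5 * s), max(5.5, 10.0 * s)),
                **scaled,
            )
        elif family == "B":
            base = cls(
                family="B",
                root_radius=(max(34.0, 60.0 * s), max(42.0, 76.0 * s)),
                ellipticity=(0.82, 0.97),
                stele_fraction=(0.46, 0.55),
                cortex_cell_size=max(5.0, 9.0 * s),
                stele_cell_size=max(3.2, 5.0 * s),
                scler_cell_size=max(3.0, 4.0 * s),
                aerenchyma_lacunae=(0, 2),
                lacuna_angle_deg=(14.0, 26.0),
                n_metaxylem=(4, 6),
                metaxylem_radius=(max(4.0, 6.0 * s), max(5.0, 8.0 * s)),
                n_vascular=(8, 12),
                wall_intensity=185.0,
                lumen_intensity=72.0,
                background_intensity=26.0,
                noise_sd=7.0,
                illumination_gradient=0.30,
                base_color=(0.55, 0.75, 1.0),
                **scaled,
            )
        else:
            raise ValueError(f"unknown family {family!r}; expected 'A' or 'B'")
        return replace(base, **overrides) if overrides else base


@dataclass
class LabeledSample:
    """One generated image with exact ground truth."""

    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray  # (H, W) uint8, 9-class indices
    binary_mask: np.ndarray  # (H, W) uint8, 1 where mask != background
    truth_traits: TraitRecord | None
    geometry: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask sizes differ")
        if not np.array_equal(self.binary_mask, (self.mask != 0).astype(np.uint8)):
            raise ValueError("binary mask inconsistent with multi-class mask")


def _sample(rng: np.random.Generator, rng_or_val) -> float:
    if isinstance(rng_or_val, tuple):
        return float(rng.uniform(rng_or_val[0], rng_or_val[1]))
    return float(rng_or_val)


def _sample_int(rng: np.random.Generator, lohi: tuple[int, int]) -> int:
    return int(rng.integers(lohi[0], lohi[1] + 1))


def _ang_dist(phi: np.ndarray, phi0: float) -> np.ndarray:
    return np.abs((phi - phi0 + math.pi) % _TWO_PI - math.pi)


def _polar_seeds(
    rng: np.random.Generator, r_inner: float, r_outer: float, spacing: float
) -> np.ndarray:
    """Jittered polar grid of cell-centre seeds in an annulus (w-space px)."""
    pts = []
    r = max(r_inner + spacing / 2.0, spacing / 2.0)
    if r_inner < spacing / 2.0 < r_outer:  # central seed for full discs
        pts.append(rng.uniform(-0.2 * spacing, 0.2 * spacing, size=(1, 2)))
    while r < r_outer - spacing / 4.0:
        n = max(3, int(round(_TWO_PI * r / spacing)))
        ang = rng.uniform(0, _TWO_PI) + np.arange(n) * _TWO_PI / n
        ang = ang + rng.uniform(-0.3, 0.3, n) * _TWO_PI / n
        rr = r + rng.uniform(-0.3, 0.3, n) * spacing
        pts.append(np.column_stack([rr * np.cos(ang), rr * np.sin(ang)]))
        r += spacing * 0.9
    if not pts:
        return np.empty((0, 2))
    return np.concatenate(pts, axis=0)


def _voronoi_walls(
    w1: np.ndarray,
    w2: np.ndarray,
    band: np.ndarray,
    seeds: np.ndarray,
    thickness: float,
) -> np.ndarray:
    """Cell-wall pixels inside ``band``: near-equidistant to two nearest seeds."""
    out = np.zeros_like(band)
    if len(seeds) < 2 or not band.any():
        return out
    tree = cKDTree(seeds)
    pts = np.column_stack([w1[band], w2[band]])
    d, _ = tree.query(pts, k=2)
    out[band] = (d[:, 1] - d[:, 0]) < thickness
    return out


def _spoke_walls(
    w1: np.ndarray,
    w2: np.ndarray,
    phi: np.ndarray,
    rho_px: np.ndarray,
    band: np.ndarray,
    cell_size: float,
    mid_radius: float,
    phase: float,
    thickness: float,
) -> np.ndarray:
    """Radial cell walls in a thin ring band, one spoke per ~cell_size of arc."""
    n = max(4, int(round(_TWO_PI * mid_radius / cell_size)))
    step = _TWO_PI / n
    a = (phi - phase) % step
    arc = np.minimum(a, step - a) * np.maximum(rho_px, 1.0)
    return band & (arc < thickness / 2.0)


def generate(spec: SyntheticSpec) -> LabeledSample:
    """Generate one labelled sample; deterministic for a fixed spec (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    bg = CLASS_INDEX["background"]

    R = _sample(rng, spec.root_radius)
    if R <= 0.0:
        return _background_only(spec, rng)

    ell = _sample(rng, spec.ellipticity)
    alpha = rng.uniform(0.0, math.pi)
    jitter = 0.03 * size
    cy = size / 2.0 + rng.uniform(-jitter, jitter)
    cx = size / 2.0 + rng.uniform(-jitter, jitter)

    epi_t = _sample(rng, spec.epi_thickness) / R
    scl_t = _sample(rng, spec.scler_thickness) / R
    endo_t = _sample(rng, spec.endo_thickness) / R
    stele_f = _sample(rng, spec.stele_fraction)

    r_epi_in = 1.0 - epi_t
    r_scl_in = r_epi_in - scl_t
    r_endo_out = stele_f + endo_t
    cortex_cell = spec.cortex_cell_size
    if spec.n_cortex_cell_layers:
        cortex_cell = max(4.0, (r_scl_in - r_endo_out) * R / spec.n_cortex_cell_layers)
    if r_scl_in - r_endo_out < 0.6 * cortex_cell / R:
        raise ValueError(
            "geometrically impossible spec: cortex annulus thinner than one cell layer "
            f"(stele_fraction={stele_f:.2f}, root radius {R:.0f}px)"
        )

    # Warped coordinates: the root is a circle of radius R in (w1, w2) space.
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    x = xx - cx
    y = yy - cy
    ca, sa = math.cos(alpha), math.sin(alpha)
    u1 = ca * x + sa * y
    u2 = (-sa * x + ca * y) / ell
    rho_px = np.hypot(u1, u2)
    rho = rho_px / R
    phi = np.arctan2(u2, u1)

    mask = np.zeros((size, size), dtype=np.uint8)
    root = rho <= 1.0
    mask[root & (rho > r_epi_in)] = CLASS_INDEX["epidermis"]
    mask[(rho <= r_epi_in) & (rho > r_scl_in)] = CLASS_INDEX["sclerenchyma"]
    mask[(rho <= r_scl_in) & (rho > r_endo_out)] = CLASS_INDEX["cortex"]
    mask[(rho <= r_endo_out) & (rho > stele_f)] = CLASS_INDEX["endodermis"]
    mask[rho <= stele_f] = CLASS_INDEX["stele_tissue"]

    # Aerenchyma lacunae: wedge-shaped cavities in the cortex.
    gap = 3.0 / R
    n_lac = _sample_int(rng, spec.aerenchyma_lacunae)
    lac_lo, lac_hi = r_endo_out + gap, r_scl_in - gap
    if n_lac > 0 and lac_hi > lac_lo:
        base_ang = rng.uniform(0, _TWO_PI)
        for i in range(n_lac):
            phi0 = base_ang + i * _TWO_PI / n_lac + rng.uniform(-0.25, 0.25) * _TWO_PI / n_lac
            hw = math.radians(_sample(rng, spec.lacuna_angle_deg)) / 2.0
            wedge = (
                (mask == CLASS_INDEX["cortex"])
                & (rho >= lac_lo)
                & (rho <= lac_hi)
                & (_ang_dist(phi, phi0) < hw)
            )
            mask[wedge] = CLASS_INDEX["aerenchyma"]

    # Vascular bundles: small dense discs near the stele periphery.
    n_vasc = _sample_int(rng, spec.n_vascular)
    vasc_centers = []
    rho_v = stele_f * 0.78 * R
    base_ang = rng.uniform(0, _TWO_PI)
    for i in range(n_vasc):
        a = base_ang + i * _TWO_PI / n_vasc + rng.uniform(-0.2, 0.2) * _TWO_PI / n_vasc
        r_vb = _sample(rng, spec.vascular_radius)
        cvx, cvy = rho_v * math.cos(a), rho_v * math.sin(a)
        disc = (np.hypot(u1 - cvx, u2 - cvy) < r_vb) & (mask == CLASS_INDEX["stele_tissue"])
        mask[disc] = CLASS_INDEX["vascular_bundle"]
        vasc_centers.append((cvx, cvy, r_vb))

    # Metaxylem vessels: large circular lumens in the stele interior.
    n_met = _sample_int(rng, spec.n_metaxylem)
    met_centers: list[tuple[float, float, float]] = []
    tries = 0
    while len(met_centers) < n_met and tries < 200:
        tries += 1
        r_m = _sample(rng, spec.metaxylem_radius)
        r_pos = rng.uniform(0.0, max(1e-6, stele_f * 0.55 * R - 0.3 * r_m))
        a = rng.uniform(0, _TWO_PI)
        cmx, cmy = r_pos * math.cos(a), r_pos * math.sin(a)
        if any(
            math.hypot(cmx - ox, cmy - oy) < r_m + orr + 2.5 for ox, oy, orr in met_centers
        ):
            continue
        if any(
            math.hypot(cmx - ox, cmy - oy) < r_m + orr + 1.5 for ox, oy, orr in vasc_centers
        ):
            continue
        disc = (np.hypot(u1 - cmx, u2 - cmy) < r_m) & (rho <= stele_f)
        mask[disc] = CLASS_INDEX["metaxylem"]
        met_centers.append((cmx, cmy, r_m))

    walls = _draw_walls(
        rng,
        spec,
        mask,
        u1,
        u2,
        rho_px,
        phi,
        R,
        (r_epi_in, r_scl_in, r_endo_out, stele_f),
        met_centers,
        cortex_cell,
    )

    image = _render(rng, spec, mask, walls, x, y, size)
    traits = _analytic_traits(R, ell, alpha, stele_f, (cy, cx))
    geometry = {
        "root_radius_px": R,
        "ellipticity": ell,
        "alpha_rad": alpha,
        "center": (cy, cx),
        "stele_fraction": stele_f,
        "n_lacunae": int(n_lac),
        "n_metaxylem": len(met_centers),
        "family": spec.family,
    }
    return LabeledSample(
        image=image,
        mask=mask,
        binary_mask=(mask != 0).astype(np.uint8),
        truth_traits=traits,
        geometry=geometry,
    )


def _draw_walls(rng, spec, mask, u1, u2, rho_px, phi, R, radii, met_centers, cortex_cell):
    r_epi_in, r_scl_in, r_endo_out, stele_f = radii
    wt = spec.wall_thickness
    walls = np.zeros(mask.shape, dtype=bool)
    inside = rho_px <= R + wt

    # Interface walls between concentric tissues (and the outer boundary).
    for b in (1.0, r_epi_in, r_scl_in, r_endo_out, stele_f):
        walls |= inside & (np.abs(rho_px - b * R) < wt / 2.0 + 0.3)

    epi_band = mask == CLASS_INDEX["epidermis"]
    walls |= _spoke_walls(
        u1, u2, phi, rho_px, epi_band, spec.epi_cell_size, (1.0 - (1.0 - r_epi_in) / 2) * R,
        rng.uniform(0, _TWO_PI), wt,
    )
    endo_band = mask == CLASS_INDEX["endodermis"]
    walls |= _spoke_walls(
        u1, u2, phi, rho_px, endo_band, spec.endo_cell_size, (stele_f + r_endo_out) / 2 * R,
        rng.uniform(0, _TWO_PI), wt,
    )

    cortex_band = mask == CLASS_INDEX["cortex"]
    seeds = _polar_seeds(rng, r_endo_out * R, r_scl_in * R, cortex_cell)
    walls |= _voronoi_walls(u1, u2, cortex_band, seeds, wt)

    stele_band = mask == CLASS_INDEX["stele_tissue"]
    seeds = _polar_seeds(rng, 0.0, stele_f * R, spec.stele_cell_size)
    walls |= _voronoi_walls(u1, u2, stele_band, seeds, wt * 0.9)

    scl_band = mask == CLASS_INDEX["sclerenchyma"]
    seeds = _polar_seeds(rng, r_scl_in * R, r_epi_in * R, spec.scler_cell_size)
    walls |= _voronoi_walls(u1, u2, scl_band, seeds, wt * 1.3)

    # Metaxylem vessel walls: bright rings around the lumens.
    for cmx, cmy, r_m in met_centers:
        d = np.hypot(u1 - cmx, u2 - cmy)
        walls |= (np.abs(d - r_m) < wt * 0.8) & (rho_px <= stele_f * R + wt)

    # Aerenchyma rims: bright cavity edge in the surrounding cortex.
    aer = mask == CLASS_INDEX["aerenchyma"]
    if aer.any():
        rim = ndimage.binary_dilation(aer, iterations=2) & ~aer
        walls |= rim & (mask == CLASS_INDEX["cortex"])
    return walls


def _render(rng, spec, mask, walls, x, y, size):
    bg_i = spec.background_intensity
    lum = spec.lumen_intensity + rng.uniform(-6, 6)
    wall_i = spec.wall_intensity + rng.uniform(-6, 6)

    intensity = np.full(mask.shape, bg_i, dtype=np.float64)
    fg = mask != 0
    intensity[fg] = lum
    intensity[mask == CLASS_INDEX["aerenchyma"]] = max(4.0, lum - 18.0)
    intensity[mask == CLASS_INDEX["metaxylem"]] = max(4.0, lum - 10.0)
    intensity[mask == CLASS_INDEX["vascular_bundle"]] = wall_i - 14.0
    intensity[walls & fg] = wall_i
    # Outer boundary wall extends a hair into background for a realistic edge.
    intensity[walls & ~fg] = wall_i * 0.85

    intensity = ndimage.gaussian_filter(intensity, sigma=0.6)

    beta = rng.uniform(0, _TWO_PI)
    proj = (x * math.cos(beta) + y * math.sin(beta)) / size
    intensity *= 1.0 + spec.illumination_gradient * proj

    color = _jitter_hue(np.array(spec.base_color, dtype=np.float64), rng, spec.hue_jitter)
    img = intensity[:, :, None] * color[None, None, :]
    img += rng.normal(0.0, spec.noise_sd, img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _jitter_hue(color: np.ndarray, rng: np.random.Generator, jitter_deg: float) -> np.ndarray:
    import colorsys

    h, s, v = colorsys.rgb_to_hsv(*color.tolist())
    h = (h + rng.uniform(-jitter_deg, jitter_deg) / 360.0) % 1.0
    out = np.array(colorsys.hsv_to_rgb(h, s, v))
    return out / max(out.max(), 1e-9)


def _analytic_traits(R, ell, alpha, stele_f, center) -> TraitRecord:
    chords = []
    for a_deg in MEASURE_ANGLES_DEG:
        th = math.radians(a_deg)
        c = math.cos(th - alpha)
        s = math.sin(th - alpha)
        chords.append(2.0 / math.sqrt((c / R) ** 2 + (s / (ell * R)) ** 2))
    root_d = float(np.mean(chords))
    stele_d = root_d * stele_f
    return TraitRecord(
        root_diameter_px=root_d,
        stele_diameter_px=stele_d,
        cortex_width_px=(root_d - stele_d) / 2.0,
        center=center,
        per_line_chords={"root": chords, "stele": [c * stele_f for c in chords]},
    )


def _background_only(spec: SyntheticSpec, rng: np.random.Generator) -> LabeledSample:
    size = spec.image_size
    mask = np.zeros((size, size), dtype=np.uint8)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    intensity = np.full(mask.shape, spec.background_intensity, dtype=np.float64)
    beta = rng.uniform(0, _TWO_PI)
    proj = ((xx - size / 2) * math.cos(beta) + (yy - size / 2) * math.sin(beta)) / size
    intensity *= 1.0 + spec.illumination_gradient * proj
    color = _jitter_hue(np.array(spec.base_color), rng, spec.hue_jitter)
    img = intensity[:, :, None] * color[None, None, :]
    img += rng.normal(0.0, spec.noise_sd, img.shape)
    return LabeledSample(
        image=np.clip(np.round(img), 0, 255).astype(np.uint8),
        mask=mask,
        binary_mask=mask.copy(),
        truth_traits=None,
        geometry={"root_radius_px": 0.0, "family": spec.family},
    )


def generate_batch(spec: SyntheticSpec, n: int, seed: int | None = None) -> list[LabeledSample]:
    """Generate ``n`` samples with per-sample seeds drawn from one master seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    master = spec.seed if seed is None else seed
    rng = np.random.default_rng(master)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    return [generate(replace(spec, seed=int(s))) for s in seeds]


_SPLIT_NAMES = {2: ("train", "test"), 3: ("train", "val", "test")}


def generate_dataset(
    spec: SyntheticSpec,
    n: int,
    out_dir: str | Path,
    split: tuple[float, ...] = (0.8, 0.2),
    seed: int | None = None,
) -> dict:
    """Write ``n`` samples (images, indexed masks, traits CSV, manifest JSON)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {split}")
    if len(split) not in _SPLIT_NAMES:
        raise ValueError("split must have 2 (train/test) or 3 (train/val/test) fractions")
    names = _SPLIT_NAMES[len(split)]

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    master = spec.seed if seed is None else seed
    rng = np.random.default_rng(master)
    seeds = rng.integers(0, 2**31 - 1, size=n)

    bounds = np.cumsum([round(f * n) for f in split[:-1]])
    split_of = np.empty(n, dtype=object)
    split_of[:] = names[-1]
    start = 0
    for b, name in zip(bounds, names[:-1]):
        split_of[start : int(b)] = name
        start = int(b)

    manifest_samples = []
    trait_rows = []
    for i, s in enumerate(seeds):
        sample_id = f"{spec.family}_{i:04d}"
        sample = generate(replace(spec, seed=int(s)))
        rio.write_image(out_dir / "images" / f"{sample_id}.png", sample.image)
        rio.write_mask(out_dir / "masks" / f"{sample_id}.png", sample.mask)
        manifest_samples.append({"id": sample_id, "seed": int(s), "split": str(split_of[i])})
        row = {"sample": sample_id, "split": str(split_of[i])}
        if sample.truth_traits is not None:
            row.update(sample.truth_traits.to_dict())
        trait_rows.append(row)

    pd.DataFrame(trait_rows).to_csv(out_dir / "traits.csv", index=False)
    manifest = {
        "family": spec.family,
        "image_size": spec.image_size,
        "master_seed": int(master),
        "split_fractions": list(split),
        "class_names": list(CLASS_NAMES),
        "samples": manifest_samples,
    }
    rio.write_json(out_dir / "manifest.json", manifest)
    return manifest


def load_dataset(data_dir: str | Path, split: str | None = None) -> list[dict]:
    """Load a generated dataset directory back as id/image/mask records."""
    data_dir = Path(data_dir)
    manifest_path = data_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json under {data_dir}")
    manifest = rio.read_json(manifest_path)
    out = []
    for entry in manifest["samples"]:
        if split is not None and entry["split"] != split:
            continue
        out.append(
            {
                "id": entry["id"],
                "image": rio.read_image(data_dir / "images" / f"{entry['id']}.png"),
                "mask": rio.read_mask(data_dir / "masks" / f"{entry['id']}.png"),
            }
        )
    return out
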
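"""Reading and writing the package's on-disk formats.

Images are 8-bit PNG/TIFF (RGB or gray).  Class masks are single-channel
indexed PNGs carrying the class palette, so they open as colour overlays in
any viewer while round-tripping class indices exactly.  Float channel stacks
use ``.npz`` as a lossless container for testing and debugging.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .vocab import PALETTE

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_region_map",
    "write_region_map",
    "save_stage_input",
    "load_stage_input",
    "write_json",
    "read_json",
]


def read_image(path: str | Path) -> np.ndarray:
    """Read an image file; returns (H, W, 3) uint8 for RGB or (H, W) for gray."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    with Image.open(path) as im:
        if im.mode in ("RGB", "RGBA"):
            return np.asarray(im.convert("RGB"), dtype=np.uint8)
        if im.mode in ("L", "I", "I;16", "P"):
            return np.asarray(im.convert("L"), dtype=np.uint8)
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def write_image(path: str | Path, arr: np.ndarray) -> None:
    arr = np.asarray(arr)
    if arr.dtype != np.uint8:
        arr = np.clip(np.round(arr), 0, 255).astype(np.uint8)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(arr).save(path)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a class mask as an indexed (palette) PNG; indices survive exactly."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    if mask.min() < 0 or mask.max() > 255:
        raise ValueError("mask indices must fit in a uint8 palette image")
    im = Image.fromarray(mask.astype(np.uint8), mode="P")
    pal = np.zeros((256, 3), dtype=np.uint8)
    pal[: len(PALETTE)] = PALETTE
    im.putpalette(pal.flatten().tolist())
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    im.save(path)


def read_mask(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask not found: {path}")
    with Image.open(path) as im:
        if im.mode == "P":
            return np.asarray(im, dtype=np.uint8)
        return np.asarray(im.convert("L"), dtype=np.uint8)


def write_region_map(path: str | Path, regions: np.ndarray) -> None:
    """Write a connected-region identifier map as 16-bit grayscale PNG."""
    regions = np.asarray(regions)
    if regions.min() < 0 or regions.max() > np.iinfo(np.uint16).max:
        raise ValueError("region ids must fit in uint16")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(regions.astype(np.uint16)).save(path)


def read_region_map(path: str | Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im, dtype=np.int64)


def save_stage_input(path: str | Path, channels: np.ndarray, stage: int) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, channels=np.asarray(channels, dtype=np.float32), stage=stage)


def load_stage_input(path: str | Path) -> tuple[np.ndarray, int]:
    with np.load(path) as z:
        return z["channels"], int(z["stage"])


def write_json(path: str | Path, obj) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
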
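"""Tissue class vocabulary shared across the package.

Nine anatomical classes for root cross-sections.  Index 0 is background;
the stele *region* used for trait measurement is the union of stele tissue,
metaxylem and vascular bundle (everything interior to the endodermis).
"""

from __future__ import annotations

import numpy as np

CLASS_NAMES: tuple[str, ...] = (
    "background",
    "cortex",
    "metaxylem",
    "stele_tissue",
    "aerenchyma",
    "vascular_bundle",
    "sclerenchyma",
    "epidermis",
    "endodermis",
)

N_CLASSES = len(CLASS_NAMES)

CLASS_INDEX: dict[str, int] = {name: i for i, name in enumerate(CLASS_NAMES)}

#: Classes forming the stele region for phenotypic measurement.
STELE_COMPOSITE: tuple[int, ...] = (
    CLASS_INDEX["metaxylem"],
    CLASS_INDEX["stele_tissue"],
    CLASS_INDEX["vascular_bundle"],
)

#: Display palette for indexed-PNG masks (RGB per class index).
PALETTE: np.ndarray = np.array(
    [
        (0, 0, 0),        # background
        (228, 160, 68),   # cortex
        (64, 110, 220),   # metaxylem
        (150, 220, 150),  # stele tissue
        (120, 60, 140),   # aerenchyma
        (230, 60, 60),    # vascular bundle
        (240, 230, 90),   # sclerenchyma
        (90, 200, 220),   # epidermis
        (250, 120, 200),  # endodermis
    ],
    dtype=np.uint8,
)

BINARY_CLASS_NAMES: tuple[str, str] = ("background", "foreground")
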
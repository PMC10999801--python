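"""Core containers shared across the pipeline.

Label conventions follow the four morphological classes used throughout:
``0`` background (lumen, slide glass, crypt lumina), ``1`` surface
epithelium, ``2`` crypt epithelium, ``3`` lamina propria (all tissue not
classified as epithelium).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    import pandas as pd

    from .synthetic.params import GenerationParams

BACKGROUND = 0
SURFACE_EPITHELIUM = 1
CRYPT_EPITHELIUM = 2
LAMINA_PROPRIA = 3

COMPARTMENT_LABELS = (BACKGROUND, SURFACE_EPITHELIUM, CRYPT_EPITHELIUM, LAMINA_PROPRIA)

#: Palette used when masks are written as indexed PNG.
MASK_PALETTE = {
    BACKGROUND: (0, 160, 0),
    SURFACE_EPITHELIUM: (40, 60, 220),
    CRYPT_EPITHELIUM: (220, 40, 40),
    LAMINA_PROPRIA: (230, 210, 40),
}

CD3_POS = "CD3_POS"
CD3_NEG = "CD3_NEG"

SURFACE = "SURFACE"
CRYPT = "CRYPT"
LP = "LAMINA_PROPRIA"
EXCLUDED = "EXCLUDED"

#: Mapping from mask label to compartment name used in cell tables.
LABEL_TO_COMPARTMENT = {
    BACKGROUND: EXCLUDED,
    SURFACE_EPITHELIUM: SURFACE,
    CRYPT_EPITHELIUM: CRYPT,
    LAMINA_PROPRIA: LP,
}

CELL_TABLE_COLUMNS = ["cell_id", "row_px", "col_px", "area_px", "true_class", "compartment"]


@dataclass
class CalibratedImage:
    """Brightfield RGB image with physical calibration.

    Pixels are stored as float64 transmitted intensity in ``[0, 1]`` relative
    to the background intensity ``I0`` (so a blank region sits at 1.0).
    """

    pixels: np.ndarray
    um_per_px: float
    stain_profile_id: str = "ihc_cd3"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) RGB array")
        if not self.um_per_px > 0:
            raise ValueError("um_per_px must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def to_uint8(self) -> np.ndarray:
        return np.clip(np.round(self.pixels * 255.0), 0, 255).astype(np.uint8)

    @classmethod
    def from_uint8(
        cls, arr: np.ndarray, um_per_px: float, stain_profile_id: str = "ihc_cd3", seed: int | None = None
    ) -> "CalibratedImage":
        return cls(np.asarray(arr, dtype=np.float64) / 255.0, um_per_px, stain_profile_id, seed)


@dataclass
class GroundTruth:
    """Complete per-pixel and per-cell truth for one synthetic biopsy."""

    compartment_mask: np.ndarray
    band_mask: np.ndarray
    cells: "pd.DataFrame"
    params: "GenerationParams"
    surface_top: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    surface_bottom: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.compartment_mask = np.asarray(self.compartment_mask, dtype=np.uint8)
        self.band_mask = np.asarray(self.band_mask, dtype=bool)
        if self.compartment_mask.shape != self.band_mask.shape:
            raise ValueError("compartment mask and band mask shapes differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.compartment_mask.shape


def validate_mask(mask: np.ndarray) -> np.ndarray:
    """Check a compartment mask only uses known labels; return as uint8."""
    mask = np.asarray(mask)
    bad = np.setdiff1d(np.unique(mask), np.array(COMPARTMENT_LABELS))
    if bad.size:
        raise ValueError(f"unknown compartment labels {bad.tolist()}; expected {COMPARTMENT_LABELS}")
    return mask.astype(np.uint8)
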
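"""Tissue geometry: undulating surface epithelium, crypts, subepithelial band.

The mucosa model is deliberately schematic: lumen above, an undulating
surface-epithelium band of configurable thickness, lamina propria below,
and vertically oriented crypt cross-sections rendered as elliptical annuli
with a lumen (crypts cut perpendicular to the surface, the orientation in
which biopsies are assessed).  The subepithelial band occupies the first
``band_thickness_um`` of lamina propria directly beneath the epithelium;
it keeps the lamina propria label and is tracked in a separate binary mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import ellipse

from .._utils import spawn_rngs
from ..core import (
    BACKGROUND,
    CRYPT_EPITHELIUM,
    LAMINA_PROPRIA,
    SURFACE_EPITHELIUM,
)
from .params import GenerationParams


@dataclass
class Crypt:
    row: int
    col: int
    ry: int
    rx: int
    wall_px: int


@dataclass
class TissueGeometry:
    compartment_mask: np.ndarray
    band_mask: np.ndarray
    surface_top: np.ndarray  # first epithelial row per column
    surface_bottom: np.ndarray  # first lamina-propria row per column
    crypts: list[Crypt] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.compartment_mask.shape


def _surface_profile(params: GenerationParams, rng: np.random.Generator) -> np.ndarray:
    """Row index of the epithelial upper boundary for every column."""
    w = params.image_width_px
    h = params.image_height_px
    amp = params.undulation_amp_um / params.um_per_px
    cols = np.arange(w)
    base = max(2.0, params.lumen_frac * h + amp)
    phase1, phase2 = rng.uniform(0, 2 * np.pi, size=2)
    und = amp * np.sin(2 * np.pi * cols / max(w / 2.5, 8) + phase1)
    und += (amp / 3.0) * np.sin(2 * np.pi * cols / max(w / 9, 4) + phase2)
    top = np.clip(np.round(base + und).astype(int), 1, max(1, h - params.surface_epi_px - 2))
    return top


def generate_tissue_geometry(params: GenerationParams) -> TissueGeometry:
    """Build the compartment mask and band mask for one biopsy.

    Deterministic given ``params.seed`` (geometry uses its own substream).
    Raises :class:`ValueError` when the requested crypt count cannot be
    placed inside the lamina propria without overlap.
    """
    rng = spawn_rngs(params.seed, 3)[0]
    h, w = params.image_height_px, params.image_width_px
    t = params.surface_epi_px
    band_px = params.band_px

    top = _surface_profile(params, rng)
    bottom = np.minimum(top + t, h)

    rows = np.arange(h)[:, None]
    mask = np.full((h, w), LAMINA_PROPRIA, dtype=np.uint8)
    mask[rows < top[None, :]] = BACKGROUND
    mask[(rows >= top[None, :]) & (rows < bottom[None, :])] = SURFACE_EPITHELIUM

    band_mask = np.zeros((h, w), dtype=bool)
    if band_px > 0:
        band_mask[(rows >= bottom[None, :]) & (rows < (bottom + band_px)[None, :])] = True
        band_mask &= mask == LAMINA_PROPRIA

    # Crypts: elliptical annuli embedded in lamina propria, below the band.
    crypts: list[Crypt] = []
    if params.n_crypts > 0:
        rx0 = max(4, round(params.crypt_radius_um / params.um_per_px))
        wall = max(2, round(params.crypt_wall_um / params.um_per_px))
        max_tries = 300 * params.n_crypts
        tries = 0
        while len(crypts) < params.n_crypts and tries < max_tries:
            tries += 1
            rx = max(4, round(rx0 * rng.uniform(0.8, 1.2)))
            ry = max(6, round(rx * rng.uniform(1.2, 1.6)))
            cx = int(rng.integers(rx + 3, max(rx + 4, w - rx - 3)))
            cy_min = int(np.max(bottom[max(0, cx - rx) : cx + rx + 1])) + band_px + 4 + ry
            cy_max = h - ry - 4
            if cy_min >= cy_max:
                continue
            cy = int(rng.integers(cy_min, cy_max))
            pad = 4
            if any(
                abs(cx - c.col) <= rx + c.rx + pad and abs(cy - c.row) <= ry + c.ry + pad
                for c in crypts
            ):
                continue
            crypts.append(Crypt(cy, cx, ry, rx, wall))
        if len(crypts) < params.n_crypts:
            raise ValueError(
                f"could only place {len(crypts)} of {params.n_crypts} crypts without "
                "overlapping the surface epithelium, band, image border or other crypts; "
                "reduce n_crypts or crypt_radius_um, or enlarge the image"
            )
        for c in crypts:
            rr, cc = ellipse(c.row, c.col, c.ry, c.rx, shape=(h, w))
            mask[rr, cc] = CRYPT_EPITHELIUM
            if c.ry - c.wall_px >= 2 and c.rx - c.wall_px >= 2:
                rr, cc = ellipse(c.row, c.col, c.ry - c.wall_px, c.rx - c.wall_px, shape=(h, w))
                mask[rr, cc] = BACKGROUND  # crypt lumen

    return TissueGeometry(mask, band_mask, top, bottom, crypts)
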
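"""Generation parameters for synthetic stained-biopsy images.

The defaults emulate a 20x-scanned colon biopsy fragment: 0.5 um/px pixel
pitch, a ~30 um columnar surface epithelium over lamina propria with crypt
cross-sections, and per-compartment CD3 rates in the range reported for
normal mucosa (a handful of IELs per 100 epithelial cells, a few hundred
CD3+ cells per mm^2 of lamina propria).
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field

STAIN_PROFILE_IDS = ("ihc_cd3", "he", "vg", "mt", "was")


class GenerationParams(BaseModel):
    """All knobs of the synthetic biopsy generator.

    Rates are expressed exactly as the downstream metrics report them:
    ``surface_iel_rate``/``crypt_iel_rate`` as CD3+ cells per 100 CD3-
    epithelial cells, ``lp_cd3_density`` / ``lp_negative_density`` as cells
    per mm^2 of lamina propria.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    image_height_px: int = Field(384, gt=0)
    image_width_px: int = Field(512, gt=0)
    um_per_px: float = Field(0.5, gt=0)
    n_crypts: int = Field(3, ge=0)
    surface_iel_rate: float = Field(5.0, ge=0)
    crypt_iel_rate: float = Field(5.0, ge=0)
    lp_cd3_density: float = Field(300.0, ge=0)
    lp_negative_density: float = Field(600.0, ge=0)
    band_thickness_um: float = Field(1.0, ge=0)
    stain_profile_id: str = "ihc_cd3"
    noise_sd: float = Field(2.0 / 255.0, ge=0)
    seed: int = 0

    # Morphology knobs (um unless noted)
    surface_epi_um: float = Field(30.0, gt=0)
    lumen_frac: float = Field(0.12, ge=0.0, le=0.5)
    undulation_amp_um: float = Field(5.0, ge=0)
    crypt_radius_um: float = Field(18.0, gt=0)
    crypt_wall_um: float = Field(6.0, gt=0)
    # Nuclei are 1.5 um radius discs; the minimum centre separation exceeds
    # one nucleus diameter plus the rendered 1-px DAB halo so that distinct
    # nuclei remain resolvable objects in the rendered image.
    cell_spacing_um: float = Field(4.5, gt=0)
    nucleus_radius_um: float = Field(1.5, gt=0)
    min_center_dist_um: float = Field(4.5, gt=0)

    def model_post_init(self, __context) -> None:
        if self.stain_profile_id not in STAIN_PROFILE_IDS:
            raise ValueError(
                f"unknown stain_profile_id {self.stain_profile_id!r}; known: {STAIN_PROFILE_IDS}"
            )

    # pixel-space conveniences -----------------------------------------
    @property
    def nucleus_radius_px(self) -> int:
        return max(2, round(self.nucleus_radius_um / self.um_per_px))

    @property
    def surface_epi_px(self) -> int:
        return max(2, round(self.surface_epi_um / self.um_per_px))

    @property
    def band_px(self) -> int:
        return int(round(self.band_thickness_um / self.um_per_px))

    @property
    def cell_spacing_px(self) -> float:
        return self.cell_spacing_um / self.um_per_px

    @property
    def min_center_dist_px(self) -> float:
        return self.min_center_dist_um / self.um_per_px

    # JSON round trip ---------------------------------------------------
    def to_json(self) -> str:
        return self.model_dump_json()

    @classmethod
    def from_json(cls, text: str) -> "GenerationParams":
        return cls.model_validate_json(text)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.model_dump(), indent=2))

    @classmethod
    def load(cls, path) -> "GenerationParams":
        return cls.model_validate_json(Path(path).read_text())
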
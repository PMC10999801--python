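"""Beer–Lambert rendering of ground truth into calibrated RGB images.

Each stain profile maps tissue structures to stain concentrations:

``ihc_cd3``
    hematoxylin on every nucleus plus DAB over the nucleus disc and a 1-px
    halo of CD3+ cells (a simplification of the membranous CD3 pattern
    that keeps positivity a per-nucleus mean-OD decision); the band gets
    no chromogen of its own — it is invisible on the immunostain.
``he``
    hematoxylin nuclei on an eosin background; the subepithelial band gets
    the *same* eosin load as surrounding stroma, i.e. essentially zero
    contrast, emulating how a thin band escapes detection on H&E.
``vg`` / ``mt`` / ``was``
    hematoxylin nuclei plus a connective-tissue chromogen that stains the
    band strongly against lightly stained stroma.

Transmitted intensity is ``I = I0 * 10**(-sum_s c_s * A_s)`` per channel
with additive Gaussian intensity noise, clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import disk

from .._utils import spawn_rngs
from ..core import CD3_POS, CalibratedImage, GroundTruth
from ..stains import StainProfile, mix
from .geometry import TissueGeometry
from .params import GenerationParams


@dataclass
class RenderProfile:
    """Structure → concentration recipe under one staining protocol."""

    stain_profile: StainProfile
    nucleus_c: np.ndarray  # concentration vector added over each nucleus disc
    positive_extra_c: np.ndarray  # added over CD3+ disc + halo
    stroma_c: np.ndarray  # base load over all tissue
    band_extra_c: np.ndarray  # added over the band mask
    nucleus_jitter: float = 0.10  # relative per-cell hematoxylin variation


def _profile(second_stain: str, positive=0.0, stroma2=0.0, band2=0.0) -> RenderProfile:
    sp = StainProfile.from_names(["hematoxylin", second_stain])
    return RenderProfile(
        stain_profile=sp,
        nucleus_c=np.array([0.70, 0.0]),
        positive_extra_c=np.array([0.0, positive]),
        stroma_c=np.array([0.05, stroma2]),
        band_extra_c=np.array([0.0, band2]),
    )


RENDER_PROFILES: dict[str, RenderProfile] = {
    "ihc_cd3": _profile("dab", positive=0.80, stroma2=0.0, band2=0.0),
    "he": _profile("eosin", stroma2=0.25, band2=0.0),
    "vg": _profile("vg_fuchsin", stroma2=0.06, band2=0.70),
    "mt": _profile("mt_aniline_blue", stroma2=0.06, band2=0.70),
    "was": _profile("was_sirius_red", stroma2=0.06, band2=0.70),
}


def get_render_profile(stain_profile_id: str) -> RenderProfile:
    try:
        return RENDER_PROFILES[stain_profile_id]
    except KeyError:
        raise ValueError(
            f"unknown stain profile {stain_profile_id!r}; known profiles: "
            f"{sorted(RENDER_PROFILES)}"
        ) from None


def concentration_maps(
    gt: GroundTruth, profile: RenderProfile, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Per-stain concentration images (H, W, k) for a ground truth."""
    h, w = gt.shape
    k = profile.stain_profile.n_stains
    conc = np.zeros((h, w, k), dtype=np.float64)
    tissue = gt.compartment_mask > 0
    conc[tissue] += profile.stroma_c
    conc[gt.band_mask] += profile.band_extra_c

    r = gt.params.nucleus_radius_px
    for row in gt.cells.itertuples(index=False):
        jit = 1.0
        if rng is not None and profile.nucleus_jitter > 0:
            jit = 1.0 + rng.uniform(-profile.nucleus_jitter, profile.nucleus_jitter)
        rr, cc = disk((row.row_px, row.col_px), r + 0.5, shape=(h, w))
        conc[rr, cc] += profile.nucleus_c * jit
        if row.true_class == CD3_POS:
            rr, cc = disk((row.row_px, row.col_px), r + 1.5, shape=(h, w))
            conc[rr, cc] += profile.positive_extra_c
    return conc


def render(gt: GroundTruth, stain_profile_id: str | None = None) -> CalibratedImage:
    """Render a ground truth under a stain profile; deterministic given seed.

    Per-cell hematoxylin jitter and pixel noise come from the render
    substream of ``params.seed``, so re-rendering the same truth under a
    different stain keeps geometry and cells identical.
    """
    params: GenerationParams = gt.params
    pid = stain_profile_id or params.stain_profile_id
    profile = get_render_profile(pid)
    rng = spawn_rngs(params.seed, 3)[2]

    conc = concentration_maps(gt, profile, rng)
    od = mix(conc, profile.stain_profile)
    img = profile.stain_profile.I0 * 10.0 ** (-od)
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return CalibratedImage(img, params.um_per_px, pid, params.seed)


def generate_biopsy(params: GenerationParams) -> GroundTruth:
    """Geometry + nuclei in one call (no rendering)."""
    from .cells import place_nuclei
    from .geometry import generate_tissue_geometry

    geom: TissueGeometry = generate_tissue_geometry(params)
    cells = place_nuclei(geom, params)
    return GroundTruth(
        compartment_mask=geom.compartment_mask,
        band_mask=geom.band_mask,
        cells=cells,
        params=params,
        surface_top=geom.surface_top,
        surface_bottom=geom.surface_bottom,
    )
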
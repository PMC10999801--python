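"""Ground-truth nucleus placement.

Epithelial nuclei are laid out along the surface band and along each crypt
wall at a fixed arc-length spacing; each one is independently CD3+ with
probability ``rate / (100 + rate)`` so that the expected ratio of positive
to negative cells is ``rate / 100`` — i.e. the configured rate is, in
expectation, exactly the "IELs per 100 epithelial cells" the pipeline
measures.  Lamina propria receives CD3+ lymphocytes and CD3- stromal
nuclei as homogeneous Poisson point processes with the configured per-mm^2
densities, thinned by a minimum centre-to-centre distance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.draw import disk

from .._utils import spawn_rngs
from ..core import (
    CD3_NEG,
    CD3_POS,
    CELL_TABLE_COLUMNS,
    CRYPT,
    CRYPT_EPITHELIUM,
    LABEL_TO_COMPARTMENT,
    LAMINA_PROPRIA,
    LP,
    SURFACE,
    SURFACE_EPITHELIUM,
)
from .geometry import TissueGeometry
from .params import GenerationParams


def _disc_area(radius: int) -> int:
    rr, cc = disk((radius, radius), radius + 0.5)
    return len(rr)


def _positive(rng: np.random.Generator, rate: float) -> bool:
    # rate per 100 negatives: P(pos) = rate / (100 + rate)
    return bool(rng.random() < rate / (100.0 + rate))


def _surface_positions(geom: TissueGeometry, params: GenerationParams, rng: np.random.Generator):
    """Arc-length walk along the surface band midline."""
    top = geom.surface_top.astype(float)
    t = params.surface_epi_px
    spacing = params.cell_spacing_px
    slopes = np.gradient(top)
    seg = np.sqrt(1.0 + slopes**2)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    offset = rng.uniform(0, spacing)
    targets = np.arange(offset, total, spacing)
    cols = np.searchsorted(arc, targets).clip(0, len(top) - 1)
    out = []
    for col in cols:
        row = top[col] + t / 2.0 + rng.uniform(-t / 6.0, t / 6.0)
        out.append((row, float(col)))
    return out


def _crypt_positions(geom: TissueGeometry, params: GenerationParams, rng: np.random.Generator):
    """Nuclei along the mid-wall ellipse of each crypt."""
    spacing = params.cell_spacing_px
    out = []
    for c in geom.crypts:
        ry = c.ry - c.wall_px / 2.0
        rx = c.rx - c.wall_px / 2.0
        theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        pts_r = c.row + ry * np.sin(theta)
        pts_c = c.col + rx * np.cos(theta)
        seg = np.sqrt(np.diff(pts_r, append=pts_r[0]) ** 2 + np.diff(pts_c, append=pts_c[0]) ** 2)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        offset = rng.uniform(0, spacing)
        targets = np.arange(offset, arc[-1], spacing)
        idx = np.searchsorted(arc, targets).clip(0, len(theta) - 1)
        for i in idx:
            out.append((float(pts_r[i]), float(pts_c[i])))
    return out


def place_nuclei(geom: TissueGeometry, params: GenerationParams) -> pd.DataFrame:
    """Place ground-truth nuclei; deterministic given ``params.seed``.

    Returns a cell table with columns
    ``cell_id, row_px, col_px, area_px, true_class, compartment``.
    """
    rng = spawn_rngs(params.seed, 3)[1]
    h, w = geom.shape
    mask = geom.compartment_mask
    r = params.nucleus_radius_px
    area = _disc_area(r)
    min_d = max(params.min_center_dist_px, 1.0)

    blocked = np.zeros((h, w), dtype=bool)
    block_r = int(np.ceil(min_d))

    def block(row: float, col: float) -> None:
        rr, cc = disk((row, col), block_r, shape=(h, w))
        blocked[rr, cc] = True

    records: list[tuple] = []

    def add(row: float, col: float, cls: str, compartment: str) -> None:
        records.append((len(records), row, col, area, cls, compartment))
        block(row, col)

    # Epithelial compartments
    for positions, rate, label, name in (
        (_surface_positions(geom, params, rng), params.surface_iel_rate, SURFACE_EPITHELIUM, SURFACE),
        (_crypt_positions(geom, params, rng), params.crypt_iel_rate, CRYPT_EPITHELIUM, CRYPT),
    ):
        for row, col in positions:
            ri, ci = int(round(row)), int(round(col))
            if not (0 <= ri < h and 0 <= ci < w) or mask[ri, ci] != label or blocked[ri, ci]:
                continue
            cls = CD3_POS if _positive(rng, rate) else CD3_NEG
            add(row, col, cls, name)

    # Lamina propria point processes
    lp_pixels = np.flatnonzero((mask == LAMINA_PROPRIA) & ~geom.band_mask)
    area_mm2 = float(np.count_nonzero(mask == LAMINA_PROPRIA)) * params.um_per_px**2 / 1e6
    for density, cls in ((params.lp_cd3_density, CD3_POS), (params.lp_negative_density, CD3_NEG)):
        if density <= 0 or lp_pixels.size == 0:
            continue
        n_target = int(rng.poisson(density * area_mm2))
        placed = 0
        tries = 0
        max_tries = 60 * max(n_target, 1)
        while placed < n_target and tries < max_tries:
            tries += 1
            flat = int(lp_pixels[rng.integers(lp_pixels.size)])
            ri, ci = divmod(flat, w)
            if blocked[ri, ci]:
                continue
            add(float(ri), float(ci), cls, LP)
            placed += 1
        if placed < n_target:
            raise ValueError(
                f"lamina propria density {density}/mm^2 is physically unplaceable at the "
                f"minimum centre distance {params.min_center_dist_um} um "
                f"(placed {placed} of {n_target})"
            )

    cells = pd.DataFrame(records, columns=CELL_TABLE_COLUMNS)
    # Invariant: every centroid lies in a non-background compartment.
    lab = mask[cells["row_px"].round().astype(int), cells["col_px"].round().astype(int)]
    assert all(LABEL_TO_COMPARTMENT[int(v)] == c for v, c in zip(lab, cells["compartment"]))
    return cells
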
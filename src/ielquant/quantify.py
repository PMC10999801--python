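"""Per-biopsy metrics and microscopic-colitis criteria.

Metrics follow the digital-counting conventions: intraepithelial
lymphocytes are reported per 100 epithelial cells separately for surface
and crypt epithelium (the denominator is the CD3-negative epithelial
nuclei — the only countable epithelial-cell proxy on a CD3 stain — with a
config toggle for pos+neg), lamina propria burden as CD3+ cells per mm^2,
and the subepithelial band as an integer micrometre thickness (median of
perpendicular depth samples, rounded half-up).

Diagnostic thresholds: lymphocytic colitis requires IELs strictly
exceeding 20 per 100 epithelial cells, its incomplete form 10–20
(inclusive); collagenous colitis requires a band strictly exceeding 10 um,
its incomplete form 5–10 um (inclusive).  "Exceeding" is read as strict,
"between" as closed, so exact boundary values fall to the incomplete
category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import round_half_up
from .core import CD3_NEG, CD3_POS, CRYPT, LAMINA_PROPRIA, LP, SURFACE, SURFACE_EPITHELIUM

RESULT_COLUMNS = [
    "biopsy_id",
    "location",
    "surface_pos",
    "surface_neg",
    "surface_iel_per_100",
    "crypt_pos",
    "crypt_neg",
    "crypt_iel_per_100",
    "lp_pos_count",
    "lp_area_mm2",
    "lp_density_per_mm2",
    "band_thickness_um",
    "lymphocytic_call",
    "collagenous_call",
]


class UndefinedMetricError(ValueError):
    """A ratio whose denominator is empty: neither 0 nor infinity."""


@dataclass
class IelResult:
    per_100: float
    pos: int
    neg: int


@dataclass
class DensityResult:
    density_per_mm2: float
    area_mm2: float
    pos_count: int


@dataclass
class HotspotResult:
    per_100: float
    fallback: bool  # True when fewer than W negatives forced the global value
    n_windows: int


@dataclass
class BandResult:
    thickness_um: int
    samples_px: list = field(default_factory=list)


@dataclass
class DiagnosticCall:
    lymphocytic: str  # NORMAL | LCi | LC
    collagenous: str  # NORMAL | CCi | CC


@dataclass
class QuantResult:
    biopsy_id: str
    location: str
    surface: IelResult
    crypt: IelResult
    lp: DensityResult
    band_thickness_um: int
    call: DiagnosticCall

    def to_row(self) -> dict:
        return {
            "biopsy_id": self.biopsy_id,
            "location": self.location,
            "surface_pos": self.surface.pos,
            "surface_neg": self.surface.neg,
            "surface_iel_per_100": self.surface.per_100,
            "crypt_pos": self.crypt.pos,
            "crypt_neg": self.crypt.neg,
            "crypt_iel_per_100": self.crypt.per_100,
            "lp_pos_count": self.lp.pos_count,
            "lp_area_mm2": self.lp.area_mm2,
            "lp_density_per_mm2": self.lp.density_per_mm2,
            "band_thickness_um": self.band_thickness_um,
            "lymphocytic_call": self.call.lymphocytic,
            "collagenous_call": self.call.collagenous,
        }


def _classes(cells: pd.DataFrame) -> pd.Series:
    col = "predicted_class" if "predicted_class" in cells else "true_class"
    return cells[col]


def iel_per_100(cells: pd.DataFrame, compartment: str, denominator: str = "negative") -> IelResult:
    """Positive lymphocytes per 100 epithelial cells in one compartment.

    ``denominator='negative'`` divides by CD3- nuclei (default);
    ``'pos_plus_neg'`` divides by all epithelial nuclei.
    """
    if compartment not in (SURFACE, CRYPT):
        raise ValueError(f"compartment must be {SURFACE} or {CRYPT}, got {compartment!r}")
    sub = cells[cells["compartment"] == compartment]
    cls = _classes(sub)
    pos = int((cls == CD3_POS).sum())
    neg = int((cls == CD3_NEG).sum())
    denom = neg if denominator == "negative" else pos + neg
    if denom == 0:
        raise UndefinedMetricError(
            f"no {'CD3-negative ' if denominator == 'negative' else ''}epithelial cells in "
            f"{compartment}: IELs per 100 is undefined"
        )
    return IelResult(100.0 * pos / denom, pos, neg)


def lp_density(cells: pd.DataFrame, mask: np.ndarray, um_per_px: float) -> DensityResult:
    """CD3+ cells per mm^2 of lamina propria (area from label-3 pixels)."""
    n_px = int(np.count_nonzero(np.asarray(mask) == LAMINA_PROPRIA))
    if n_px == 0:
        raise UndefinedMetricError("mask contains no lamina propria pixels")
    area_mm2 = n_px * um_per_px**2 / 1e6
    sub = cells[cells["compartment"] == LP]
    pos = int((_classes(sub) == CD3_POS).sum())
    return DensityResult(pos / area_mm2, area_mm2, pos)


def order_surface_cells(cells: pd.DataFrame) -> pd.DataFrame:
    """Surface-epithelium cells ordered along the surface path.

    The generator's surface band is single-valued in the column index, so
    arc-length order coincides with column order; a precomputed
    ``arc_order`` column takes precedence when present.
    """
    sub = cells[cells["compartment"] == SURFACE]
    key = ["arc_order"] if "arc_order" in sub else ["col_px", "row_px"]
    return sub.sort_values(key, kind="mergesort").reset_index(drop=True)


def hotspot_count(ordered_cells: pd.DataFrame, window_negatives: int = 100) -> HotspotResult:
    """Maximum IELs-per-100 over sliding windows of W consecutive CD3- cells.

    Emulates manual hotspot reading against whole-compartment digital
    counting.  Window ``i`` covers negatives ``i .. i+W-1`` and counts the
    positives lying strictly between the neighbouring negatives ``i-1``
    and ``i+W`` (extended to the sequence ends), so every positive in the
    stretch — including those flanking the first/last negative — is
    attributed to the window.  With fewer than W negatives the global
    per-100 is returned, flagged as a fallback.
    """
    W = int(window_negatives)
    if W < 10:
        raise ValueError("window_negatives must be >= 10")
    cls = _classes(ordered_cells).to_numpy()
    is_pos = cls == CD3_POS
    n_pos_prefix = np.concatenate([[0], np.cumsum(is_pos)])
    neg_idx = np.flatnonzero(cls == CD3_NEG)
    N = len(neg_idx)
    total_pos = int(is_pos.sum())
    if N == 0:
        raise UndefinedMetricError("no CD3-negative surface epithelial cells")
    global_per_100 = 100.0 * total_pos / N
    if N < W:
        return HotspotResult(global_per_100, fallback=True, n_windows=0)
    best = 0.0
    n_windows = N - W + 1
    seq_len = len(cls)
    for i in range(n_windows):
        lo = 0 if i == 0 else neg_idx[i - 1] + 1
        hi = seq_len if i + W >= N else neg_idx[i + W]
        pos_in = n_pos_prefix[hi] - n_pos_prefix[lo]
        best = max(best, 100.0 * pos_in / W)
    return HotspotResult(best, fallback=False, n_windows=n_windows)


def band_thickness(
    band_evidence: np.ndarray,
    mask: np.ndarray,
    um_per_px: float,
    sample_every: int = 4,
    evidence_threshold: float = 0.4,
    search_tol_px: int = 4,
) -> BandResult:
    """Integer-um band thickness from a band mask or stain-concentration map.

    At every ``sample_every``-th column containing surface epithelium, the
    run of band evidence directly beneath the deepest surface pixel is
    measured; the representative thickness is the median of these
    perpendicular depth samples, rounded half-up to whole micrometres.

    ``search_tol_px`` lets the scan pick up the band within a few pixels of
    the nominal epithelial lower boundary, absorbing the boundary error of
    a segmentation mask predicted at a reduced working scale (exact masks
    are unaffected: rows above the true boundary carry no evidence).
    """
    ev = np.asarray(band_evidence)
    if ev.dtype != bool:
        ev = ev > evidence_threshold
    mask = np.asarray(mask)
    if ev.shape != mask.shape:
        raise ValueError("band evidence and mask shapes differ")
    surf_cols = np.flatnonzero((mask == SURFACE_EPITHELIUM).any(axis=0))
    if surf_cols.size == 0:
        raise ValueError("mask contains no surface epithelium")
    if not ev.any():
        return BandResult(0, [])
    h = mask.shape[0]
    samples = []
    for col in surf_cols[::sample_every]:
        col_surface = np.flatnonzero(mask[:, col] == SURFACE_EPITHELIUM)
        nominal = col_surface.max() + 1
        start = max(nominal - search_tol_px, 0)
        stop = min(nominal + search_tol_px + 1, h)
        hits = np.flatnonzero(ev[start:stop, col])
        if hits.size == 0:
            samples.append(0)
            continue
        r = start + hits[0]
        depth = 0
        while r < h and ev[r, col]:
            depth += 1
            r += 1
        samples.append(depth)
    med_px = float(np.median(samples))
    return BandResult(int(round_half_up(med_px * um_per_px)), samples)


def classify_mc(surface_iel_per_100: float, band_thickness_um: float) -> DiagnosticCall:
    """Diagnostic classification against microscopic-colitis criteria."""
    if surface_iel_per_100 < 0 or band_thickness_um < 0:
        raise ValueError("inputs must be non-negative")
    if surface_iel_per_100 > 20:
        lymph = "LC"
    elif surface_iel_per_100 >= 10:
        lymph = "LCi"
    else:
        lymph = "NORMAL"
    if band_thickness_um > 10:
        coll = "CC"
    elif band_thickness_um >= 5:
        coll = "CCi"
    else:
        coll = "NORMAL"
    return DiagnosticCall(lymph, coll)


def quantify_biopsy(
    cells: pd.DataFrame,
    mask: np.ndarray,
    um_per_px: float,
    band_evidence: np.ndarray | None = None,
    biopsy_id: str = "biopsy",
    location: str = "RIGHT_COLON",
    denominator: str = "negative",
) -> QuantResult:
    """All per-biopsy metrics in one call."""
    surface = iel_per_100(cells, SURFACE, denominator)
    crypt = iel_per_100(cells, CRYPT, denominator)
    lp = lp_density(cells, mask, um_per_px)
    if band_evidence is not None:
        band = band_thickness(band_evidence, mask, um_per_px).thickness_um
    else:
        band = 0
    call = classify_mc(surface.per_100, band)
    return QuantResult(biopsy_id, location, surface, crypt, lp, band, call)
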
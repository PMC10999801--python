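"""Nucleus detection, CD3 positivity calling and compartment assignment.

Detection is a deterministic classical pipeline over a nuclear-signal map
(the unmixed hematoxylin concentration — every nucleus carries the
counterstain, whereas the DAB halo of a CD3+ cell would fuse neighbouring
blobs): Gaussian smoothing,
thresholding, distance-transform watershed to split touching nuclei, and
an area filter.  Positivity is a per-nucleus decision: a cell is CD3+ iff
its mean DAB optical density over the nucleus region plus a 1-px halo
(matching the renderer's membranous-pattern simplification) strictly
exceeds the threshold.  The threshold can be calibrated from labelled
material as the midpoint of the two class-conditional mean-OD means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import disk
from skimage.feature import peak_local_max
from skimage.filters import gaussian
from skimage.measure import label as cc_label
from skimage.segmentation import expand_labels, watershed

from .core import CD3_NEG, CD3_POS, LABEL_TO_COMPARTMENT


@dataclass
class DetectionConfig:
    smooth_sigma: float = 1.0
    threshold: float = 0.35
    min_nucleus_area: int = 8
    max_nucleus_area: int = 500
    peak_min_distance: int = 3
    halo_px: int = 1


@dataclass
class DetectionResult:
    cells: pd.DataFrame  # cell_id, row_px, col_px, area_px
    labels: np.ndarray  # labelled nucleus image, 0 = background


@dataclass
class DetectionMetrics:
    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float
    recall: float
    f1: float
    match_radius_px: float


@dataclass
class CalibrationResult:
    threshold_od: float
    pos_mean: float
    neg_mean: float
    separation: float  # gap between class means in OD units


def detect_nuclei(nuclear_map: np.ndarray, config: DetectionConfig | None = None) -> DetectionResult:
    """Detect nuclei on a 2-D nuclear-signal map.

    Returns one record per retained component with intensity-weighted
    centroids; an empty table is a valid result.  Fully deterministic
    (watershed seeds are distance-transform maxima, ties broken by scan
    order).
    """
    config = config or DetectionConfig()
    m = np.asarray(nuclear_map, dtype=np.float64)
    if m.ndim != 2:
        raise ValueError("nuclear_map must be 2-D")
    if not np.all(np.isfinite(m)):
        raise ValueError("nuclear_map must be finite")
    sm = gaussian(m, sigma=config.smooth_sigma, preserve_range=True)
    mask = sm > config.threshold
    empty = DetectionResult(
        pd.DataFrame(columns=["cell_id", "row_px", "col_px", "area_px"]), np.zeros_like(m, dtype=np.int32)
    )
    if not mask.any():
        return empty
    dist = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(
        dist, min_distance=config.peak_min_distance, labels=cc_label(mask), exclude_border=False
    )
    if len(peaks) == 0:
        return empty
    markers = np.zeros_like(m, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-dist, markers, mask=mask)

    n_lab = int(labels.max())
    idx = np.arange(1, n_lab + 1)
    areas = np.bincount(labels.ravel(), minlength=n_lab + 1)[1:]
    keep = (areas >= config.min_nucleus_area) & (areas <= config.max_nucleus_area)
    rows_g, cols_g = np.mgrid[0 : m.shape[0], 0 : m.shape[1]]
    wsum = ndi.sum_labels(m, labels, idx)
    rw = ndi.sum_labels(m * rows_g, labels, idx)
    cw = ndi.sum_labels(m * cols_g, labels, idx)
    ru = ndi.sum_labels(rows_g.astype(float), labels, idx) / np.maximum(areas, 1)
    cu = ndi.sum_labels(cols_g.astype(float), labels, idx) / np.maximum(areas, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rows = np.where(wsum > 0, rw / wsum, ru)
        cols = np.where(wsum > 0, cw / wsum, cu)
    kept = idx[keep]
    lut = np.zeros(n_lab + 1, dtype=np.int32)
    lut[kept] = np.arange(1, len(kept) + 1)
    out_labels = lut[labels]
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(len(kept)),
            "row_px": rows[keep],
            "col_px": cols[keep],
            "area_px": areas[keep].astype(int),
        }
    )
    return DetectionResult(cells, out_labels)


def measure_mean_dab(
    cells: pd.DataFrame,
    dab_map: np.ndarray,
    labels: np.ndarray | None = None,
    halo_px: int = 1,
) -> np.ndarray:
    """Mean DAB OD over each nucleus region + halo.

    With a label image the halo is a distance expansion of each nucleus
    component; without one a disc of the equivalent radius + halo around
    the centroid is used.
    """
    dab = np.asarray(dab_map, dtype=np.float64)
    h, w = dab.shape
    rows = cells["row_px"].to_numpy()
    colx = cells["col_px"].to_numpy()
    if np.any((rows < 0) | (rows > h - 1) | (colx < 0) | (colx > w - 1)):
        raise ValueError("cell centroid outside the DAB map bounds")
    if labels is not None and labels.max() > 0:
        expanded = expand_labels(labels, distance=halo_px) if halo_px > 0 else labels
        idx = cells["cell_id"].to_numpy() + 1
        return ndi.mean(dab, labels=expanded, index=idx)
    out = np.empty(len(cells))
    for i, (row, col, area) in enumerate(zip(rows, colx, cells["area_px"].to_numpy())):
        r = float(np.sqrt(max(area, 1) / np.pi)) + halo_px
        rr, cc = disk((row, col), r + 0.5, shape=(h, w))
        out[i] = dab[rr, cc].mean() if len(rr) else 0.0
    return out


def classify_positivity(
    cells: pd.DataFrame,
    dab_map: np.ndarray,
    threshold_od: float,
    labels: np.ndarray | None = None,
    halo_px: int = 1,
) -> pd.DataFrame:
    """Add ``mean_dab_od`` and ``predicted_class`` columns.

    A cell is CD3_POS iff mean DAB OD strictly exceeds the threshold;
    a mean exactly at the threshold is CD3_NEG.
    """
    if not threshold_od > 0:
        raise ValueError("threshold_od must be positive")
    out = cells.copy()
    mean_od = measure_mean_dab(cells, dab_map, labels, halo_px)
    out["mean_dab_od"] = mean_od
    out["predicted_class"] = np.where(mean_od > threshold_od, CD3_POS, CD3_NEG)
    return out


def calibrate_threshold(labelled_cells: pd.DataFrame, class_column: str = "true_class") -> CalibrationResult:
    """Midpoint of the class-conditional mean-OD means on labelled material.

    ``labelled_cells`` needs ``mean_dab_od`` and a class column containing
    both CD3_POS and CD3_NEG.
    """
    if "mean_dab_od" not in labelled_cells:
        raise ValueError("labelled cells need a mean_dab_od column (run measure_mean_dab first)")
    pos = labelled_cells.loc[labelled_cells[class_column] == CD3_POS, "mean_dab_od"]
    neg = labelled_cells.loc[labelled_cells[class_column] == CD3_NEG, "mean_dab_od"]
    if pos.empty or neg.empty:
        missing = CD3_POS if pos.empty else CD3_NEG
        raise ValueError(f"calibration set contains no {missing} cells")
    pm, nm = float(pos.mean()), float(neg.mean())
    return CalibrationResult((pm + nm) / 2.0, pm, nm, abs(pm - nm))


def assign_compartment(cells: pd.DataFrame, mask: np.ndarray) -> pd.DataFrame:
    """Compartment by centroid-pixel label (background → EXCLUDED)."""
    out = cells.copy()
    rr = cells["row_px"].round().astype(int).clip(0, mask.shape[0] - 1)
    cc = cells["col_px"].round().astype(int).clip(0, mask.shape[1] - 1)
    out["compartment"] = [LABEL_TO_COMPARTMENT[int(v)] for v in mask[rr, cc]]
    return out


def detection_metrics(
    pred: pd.DataFrame, truth: pd.DataFrame, match_radius_px: float
) -> DetectionMetrics:
    """Greedy one-to-one nearest-distance matching within a radius."""
    if not match_radius_px > 0:
        raise ValueError("match_radius_px must be positive")
    p = pred[["row_px", "col_px"]].to_numpy(float)
    t = truth[["row_px", "col_px"]].to_numpy(float)
    pairs = []
    if len(p) and len(t):
        from scipy.spatial import cKDTree

        tree = cKDTree(t)
        cand = tree.query_ball_point(p, r=match_radius_px)
        for i, js in enumerate(cand):
            for j in js:
                d = np.hypot(*(p[i] - t[j]))
                pairs.append((d, i, j))
        pairs.sort(key=lambda x: (x[0], x[1], x[2]))
    used_p: set[int] = set()
    used_t: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        tp += 1
    fp = len(p) - tp
    fn = len(t) - tp
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return DetectionMetrics(tp, fp, fn, precision, recall, f1, match_radius_px)


def count_cells(
    nuclear_map: np.ndarray,
    dab_map: np.ndarray,
    mask: np.ndarray,
    threshold_od: float,
    config: DetectionConfig | None = None,
) -> pd.DataFrame:
    """Convenience: detect → classify → assign compartments in one call."""
    config = config or DetectionConfig()
    det = detect_nuclei(nuclear_map, config)
    cells = classify_positivity(det.cells, dab_map, threshold_od, det.labels, config.halo_px)
    return assign_compartment(cells, mask)
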
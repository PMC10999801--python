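"""Four-class tissue segmentation from sparse labelled ROIs.

A pixel classifier is trained at a reduced working scale (default 4x
downsample, standing in for training at 5x on 20x scans) on per-pixel
features — optical density, multi-scale smoothed texture, a nuclear-density
proxy, relative row position and distance into tissue — and applied
full-frame, upsampled back to native resolution, then cleaned with a
majority (mode) filter and minimum-region-size relabelling.  The classifier
is a random forest: it trains on one CPU in seconds at fixture scale, is
deterministic given a seed, and supports the retrain-with-more-ROIs loop by
keeping its training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.filters import gaussian
from skimage.filters.rank import majority
from skimage.morphology import disk as disk_footprint
from skimage.transform import resize
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix

from .core import COMPARTMENT_LABELS, CalibratedImage, validate_mask
from .stains import rgb_to_od

UNLABELLED = 255  # sentinel in ROI label masks


@dataclass
class SegmentationConfig:
    scale_factor: int = 4
    sigmas: tuple = (1.0, 2.0, 4.0)
    n_estimators: int = 60
    max_depth: int | None = 16
    min_samples_per_class: int = 20
    mode_filter_radius: int = 2
    min_region_px: int = 64  # at native scale
    tissue_od_threshold: float = 0.12
    nuclear_od_threshold: float = 0.5
    accuracy_floor: float = 0.90
    # Coarse-to-fine: after the working-scale prediction, re-classify a
    # native-resolution zone around compartment boundaries with a second
    # classifier trained at native scale.  Boundary placement then carries
    # ~1 px error instead of ~scale_factor px, which matters because cell
    # compartment assignment is a centroid-pixel decision.
    refine_boundaries: bool = True
    refine_margin_px: int = 6
    refine_max_samples: int = 150_000

    def to_dict(self) -> dict:
        return {
            "scale_factor": self.scale_factor,
            "sigmas": list(self.sigmas),
            "n_estimators": self.n_estimators,
            "max_depth": self.max_depth,
            "min_samples_per_class": self.min_samples_per_class,
            "mode_filter_radius": self.mode_filter_radius,
            "min_region_px": self.min_region_px,
            "tissue_od_threshold": self.tissue_od_threshold,
            "nuclear_od_threshold": self.nuclear_od_threshold,
            "accuracy_floor": self.accuracy_floor,
            "refine_boundaries": self.refine_boundaries,
            "refine_margin_px": self.refine_margin_px,
            "refine_max_samples": self.refine_max_samples,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentationConfig":
        d = dict(d)
        d["sigmas"] = tuple(d.get("sigmas", (1.0, 2.0, 4.0)))
        return cls(**d)


@dataclass
class LabeledROI:
    """One labelled region: full image + label mask (255 = unlabelled)."""

    image: CalibratedImage
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.shape != self.image.shape:
            raise ValueError("ROI label mask shape must match its image")


@dataclass
class TrainingData:
    """Coarse (working-scale) samples plus optional native-scale boundary
    samples for the refinement classifier.  Iterates as ``(X, y)``."""

    X: np.ndarray
    y: np.ndarray
    X_fine: np.ndarray | None = None
    y_fine: np.ndarray | None = None

    def __iter__(self):
        return iter((self.X, self.y))


@dataclass
class SegmentationModel:
    classifier: RandomForestClassifier
    config: SegmentationConfig
    classes: tuple = COMPARTMENT_LABELS
    seed: int = 0
    fine_classifier: RandomForestClassifier | None = None
    # Training cache enabling the incremental retrain loop.
    X: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    y: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    X_fine: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    y_fine: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def save(self, path) -> None:
        import joblib

        joblib.dump(self, Path(path))

    @classmethod
    def load(cls, path) -> "SegmentationModel":
        import joblib

        return joblib.load(Path(path))


@dataclass
class SegmentationMetrics:
    confusion: np.ndarray
    accuracy: float
    iou: dict
    recall: dict
    precision: dict


class SegmentationTrainingError(RuntimeError):
    """Raised when training cannot reach the configured accuracy floor."""

    def __init__(self, message: str, report: dict):
        super().__init__(message)
        self.report = report


# ---------------------------------------------------------------------------
# Features


def compute_features(
    image: CalibratedImage, config: SegmentationConfig, scale: int | None = None
) -> np.ndarray:
    """Per-pixel feature stack at the working scale (or an override scale).

    Deterministic given the image and config.  Returns (h, w, n_features).
    """
    s = config.scale_factor if scale is None else scale
    px = image.pixels
    if s > 1:
        small_shape = (int(np.ceil(px.shape[0] / s)), int(np.ceil(px.shape[1] / s)))
        px = resize(px, small_shape + (3,), order=1, anti_aliasing=True, preserve_range=True)
    od = rgb_to_od(px)
    od_total = od.sum(axis=2)
    h, w = od_total.shape
    n_feat = 3 + 3 + len(config.sigmas) + 1 + 1 + 1 + 2 + 1 + 1
    out = np.empty((h, w, n_feat), dtype=np.float32)
    k = 0

    def put(arr):
        nonlocal k
        out[..., k] = arr
        k += 1

    for ch in range(3):
        put(od[..., ch])
    # smoothed per-channel OD gives local stain-colour context (e.g. DAB-
    # rich lamina propria vs hematoxylin-dense epithelium)
    for ch in range(3):
        put(gaussian(od[..., ch], sigma=2.0, preserve_range=True))
    for sigma in config.sigmas:
        put(gaussian(od_total, sigma=sigma, preserve_range=True))
    g1 = gaussian(od_total, sigma=1.0, preserve_range=True)
    gy, gx = np.gradient(g1)
    put(np.hypot(gy, gx))
    # local variance (texture) and a coarse intensity context
    m2 = gaussian(od_total**2, sigma=2.0, preserve_range=True)
    m1 = gaussian(od_total, sigma=2.0, preserve_range=True)
    put(np.sqrt(np.maximum(m2 - m1**2, 0.0)))
    put(gaussian(od_total, sigma=8.0, preserve_range=True))
    # nucleus packing density: binarized nuclei smoothed at two scales, so a
    # strongly stained isolated nucleus (e.g. a CD3+ lymphocyte in lamina
    # propria) is not confused with a contiguous epithelial nuclear band
    nuc = (od_total > config.nuclear_od_threshold).astype(np.float64)
    put(gaussian(nuc, sigma=2.0, preserve_range=True))
    put(gaussian(nuc, sigma=6.0, preserve_range=True))
    put(np.arange(h, dtype=np.float32)[:, None] / max(h - 1, 1) * np.ones((1, w), np.float32))
    tissue = m1 > config.tissue_od_threshold
    put(ndi.distance_transform_edt(tissue) / max(h, w))
    assert k == n_feat
    return out


def _downsample_labels(labels: np.ndarray, s: int) -> np.ndarray:
    if s <= 1:
        return labels
    small_shape = (int(np.ceil(labels.shape[0] / s)), int(np.ceil(labels.shape[1] / s)))
    return resize(labels, small_shape, order=0, anti_aliasing=False, preserve_range=True).astype(
        np.uint8
    )


def _label_boundary_zone(labels: np.ndarray, margin: int) -> np.ndarray:
    """Pixels within ``margin`` of a boundary between two labelled classes
    (255 = unlabelled is ignored)."""
    lab = labels
    boundary = np.zeros(lab.shape, dtype=bool)
    known = lab != UNLABELLED
    diff_v = (lab[:-1] != lab[1:]) & known[:-1] & known[1:]
    boundary[:-1] |= diff_v
    boundary[1:] |= diff_v
    diff_h = (lab[:, :-1] != lab[:, 1:]) & known[:, :-1] & known[:, 1:]
    boundary[:, :-1] |= diff_h
    boundary[:, 1:] |= diff_h
    if not boundary.any():
        return boundary
    return ndi.distance_transform_edt(~boundary) <= margin


def extract_training_set(
    rois: list[LabeledROI], config: SegmentationConfig | None = None
) -> TrainingData:
    """Feature/label pairs from labelled ROIs at the working scale.

    When boundary refinement is enabled, native-scale samples near class
    boundaries are extracted as well (deterministically subsampled).
    Raises :class:`ValueError` naming any compartment class absent from
    all ROIs combined.
    """
    config = config or SegmentationConfig()
    xs, ys = [], []
    xf, yf = [], []
    for roi in rois:
        feats = compute_features(roi.image, config)
        lab = _downsample_labels(roi.labels, config.scale_factor)
        sel = lab != UNLABELLED
        xs.append(feats[sel])
        ys.append(lab[sel])
        if config.refine_boundaries:
            zone = _label_boundary_zone(roi.labels, config.refine_margin_px)
            zone &= roi.labels != UNLABELLED
            if zone.any():
                nfeats = compute_features(roi.image, config, scale=1)
                xf.append(nfeats[zone])
                yf.append(roi.labels[zone])
    X = np.concatenate(xs, axis=0)
    y = np.concatenate(ys, axis=0)
    missing = [c for c in COMPARTMENT_LABELS if not np.any(y == c)]
    if missing:
        raise ValueError(f"class(es) {missing} absent from all training ROIs")
    X_fine = y_fine = None
    if xf:
        X_fine = np.concatenate(xf, axis=0)
        y_fine = np.concatenate(yf, axis=0)
        if len(y_fine) > config.refine_max_samples:
            idx = np.linspace(0, len(y_fine) - 1, config.refine_max_samples).astype(int)
            X_fine, y_fine = X_fine[idx], y_fine[idx]
    return TrainingData(X, y, X_fine, y_fine)


# ---------------------------------------------------------------------------
# Training / prediction


def train(
    training_set: tuple[np.ndarray, np.ndarray],
    config: SegmentationConfig | None = None,
    seed: int = 0,
    validation: list[tuple[CalibratedImage, np.ndarray]] | None = None,
) -> SegmentationModel:
    """Fit the pixel classifier; deterministic given the seed.

    If ``validation`` (image, truth-mask) pairs are given, held-out pixel
    accuracy is checked against ``config.accuracy_floor`` and a
    :class:`SegmentationTrainingError` carrying the per-class report is
    raised when the floor is not met.
    """
    config = config or SegmentationConfig()
    X, y = training_set
    X_fine = getattr(training_set, "X_fine", None)
    y_fine = getattr(training_set, "y_fine", None)
    present, counts = np.unique(y, return_counts=True)
    if len(present) < 2:
        raise ValueError(f"degenerate training set: only class(es) {present.tolist()} present")
    low = {int(c): int(n) for c, n in zip(present, counts) if n < config.min_samples_per_class}
    if low:
        raise ValueError(f"too few training samples for class(es) {low} (min {config.min_samples_per_class})")
    clf = RandomForestClassifier(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(X, y)
    fine_clf = None
    if config.refine_boundaries and X_fine is not None:
        fine_clf = RandomForestClassifier(
            n_estimators=config.n_estimators,
            max_depth=config.max_depth,
            random_state=seed + 1,
            n_jobs=1,
        )
        fine_clf.fit(X_fine, y_fine)
    model = SegmentationModel(
        clf, config, tuple(int(c) for c in present), seed,
        fine_classifier=fine_clf, X=X, y=y, X_fine=X_fine, y_fine=y_fine,
    )
    if validation is not None:
        accs = []
        for img, truth in validation:
            pred = segment(model, img)
            accs.append(float(np.mean(pred == truth)))
        mean_acc = float(np.mean(accs))
        if mean_acc < config.accuracy_floor:
            raise SegmentationTrainingError(
                f"held-out accuracy {mean_acc:.3f} below floor {config.accuracy_floor}",
                report={"per_image_accuracy": accs, "mean_accuracy": mean_acc},
            )
    return model


def retrain(model: SegmentationModel, extra_rois: list[LabeledROI]) -> SegmentationModel:
    """Retrain with additional corrective ROIs appended to the cached set."""
    extra = extract_training_set(extra_rois, model.config)
    X = np.concatenate([model.X, extra.X], axis=0)
    y = np.concatenate([model.y, extra.y], axis=0)
    Xf = yf = None
    if model.X_fine is not None and extra.X_fine is not None:
        Xf = np.concatenate([model.X_fine, extra.X_fine], axis=0)
        yf = np.concatenate([model.y_fine, extra.y_fine], axis=0)
    elif extra.X_fine is not None:
        Xf, yf = extra.X_fine, extra.y_fine
    else:
        Xf, yf = model.X_fine, model.y_fine
    return train(TrainingData(X, y, Xf, yf), model.config, model.seed)


def _remove_small_regions(mask: np.ndarray, min_px: int) -> np.ndarray:
    """Relabel connected components smaller than min_px to the surrounding
    majority class."""
    out = mask.copy()
    for cls in np.unique(mask):
        comp = measure.label(mask == cls, connectivity=1)
        for region in measure.regionprops(comp):
            if region.area >= min_px:
                continue
            rr0, cc0, rr1, cc1 = region.bbox
            r0, c0 = max(rr0 - 1, 0), max(cc0 - 1, 0)
            r1, c1 = min(rr1 + 1, mask.shape[0]), min(cc1 + 1, mask.shape[1])
            patch = comp[r0:r1, c0:c1] == region.label
            border = ndi.binary_dilation(patch) & ~patch
            vals = out[r0:r1, c0:c1][border]
            if vals.size:
                out[r0:r1, c0:c1][patch] = np.bincount(vals).argmax()
    return out


def segment(model: SegmentationModel, image: CalibratedImage) -> np.ndarray:
    """Full-frame prediction at native resolution with post-processing."""
    feats = compute_features(image, model.config)
    h, w = feats.shape[:2]
    pred = model.classifier.predict(feats.reshape(-1, feats.shape[-1])).reshape(h, w).astype(np.uint8)
    H, W = image.shape
    if model.config.scale_factor > 1:
        pred = resize(pred, (H, W), order=0, anti_aliasing=False, preserve_range=True).astype(np.uint8)
    if model.config.mode_filter_radius > 0:
        pred = majority(pred, disk_footprint(model.config.mode_filter_radius))
    if model.fine_classifier is not None and model.config.scale_factor > 1:
        zone = _label_boundary_zone(pred, model.config.refine_margin_px)
        if zone.any():
            nfeats = compute_features(image, model.config, scale=1)
            pred = pred.copy()
            pred[zone] = model.fine_classifier.predict(nfeats[zone]).astype(np.uint8)
            if model.config.mode_filter_radius > 0:
                pred = majority(pred, disk_footprint(model.config.mode_filter_radius))
    if model.config.min_region_px > 0:
        pred = _remove_small_regions(pred, model.config.min_region_px)
    return validate_mask(pred)


def evaluate_segmentation(pred: np.ndarray, truth: np.ndarray) -> SegmentationMetrics:
    """Confusion matrix, overall accuracy and per-class IoU/recall/precision."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    labels = list(COMPARTMENT_LABELS)
    cm = confusion_matrix(truth.ravel(), pred.ravel(), labels=labels)
    accuracy = float(np.trace(cm) / cm.sum())
    iou, recall, precision = {}, {}, {}
    for i, c in enumerate(labels):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        denom = tp + fn + fp
        iou[c] = float(tp / denom) if denom else float("nan")
        recall[c] = float(tp / (tp + fn)) if (tp + fn) else float("nan")
        precision[c] = float(tp / (tp + fp)) if (tp + fp) else float("nan")
    return SegmentationMetrics(cm, accuracy, iou, recall, precision)


# ---------------------------------------------------------------------------
# ROI harvesting from synthetic ground truth


def rois_from_ground_truth(
    image: CalibratedImage,
    truth_mask: np.ndarray,
    n_rois: int,
    roi_size: tuple[int, int],
    rng: np.random.Generator,
) -> list[LabeledROI]:
    """Sample rectangular fully-labelled ROIs from a ground-truth mask,
    emulating a pathologist annotating representative regions."""
    H, W = truth_mask.shape
    rh, rw = roi_size
    rois = []
    for _ in range(n_rois):
        r0 = int(rng.integers(0, max(H - rh, 1)))
        c0 = int(rng.integers(0, max(W - rw, 1)))
        labels = np.full((H, W), UNLABELLED, dtype=np.uint8)
        labels[r0 : r0 + rh, c0 : c0 + rw] = truth_mask[r0 : r0 + rh, c0 : c0 + rw]
        rois.append(LabeledROI(image, labels))
    return rois
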
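"""End-to-end orchestration: simulate → train → segment → count → quantify → stats.

Every stage reads and writes files under one run directory, so a full run
is literally the sequential execution of the individual stages and reruns
with the same config and seed reproduce identical artifacts (verified via
the manifest's content hashes).  Stage seeds are derived deterministically
from the master seed and a fixed stage index.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .detection import DetectionConfig, count_cells, measure_mean_dab, calibrate_threshold
from .quantify import RESULT_COLUMNS, quantify_biopsy
from .segmentation import (
    SegmentationConfig,
    SegmentationModel,
    evaluate_segmentation,
    extract_training_set,
    rois_from_ground_truth,
    segment,
    train,
)
from .stains import rgb_to_od, unmix
from .stats import PairedSample, paired_t, summarize
from .synthetic import GenerationParams, generate_biopsy, get_render_profile, read_fixture, render, write_fixture

log = logging.getLogger("ielquant")

STAGES = ("simulate", "train", "segment", "count", "quantify", "stats")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class SegmentationStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    scale_factor: int = 4
    n_estimators: int = 60
    n_train_images: int = Field(3, ge=1)
    rois_per_image: int = 6
    roi_size: int = 64


class DetectionStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    threshold: float | str = "auto"  # "auto" calibrates on the first biopsy's truth
    smooth_sigma: float = 1.0
    nuclear_threshold: float = 0.35
    min_nucleus_area: int = 8
    max_nucleus_area: int = 500


class QuantStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    window_negatives: int = 100
    denominator: str = "negative"


class StatsStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    alpha: float = 0.05
    exact_cutoff: int = 20
    make_boxplots: bool = True


class RunConfig(BaseModel):
    """Validated end-to-end run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    locations: dict[str, dict] = Field(
        default_factory=lambda: {"ILEUM": {}, "RIGHT_COLON": {}, "LEFT_COLON": {}}
    )
    n_biopsies_per_location: int = Field(2, ge=1)
    generation: dict = Field(default_factory=dict)
    band_stains: list[str] = Field(default_factory=lambda: ["he", "vg"])
    segmentation: SegmentationStageConfig = SegmentationStageConfig()
    detection: DetectionStageConfig = DetectionStageConfig()
    quantification: QuantStageConfig = QuantStageConfig()
    statistics: StatsStageConfig = StatsStageConfig()

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.model_validate(yaml.safe_load(text))
        return cls.model_validate_json(text)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(master: int, stage_index: int, *extra: int) -> int:
    ss = np.random.SeedSequence([int(master), stage_index, *map(int, extra)])
    return int(ss.generate_state(1)[0] % (2**31))


def _biopsy_ids(config: RunConfig) -> list[tuple[str, str]]:
    return [
        (f"{loc.lower()}_{j}", loc)
        for loc in config.locations
        for j in range(config.n_biopsies_per_location)
    ]


# ---------------------------------------------------------------------------
# Stages (each returns {filename: sha256})


def stage_simulate(config: RunConfig, workdir: Path, seed: int) -> dict:
    files = {}
    for i, (bid, loc) in enumerate(_biopsy_ids(config)):
        overrides = {**config.generation, **config.locations[loc]}
        params = GenerationParams(**overrides, seed=_stage_seed(seed, 0, i))
        gt = generate_biopsy(params)
        img = render(gt, "ihc_cd3")
        files.update(write_fixture(gt, img, workdir, basename=bid))
        for stain in config.band_stains:
            extra = render(gt, stain)
            path = workdir / f"{bid}_{stain}.tif"
            tifffile.imwrite(path, extra.to_uint8())
            files[f"{stain}:{bid}"] = str(path)
    return files


def stage_train(config: RunConfig, workdir: Path, seed: int) -> dict:
    rng = np.random.default_rng(_stage_seed(seed, 1))
    ids = _biopsy_ids(config)[: config.segmentation.n_train_images]
    rois = []
    for bid, _ in ids:
        gt, img = read_fixture(workdir, bid)
        rois.extend(
            rois_from_ground_truth(
                img, gt.compartment_mask, config.segmentation.rois_per_image,
                (config.segmentation.roi_size, config.segmentation.roi_size), rng,
            )
        )
    seg_cfg = SegmentationConfig(
        scale_factor=config.segmentation.scale_factor,
        n_estimators=config.segmentation.n_estimators,
    )
    model = train(extract_training_set(rois, seg_cfg), seg_cfg, seed=_stage_seed(seed, 1, 1))
    model_path = workdir / "model.bin"
    model.save(model_path)
    (workdir / "model_config.json").write_text(json.dumps(seg_cfg.to_dict(), indent=2))
    return {"model": str(model_path), "model_config": str(workdir / "model_config.json")}


def stage_segment(config: RunConfig, workdir: Path, seed: int) -> dict:
    from .synthetic.io import _write_palette_png

    model = SegmentationModel.load(workdir / "model.bin")
    files = {}
    report = {}
    for bid, _ in _biopsy_ids(config):
        gt, img = read_fixture(workdir, bid)
        pred = segment(model, img)
        path = workdir / f"{bid}_predmask.png"
        _write_palette_png(pred, path)
        files[f"predmask:{bid}"] = str(path)
        report[bid] = evaluate_segmentation(pred, gt.compartment_mask).accuracy
    rpath = workdir / "segmentation_report.json"
    rpath.write_text(json.dumps(report, indent=2))
    files["segmentation_report"] = str(rpath)
    return files


def _dab_threshold(config: RunConfig, workdir: Path) -> float:
    if config.detection.threshold != "auto":
        return float(config.detection.threshold)
    bid, _ = _biopsy_ids(config)[0]
    gt, img = read_fixture(workdir, bid)
    profile = get_render_profile("ihc_cd3").stain_profile
    conc = unmix(rgb_to_od(img), profile)
    cells = gt.cells.copy()
    cells["mean_dab_od"] = measure_mean_dab(cells, conc[..., 1])
    return calibrate_threshold(cells).threshold_od


def stage_count(config: RunConfig, workdir: Path, seed: int) -> dict:
    from .synthetic.io import _read_indexed_png

    threshold = _dab_threshold(config, workdir)
    det_cfg = DetectionConfig(
        smooth_sigma=config.detection.smooth_sigma,
        threshold=config.detection.nuclear_threshold,
        min_nucleus_area=config.detection.min_nucleus_area,
        max_nucleus_area=config.detection.max_nucleus_area,
    )
    profile = get_render_profile("ihc_cd3").stain_profile
    files = {}
    for bid, _ in _biopsy_ids(config):
        _, img = read_fixture(workdir, bid)
        pred_mask = _read_indexed_png(workdir / f"{bid}_predmask.png")
        conc = unmix(rgb_to_od(img), profile)
        cells = count_cells(conc[..., 0], conc[..., 1], pred_mask, threshold, det_cfg)
        path = workdir / f"{bid}_cells_pred.csv"
        cells.to_csv(path, index=False)
        files[f"cells:{bid}"] = str(path)
    (workdir / "count_config.json").write_text(json.dumps({"dab_threshold_od": threshold}, indent=2))
    files["count_config"] = str(workdir / "count_config.json")
    log.info("DAB positivity threshold OD = %.4f", threshold)
    return files


def stage_quantify(config: RunConfig, workdir: Path, seed: int) -> dict:
    from .synthetic.io import _read_indexed_png

    rows = []
    band_stain = next((s for s in config.band_stains if s != "he"), None)
    for bid, loc in _biopsy_ids(config):
        gt, img = read_fixture(workdir, bid)
        pred_mask = _read_indexed_png(workdir / f"{bid}_predmask.png")
        cells = pd.read_csv(workdir / f"{bid}_cells_pred.csv")
        band_evidence = None
        if band_stain is not None:
            arr = tifffile.imread(workdir / f"{bid}_{band_stain}.tif")
            sp = get_render_profile(band_stain).stain_profile
            band_evidence = unmix(rgb_to_od(np.asarray(arr, float) / 255.0), sp)[..., 1]
        res = quantify_biopsy(
            cells, pred_mask, img.um_per_px, band_evidence,
            biopsy_id=bid, location=loc, denominator=config.quantification.denominator,
        )
        rows.append(res.to_row())
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    path = workdir / "results.csv"
    out.to_csv(path, index=False)
    return {"results": str(path)}


def stage_stats(config: RunConfig, workdir: Path, seed: int) -> dict:
    results = pd.read_csv(workdir / "results.csv")
    report: dict = {"summaries": {}, "tests": {}}
    for loc, sub in results.groupby("location"):
        s = summarize(sub["surface_iel_per_100"])
        report["summaries"][loc] = {
            "n": s.n, "mean": s.mean, "ci": [s.ci_low, s.ci_high], "range": [s.min, s.max],
        }
    right = results[results["location"] == "RIGHT_COLON"].reset_index()
    left = results[results["location"] == "LEFT_COLON"].reset_index()
    n = min(len(right), len(left))
    if n >= 2:
        for metric in ("surface_iel_per_100", "crypt_iel_per_100", "lp_density_per_mm2"):
            try:
                res = paired_t(PairedSample(list(range(n)), right[metric][:n], left[metric][:n]))
                report["tests"][f"right_vs_left:{metric}"] = {
                    "method": res.method, "statistic": res.statistic, "p_value": res.p_value, "n": res.n_used,
                }
            except ValueError as exc:
                report["tests"][f"right_vs_left:{metric}"] = {"error": str(exc)}
    files = {}
    path = workdir / "stats_report.json"
    path.write_text(json.dumps(report, indent=2))
    files["stats_report"] = str(path)
    if config.statistics.make_boxplots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        groups = [g["surface_iel_per_100"].to_numpy() for _, g in results.groupby("location")]
        ax.boxplot(groups, tick_labels=[str(k) for k, _ in results.groupby("location")])
        ax.set_ylabel("surface IELs per 100 epithelial cells")
        fig.tight_layout()
        fig_path = workdir / "surface_iel_boxplot.png"
        fig.savefig(fig_path, dpi=120)
        plt.close(fig)
        files["boxplot"] = str(fig_path)
    return files


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "train": stage_train,
    "segment": stage_segment,
    "count": stage_count,
    "quantify": stage_quantify,
    "stats": stage_stats,
}


def run_stage(name: str, config: RunConfig, workdir, seed: int) -> dict:
    """Run one stage; returns {label: sha256-hashed file path}."""
    if name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {name!r}; stages: {STAGES}")
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    try:
        files = _STAGE_FUNCS[name](config, workdir, seed)
    except Exception as exc:
        raise StageError(name, exc) from exc
    log.info("stage %s finished in %.1fs (%d files)", name, time.perf_counter() - t0, len(files))
    return {label: {"path": p, "sha256": _sha256(Path(p))} for label, p in files.items()}


def run_full(config: RunConfig, workdir, seed: int) -> dict:
    """Execute all stages in order; returns the run manifest."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": int(seed),
        "config": json.loads(config.model_dump_json()),
        "stages": {},
    }
    for i, name in enumerate(STAGES):
        t0 = time.perf_counter()
        manifest["stages"][name] = {
            "files": run_stage(name, config, workdir, seed),
            "seed": int(seed),
            "elapsed_s": round(time.perf_counter() - t0, 3),
        }
    (workdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
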
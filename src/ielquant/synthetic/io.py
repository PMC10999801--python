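"""Fixture I/O: TIFF image, palette-PNG masks, CSV cell table, JSON sidecar."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from ..core import MASK_PALETTE, CalibratedImage, GroundTruth, validate_mask
from .params import GenerationParams


def _write_palette_png(mask: np.ndarray, path: Path) -> None:
    img = Image.fromarray(mask.astype(np.uint8), mode="P")
    palette = np.zeros((256, 3), dtype=np.uint8)
    for idx, rgb in MASK_PALETTE.items():
        palette[idx] = rgb
    img.putpalette(palette.flatten().tolist())
    img.save(path)


def _read_indexed_png(path: Path) -> np.ndarray:
    return np.asarray(Image.open(path), dtype=np.uint8)


def write_fixture(gt: GroundTruth, image: CalibratedImage, directory, basename: str = "biopsy") -> dict:
    """Write one biopsy fixture; returns the file map.

    Files: ``<base>_image.tif`` (8-bit RGB), ``<base>_mask.png`` (palette,
    indices 0–3), ``<base>_band.png`` (binary), ``<base>_cells.csv`` and
    ``<base>_params.json`` (generation params + calibration sidecar).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {
        "image": directory / f"{basename}_image.tif",
        "mask": directory / f"{basename}_mask.png",
        "band": directory / f"{basename}_band.png",
        "cells": directory / f"{basename}_cells.csv",
        "params": directory / f"{basename}_params.json",
    }
    try:
        tifffile.imwrite(files["image"], image.to_uint8())
        _write_palette_png(validate_mask(gt.compartment_mask), files["mask"])
        _write_palette_png(gt.band_mask.astype(np.uint8), files["band"])
        gt.cells.to_csv(files["cells"], index=False)
        sidecar = {
            "um_per_px": image.um_per_px,
            "stain_profile_id": image.stain_profile_id,
            "seed": gt.params.seed,
            "params": gt.params.model_dump(),
        }
        files["params"].write_text(json.dumps(sidecar, indent=2))
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise OSError(f"failed writing fixture under {directory}: {exc}") from exc
    return {k: str(v) for k, v in files.items()}


def read_fixture(directory, basename: str = "biopsy") -> tuple[GroundTruth, CalibratedImage]:
    """Reconstruct the objects written by :func:`write_fixture`."""
    directory = Path(directory)
    sidecar = json.loads((directory / f"{basename}_params.json").read_text())
    params = GenerationParams.model_validate(sidecar["params"])
    arr = tifffile.imread(directory / f"{basename}_image.tif")
    image = CalibratedImage.from_uint8(
        arr, sidecar["um_per_px"], sidecar["stain_profile_id"], sidecar["seed"]
    )
    mask = validate_mask(_read_indexed_png(directory / f"{basename}_mask.png"))
    band = _read_indexed_png(directory / f"{basename}_band.png").astype(bool)
    cells = pd.read_csv(directory / f"{basename}_cells.csv")
    return GroundTruth(mask, band, cells, params), image
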
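"""Optical-density conversion and linear stain unmixing.

Brightfield absorbance follows Beer–Lambert: the transmitted intensity in
channel ``c`` is ``I_c = I0_c * 10**(-OD_c)`` and optical densities of
co-localised stains add linearly.  A :class:`StainProfile` holds one unit
absorbance (OD) vector per stain; unmixing is the least-squares projection
of each pixel's OD vector onto that basis with negative amounts clipped to
zero (stain amounts are physical concentrations).

Hematoxylin / eosin / DAB vectors are the published Ruifrok–Johnston
values; the connective-tissue chromogens (Van Gieson picrofuchsin, Masson
aniline blue, Sirius red) are plausible synthetic vectors chosen to be well
conditioned against hematoxylin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import CalibratedImage

#: Intensity floor applied before the log so saturated-dark pixels stay finite.
INTENSITY_FLOOR = 1.0 / 255.0

#: Maximum basis condition number accepted by :func:`unmix`.
MAX_CONDITION_NUMBER = 1e3


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    return v / np.linalg.norm(v)


# Ruifrok & Johnston absorbance vectors (RGB order).
HEMATOXYLIN_OD = _unit([0.650, 0.704, 0.286])
EOSIN_OD = _unit([0.072, 0.990, 0.105])
DAB_OD = _unit([0.268, 0.570, 0.776])

# Synthetic connective-stain chromogens (see module docstring).
VG_FUCHSIN_OD = _unit([0.15, 0.79, 0.59])
MT_ANILINE_BLUE_OD = _unit([0.74, 0.64, 0.20])
WAS_SIRIUS_RED_OD = _unit([0.09, 0.74, 0.67])

STAIN_VECTORS = {
    "hematoxylin": HEMATOXYLIN_OD,
    "eosin": EOSIN_OD,
    "dab": DAB_OD,
    "vg_fuchsin": VG_FUCHSIN_OD,
    "mt_aniline_blue": MT_ANILINE_BLUE_OD,
    "was_sirius_red": WAS_SIRIUS_RED_OD,
}


@dataclass
class StainProfile:
    """Ordered stain basis for unmixing plus the background intensity I0."""

    stain_names: list[str]
    od_matrix: np.ndarray  # (3, k), unit-norm columns
    I0: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        self.od_matrix = np.asarray(self.od_matrix, dtype=np.float64)
        self.I0 = np.asarray(self.I0, dtype=np.float64)
        if self.od_matrix.ndim != 2 or self.od_matrix.shape[0] != 3:
            raise ValueError("od_matrix must have shape (3, k)")
        if self.od_matrix.shape[1] != len(self.stain_names):
            raise ValueError("od_matrix column count must match stain_names")
        if self.od_matrix.shape[1] > 3:
            raise ValueError("at most 3 stains are supported")
        norms = np.linalg.norm(self.od_matrix, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError(f"od_matrix columns must be unit norm, got norms {norms}")
        if np.any(self.I0 <= 0):
            raise ValueError("I0 must be strictly positive")

    @property
    def n_stains(self) -> int:
        return len(self.stain_names)

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.od_matrix))

    @classmethod
    def from_names(cls, names: list[str], I0=None) -> "StainProfile":
        mat = np.column_stack([STAIN_VECTORS[n] for n in names])
        return cls(list(names), mat, np.ones(3) if I0 is None else np.asarray(I0, float))

    # -- JSON round trip -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "stain_names": list(self.stain_names),
            "od_matrix": self.od_matrix.tolist(),  # row-major
            "I0": self.I0.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StainProfile":
        return cls(list(d["stain_names"]), np.asarray(d["od_matrix"]), np.asarray(d["I0"]))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "StainProfile":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _as_intensity(image) -> np.ndarray:
    if isinstance(image, CalibratedImage):
        return image.pixels
    arr = np.asarray(image, dtype=np.float64)
    return arr


def rgb_to_od(image, I0=1.0, floor: float = INTENSITY_FLOOR) -> np.ndarray:
    """Convert transmitted intensity to optical density per channel.

    ``OD = -log10(I / I0)`` with intensities floored at ``floor`` so that
    dark pixels map to a large finite OD.  ``I0`` may be scalar or
    per-channel.
    """
    I0 = np.asarray(I0, dtype=np.float64)
    if np.any(I0 <= 0):
        raise ValueError("I0 must be strictly positive")
    inten = np.maximum(_as_intensity(image), floor)
    od = -np.log10(inten / I0)
    return np.maximum(od, 0.0)


def od_to_rgb(od: np.ndarray, I0=1.0) -> np.ndarray:
    """Inverse of :func:`rgb_to_od` (without the floor)."""
    return np.asarray(I0, float) * 10.0 ** (-np.asarray(od, float))


def unmix(od: np.ndarray, profile: StainProfile, clip_negative: bool = True) -> np.ndarray:
    """Least-squares stain concentrations per pixel.

    Returns an array of shape ``od.shape[:-1] + (n_stains,)``.  Negative
    amounts are clipped to zero by default.
    """
    cond = profile.condition_number()
    if cond > MAX_CONDITION_NUMBER:
        raise ValueError(
            f"stain basis is ill-conditioned (condition number {cond:.3g} > {MAX_CONDITION_NUMBER:g})"
        )
    od = np.asarray(od, dtype=np.float64)
    if od.shape[-1] != 3:
        raise ValueError("last axis of od must have length 3 (RGB channels)")
    pinv = np.linalg.pinv(profile.od_matrix)  # (k, 3)
    conc = od @ pinv.T
    if clip_negative:
        conc = np.maximum(conc, 0.0)
    return conc


def mix(concentrations: np.ndarray, profile: StainProfile) -> np.ndarray:
    """Forward model: OD image from per-stain concentration maps."""
    conc = np.asarray(concentrations, dtype=np.float64)
    if conc.shape[-1] != profile.n_stains:
        raise ValueError(
            f"concentration last axis {conc.shape[-1]} does not match {profile.n_stains} stains"
        )
    if np.any(conc < 0):
        raise ValueError("stain concentrations must be non-negative")
    return conc @ profile.od_matrix.T
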
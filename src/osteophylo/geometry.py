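"""Cross-sectional geometry of long-bone slices.

A transverse slice is a calibrated greyscale raster: rows run cranio-caudally,
columns medio-laterally, and a single minimum intensity threshold separates
bone tissue from background.  From the set of bone pixels we compute

* CSA   — cross-sectional area, (bone-pixel count) x spacing^2 [mm^2],
* SMA   — second moment of area about a centroidal anatomical axis,
          Sigma A d^2 with A the pixel area and d the perpendicular distance
          of the pixel centre from the centroid [mm^4],
* MOD   — section modulus, SMA / c with c the extreme-fibre distance [mm^3].

SMA_ML (about the medio-lateral axis, resisting cranio-caudal bending) uses
row-axis distances; SMA_CC uses column-axis distances.  Pixels are treated
as point areas at their centres — there is no h^2/12 self-moment term — so a
single-pixel section has SMA = 0 and the discretization error of a smooth
section vanishes linearly as spacing -> 0.

Traits are made size-free by reducing each to a length (CSA^1/2, SMA^1/4,
MOD^1/3) and dividing by the bone's proximodistal inter-articular length;
the ratio R = dimensionless SMA / dimensionless CSA contrasts bending versus
axial-compression resistance.

Whole bones arrive as ordered slice stacks; profiles are taken at 5%
increments of bone length by downsampling the proximal-to-distal slice span
to 21 indices.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "SectionImage",
    "BoneStack",
    "SectionTraits",
    "DimensionlessTraits",
    "IncrementProfile",
    "EmptySectionError",
    "slice_indices",
    "section_traits",
    "normalize_dimensionless",
    "bone_stress",
    "extract_profile",
    "read_stack",
    "write_stack",
    "otsu_threshold",
]

BONES = ("humerus", "radius", "ulna")

TRAIT_COLUMNS = [
    "csa_mm2", "sma_ml_mm4", "sma_cc_mm4", "mod_ml_mm3", "mod_cc_mm3",
    "csa_d", "sma_ml_d", "sma_cc_d", "mod_ml_d", "mod_cc_d", "r_ml", "r_cc",
]


class EmptySectionError(ValueError):
    """Raised when thresholding leaves no bone pixels in a section."""


@dataclass
class SectionImage:
    """A single calibrated greyscale cross-section.

    rows = cranio-caudal axis, columns = medio-lateral axis; images must be
    pre-oriented to this convention (readers accept a rotation flag).
    """

    pixels: np.ndarray
    pixel_spacing: float  # mm per pixel, isotropic
    threshold: float      # minimum intensity counted as bone

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("section image must be 2-D")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")

    @property
    def bone_mask(self) -> np.ndarray:
        return self.pixels >= self.threshold


@dataclass
class BoneStack:
    """Ordered proximal-to-distal slices of one bone with calibration."""

    slices: list[SectionImage]
    proximal_index: int
    distal_index: int
    bone_length_mm: float
    specimen_id: str = "specimen"
    bone: str = "humerus"

    def __post_init__(self):
        if self.proximal_index >= self.distal_index:
            raise ValueError("proximal_index must precede distal_index")
        if self.bone_length_mm <= 0:
            raise ValueError("bone_length_mm must be positive")
        if self.distal_index - self.proximal_index < 20:
            raise ValueError("stack too short to downsample")


@dataclass
class SectionTraits:
    """Raw section traits in physical units (mm-based)."""

    csa: float
    sma_ml: float
    sma_cc: float
    mod_ml: float
    mod_cc: float
    centroid_row: float
    centroid_col: float
    c_ml: float = 0.0  # extreme-fibre distance along the row (CC) axis
    c_cc: float = 0.0  # extreme-fibre distance along the column (ML) axis


@dataclass
class DimensionlessTraits:
    csa_d: float
    sma_ml_d: float
    sma_cc_d: float
    mod_ml_d: float
    mod_cc_d: float
    r_ml: float
    r_cc: float


@dataclass
class IncrementProfile:
    """Per-increment traits along one bone of one specimen."""

    specimen_id: str
    bone: str
    increments: list[int]
    raw: list[SectionTraits]
    traits: list[DimensionlessTraits]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pct, rt, dt in zip(self.increments, self.raw, self.traits):
            rows.append({
                "specimen_id": self.specimen_id,
                "bone": self.bone,
                "increment_pct": pct,
                "csa_mm2": rt.csa,
                "sma_ml_mm4": rt.sma_ml,
                "sma_cc_mm4": rt.sma_cc,
                "mod_ml_mm3": rt.mod_ml,
                "mod_cc_mm3": rt.mod_cc,
                "csa_d": dt.csa_d,
                "sma_ml_d": dt.sma_ml_d,
                "sma_cc_d": dt.sma_cc_d,
                "mod_ml_d": dt.mod_ml_d,
                "mod_cc_d": dt.mod_cc_d,
                "r_ml": dt.r_ml,
                "r_cc": dt.r_cc,
            })
        return pd.DataFrame(rows)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def slice_indices(proximal_index: int, distal_index: int) -> list[int]:
    """The 21 slice numbers at 0, 5, ..., 100% of the proximodistal span.

    The span is divided by 20; fractional positions round half away from
    zero.  Spans of 20-39 slices can yield duplicate indices, which are
    retained.
    """
    span = distal_index - proximal_index
    if span < 20:
        raise ValueError("stack too short to downsample")
    return [proximal_index + _round_half_away(k * span / 20) for k in range(21)]


def section_traits(img: SectionImage) -> SectionTraits:
    """CSA, SMA and MOD of one thresholded section.

    Bone pixels are intensities >= threshold; each contributes a point area
    spacing^2 at its centre.  SMA_ML sums A d^2 over cranio-caudal (row)
    distances from the area centroid, SMA_CC over medio-lateral (column)
    distances; MOD_x = SMA_x / c_x with c_x the largest |d| for that axis.
    """
    mask = img.bone_mask
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise EmptySectionError("empty section: no pixels at or above threshold")
    h = img.pixel_spacing
    area = h * h
    # physical coordinates of pixel centres
    y = (rows + 0.5) * h  # cranio-caudal
    x = (cols + 0.5) * h  # medio-lateral
    cy = y.mean()
    cx = x.mean()
    d_cc = y - cy
    d_ml = x - cx
    csa = rows.size * area
    sma_ml = area * float(np.sum(d_cc**2))
    sma_cc = area * float(np.sum(d_ml**2))
    c_ml = float(np.max(np.abs(d_cc)))
    c_cc = float(np.max(np.abs(d_ml)))
    mod_ml = sma_ml / c_ml if c_ml > 0 else 0.0
    mod_cc = sma_cc / c_cc if c_cc > 0 else 0.0
    return SectionTraits(
        csa=csa, sma_ml=sma_ml, sma_cc=sma_cc, mod_ml=mod_ml, mod_cc=mod_cc,
        centroid_row=cy, centroid_col=cx, c_ml=c_ml, c_cc=c_cc,
    )


def normalize_dimensionless(t: SectionTraits, bone_length_mm: float) -> DimensionlessTraits:
    """Reduce each trait to a length (2nd/4th/3rd root) and divide by L."""
    if bone_length_mm <= 0:
        raise ValueError("bone length must be positive")
    L = bone_length_mm
    csa_d = t.csa ** 0.5 / L
    sma_ml_d = t.sma_ml ** 0.25 / L
    sma_cc_d = t.sma_cc ** 0.25 / L
    mod_ml_d = t.mod_ml ** (1 / 3) / L
    mod_cc_d = t.mod_cc ** (1 / 3) / L
    r_ml = sma_ml_d / csa_d if csa_d > 0 else float("nan")
    r_cc = sma_cc_d / csa_d if csa_d > 0 else float("nan")
    return DimensionlessTraits(csa_d, sma_ml_d, sma_cc_d, mod_ml_d, mod_cc_d, r_ml, r_cc)


def bone_stress(F: float, M: float, y: float, t: SectionTraits,
                axis: str = "ml") -> tuple[float, float]:
    """Illustrative axial and bending stresses (MPa).

    sigma_compression = F / CSA;  sigma_bending = M y / SMA_axis.
    F in N, M in N*mm, y in mm; with areas in mm^2 the results are MPa.
    """
    sma = t.sma_ml if axis == "ml" else t.sma_cc
    if t.csa <= 0 or sma <= 0:
        raise ValueError("stress undefined for zero CSA or SMA")
    return F / t.csa, M * y / sma


def extract_profile(stack: BoneStack) -> IncrementProfile:
    """Traits at 0-100% increments (5% steps) along one bone.

    Downsamples the stack to 21 slices, computes section traits for each and
    normalizes by the bone's inter-articular length.  Downstream statistics
    use only the 19 interior increments (5-95%).
    """
    idx = slice_indices(stack.proximal_index, stack.distal_index)
    raw: list[SectionTraits] = []
    dimless: list[DimensionlessTraits] = []
    for pct, i in zip(range(0, 101, 5), idx):
        local = i - stack.proximal_index
        if local < 0 or local >= len(stack.slices):
            raise IndexError(f"slice {i} missing from stack (increment {pct}%)")
        try:
            t = section_traits(stack.slices[local])
        except EmptySectionError as exc:
            raise EmptySectionError(f"slice {i} (increment {pct}%): {exc}") from exc
        raw.append(t)
        dimless.append(normalize_dimensionless(t, stack.bone_length_mm))
    return IncrementProfile(
        specimen_id=stack.specimen_id, bone=stack.bone,
        increments=list(range(0, 101, 5)), raw=raw, traits=dimless,
    )


def otsu_threshold(pixels: np.ndarray) -> float:
    """Otsu's between-class-variance threshold (explicit fallback only).

    The standard procedure is a manually chosen minimum intensity per slice;
    this automatic alternative must be requested, never silently applied.
    """
    flat = np.asarray(pixels).ravel()
    hist, edges = np.histogram(flat, bins=256)
    mids = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(float)
    total = w.sum()
    best, best_t = -1.0, mids[0]
    cum_w = np.cumsum(w)
    cum_m = np.cumsum(w * mids)
    mean_all = cum_m[-1] / total
    for i in range(1, 256):
        w0 = cum_w[i - 1]
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = cum_m[i - 1] / w0
        m1 = (cum_m[-1] - cum_m[i - 1]) / w1
        var = w0 * w1 * (m0 - m1) ** 2
        if var > best:
            best, best_t = var, mids[i]
    return float(best_t)


# ----------------------------------------------------------------- stack io

_SLICE_RE = re.compile(r"(\d+)\.(png|tif|tiff)$", re.IGNORECASE)


def write_stack(stack: BoneStack, directory) -> Path:
    """Write a stack as zero-padded PNG slices plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(stack.distal_index)))
    for offset, img in enumerate(stack.slices):
        num = stack.proximal_index + offset
        arr = np.clip(img.pixels, 0, 255).astype(np.uint8)
        iio.imwrite(directory / f"slice_{num:0{width}d}.png", arr)
    sidecar = {
        "pixel_spacing_mm": stack.slices[0].pixel_spacing,
        "bone_length_mm": stack.bone_length_mm,
        "proximal_index": stack.proximal_index,
        "distal_index": stack.distal_index,
        "threshold": stack.slices[0].threshold,
        "specimen_id": stack.specimen_id,
        "bone": stack.bone,
    }
    (directory / "stack.json").write_text(json.dumps(sidecar, indent=2))
    return directory


def read_stack(directory, rotate: int = 0) -> BoneStack:
    """Read a slice directory written by :func:`write_stack`.

    ``rotate`` applies that many 90-degree counter-clockwise turns to every
    slice, for stacks stored with a different axis convention.
    """
    directory = Path(directory)
    meta = json.loads((directory / "stack.json").read_text())
    files = sorted(
        (p for p in directory.iterdir() if _SLICE_RE.search(p.name)),
        key=lambda p: int(_SLICE_RE.search(p.name).group(1)),
    )
    if not files:
        raise FileNotFoundError(f"no slice images in {directory}")
    slices = []
    for p in files:
        arr = np.asarray(iio.imread(p))
        if arr.ndim == 3:  # greyscale PNG saved with channels
            arr = arr[..., 0]
        if rotate:
            arr = np.rot90(arr, rotate)
        slices.append(SectionImage(arr, meta["pixel_spacing_mm"], meta["threshold"]))
    return BoneStack(
        slices=slices,
        proximal_index=meta["proximal_index"],
        distal_index=meta["distal_index"],
        bone_length_mm=meta["bone_length_mm"],
        specimen_id=meta.get("specimen_id", directory.name),
        bone=meta.get("bone", "humerus"),
    )
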
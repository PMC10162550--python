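"""Annulus evaluating patterns in ONH-relative coordinates.

Patterns are defined by a relative distance ``d_r`` (annulus mid-line
radius divided by the ONH radius) and relative width ``w_r``; ``d_r < 1``
places the annulus inside the ONH. Sectors restrict the annulus to its
temporal or nasal half (split by the vertical line through the ONH center,
side resolved by laterality), and the ``onh_area`` sector falls back to the
filled ONH mask for comparison with whole-disc analysis.

The angularly corresponding RNFL quantity is the mean thickness of the
peripapillary circular-scan profile over the same sector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .masks import ONHGeometry
from .paa import PAAMap

__all__ = [
    "AnnulusSpec",
    "RNFLProfile",
    "PatternMean",
    "annulus_mask",
    "relative_to_absolute",
    "pattern_mean_paa",
    "rnfl_sector_mean",
]

SECTORS = ("full", "temporal", "nasal", "onh_area")

#: rasterization floor: an annulus is never thinner than 1 px.
MIN_WIDTH_PX = 1.0


@dataclass(frozen=True)
class AnnulusSpec:
    """Evaluating-pattern geometry in ONH-relative units."""

    d_r: float
    w_r: float
    sector: str = "full"
    laterality: str = "OD"

    def __post_init__(self) -> None:
        if self.sector not in SECTORS:
            raise ValueError(f"sector must be one of {SECTORS}")
        if self.laterality not in ("OD", "OS"):
            raise ValueError("laterality must be 'OD' or 'OS'")
        if self.sector != "onh_area":
            if not 0 <= self.d_r <= 1.5:
                raise ValueError("d_r must lie in [0, 1.5]")
            if not 0 <= self.w_r <= 0.25:
                raise ValueError("w_r must lie in [0, 0.25]")


@dataclass
class RNFLProfile:
    """RNFL thickness (um) at equally spaced angles on the 3.5 mm circle.

    Angle convention: 0 deg at the temporal horizontal, increasing
    counter-clockwise for OD; the convention is eye-relative, so sector
    means do not depend on laterality.
    """

    angles_deg: np.ndarray
    thickness_um: np.ndarray

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.thickness_um = np.asarray(self.thickness_um, dtype=float)
        if self.angles_deg.shape != self.thickness_um.shape:
            raise ValueError("angles and thickness must have equal length")
        if len(self.thickness_um) < 8:
            raise ValueError("RNFL profile needs at least 8 samples")
        if not np.all(self.thickness_um > 0):
            raise ValueError("RNFL thickness values must be positive")

    @classmethod
    def from_thickness(cls, thickness_um: np.ndarray) -> "RNFLProfile":
        t = np.asarray(thickness_um, dtype=float)
        angles = np.arange(len(t)) * (360.0 / len(t))
        return cls(angles_deg=angles, thickness_um=t)


class PatternMean(NamedTuple):
    """Mean PAA over a pattern, with the number of contributing pixels."""

    value: float
    n_pixels: int


def band_limits(d_r: float, w_r: float, radius: float,
                min_width_px: float = MIN_WIDTH_PX) -> tuple[float, float]:
    """Radial band [lo, hi] in pixels for an annulus spec.

    Shared by mask rasterization and the landscape's radial-prefix-sum
    path so both select exactly the same pixels.
    """
    w_px = np.maximum(np.asarray(w_r, dtype=float) * radius, min_width_px)
    mid = np.asarray(d_r, dtype=float) * radius
    return mid - w_px / 2.0, mid + w_px / 2.0


def temporal_side(
    cols: np.ndarray,
    center_col: float,
    laterality: str,
    temporal_left_for_od: bool = True,
) -> np.ndarray:
    """Boolean: which columns fall on the temporal side of the divider.

    The divider is the vertical line through the ONH center; pixels on the
    line tie-break to temporal. By the default device convention the
    temporal side is image-left for OD and image-right for OS.
    """
    left = (laterality == "OD") == temporal_left_for_od
    return cols <= center_col if left else cols >= center_col


def annulus_mask(
    geom: ONHGeometry,
    spec: AnnulusSpec,
    image_shape: tuple[int, int],
    onh_mask: np.ndarray | None = None,
    min_width_px: float = MIN_WIDTH_PX,
    temporal_left_for_od: bool = True,
) -> np.ndarray:
    """Rasterize an evaluating pattern into a boolean mask.

    For annulus sectors, a pixel belongs to the pattern when its distance
    rho from the ONH center satisfies |rho - d_r*r| <= max(w_r*r, 1 px)/2;
    the temporal/nasal sectors keep the corresponding half-plane. The
    ``onh_area`` sector returns the filled ONH mask instead and requires
    ``onh_mask``.
    """
    if spec.sector == "onh_area":
        if onh_mask is None:
            raise ValueError("onh_area pattern requires the ONH mask")
        return np.asarray(onh_mask) > 0
    rows, cols = np.mgrid[0 : image_shape[0], 0 : image_shape[1]]
    rho = np.hypot(rows - geom.center[0], cols - geom.center[1])
    lo, hi = band_limits(spec.d_r, spec.w_r, geom.radius, min_width_px)
    mask = (rho >= lo) & (rho <= hi)
    if spec.sector in ("temporal", "nasal"):
        temp = temporal_side(cols, geom.center[1], spec.laterality,
                             temporal_left_for_od)
        mask &= temp if spec.sector == "temporal" else ~temp
    if not mask.any():
        raise ValueError("annulus pattern lies entirely outside the image")
    return mask


def relative_to_absolute(rel: float, r: float) -> float:
    """Convert a relative annulus parameter to pixels: ``rel * r``.

    Reported rounded half-away-from-zero to one decimal, matching how
    absolute distances/widths are tabulated against the dataset mean ONH
    radius.
    """
    if rel < 0:
        raise ValueError("relative parameter must be non-negative")
    if r <= 0:
        raise ValueError("ONH radius must be positive")
    value = rel * r
    return math.floor(value * 10.0 + 0.5) / 10.0


def pattern_mean_paa(
    paa_map: PAAMap,
    pattern: np.ndarray,
    vessel_mask: np.ndarray | None = None,
) -> PatternMean:
    """Mean of valid PAA values over ``pattern`` minus the vessel mask.

    Returns NaN with a zero pixel count when no valid pixel remains (for
    example a pattern fully covered by vessels).
    """
    pattern = np.asarray(pattern) > 0
    if pattern.shape != paa_map.data.shape:
        raise ValueError("pattern shape does not match the PAA map")
    sel = pattern & paa_map.valid
    if vessel_mask is not None:
        sel &= ~(np.asarray(vessel_mask) > 0)
    n = int(sel.sum())
    if n == 0:
        return PatternMean(float("nan"), 0)
    return PatternMean(float(paa_map.data[sel].mean()), n)


def rnfl_sector_mean(
    profile: RNFLProfile, sector: str, laterality: str = "OD"
) -> float:
    """Mean RNFL thickness over the sector's half-circle.

    ``full`` averages all samples; ``temporal``/``nasal`` average the
    samples whose angle lies in the corresponding half (0 deg = temporal
    horizontal; boundary samples at +-90 deg tie-break to temporal). The
    profile convention is eye-relative, so ``laterality`` does not change
    the result; it is accepted for interface symmetry with the image-side
    masks.
    """
    if sector not in ("full", "temporal", "nasal"):
        raise ValueError("sector must be 'full', 'temporal' or 'nasal'")
    t = profile.thickness_um
    if sector == "full":
        return float(t.mean())
    c = np.cos(np.deg2rad(profile.angles_deg))
    c[np.abs(c) < 1e-12] = 0.0
    sel = c >= 0 if sector == "temporal" else c < 0
    if not sel.any():
        raise ValueError(f"no profile samples in the {sector} sector")
    return float(t[sel].mean())
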
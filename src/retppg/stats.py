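"""Age-controlled PAA-RNFL correlation analysis.

RNFL thickness declines with age, so the association between pattern-mean
PAA and sector-mean RNFL thickness is measured with the first-order partial
Pearson correlation controlling for age:

    R = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2) (1 - r_yz^2)),

with two-sided p-values from t = R * sqrt((n-3)/(1-R^2)) on n-3 degrees of
freedom. A full-search over the annulus parameters (d_r, w_r) yields a
correlation landscape whose optimum locates the evaluating pattern that
maximizes |R|; the cells with R >= 95% of the maximum form the plateau
region reported alongside the optimum.

Note that the landscape maximum is selection-inflated: no multiplicity
correction is applied across grid cells, so the maximal R overstates the
out-of-sample correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst

from .masks import ONHGeometry
from .paa import PAAMap
from .patterns import (
    MIN_WIDTH_PX,
    RNFLProfile,
    band_limits,
    rnfl_sector_mean,
    temporal_side,
)

__all__ = [
    "GROUPS",
    "EyeSample",
    "CorrelationLandscape",
    "LandscapeOptimum",
    "partial_correlation",
    "correlation_landscape",
    "landscape_optimum",
    "group_summary",
    "default_d_r_grid",
    "default_w_r_grid",
]

#: glaucoma staging groups, ordered by increasing severity (OHT precedes
#: pre-perimetric in the clinical grouping convention used throughout).
GROUPS = ("G_norm", "G_OHT", "G_pre", "G_per")


def default_d_r_grid() -> np.ndarray:
    """Relative-distance grid: step 0.01 over [0, 1.5]."""
    return np.round(np.arange(0, 151) * 0.01, 6)


def default_w_r_grid() -> np.ndarray:
    """Relative-width grid: step 0.004 over [0, 0.25]."""
    return np.round(np.arange(0, 63) * 0.004, 6)


@dataclass
class EyeSample:
    """Everything the landscape needs for one eye."""

    eye_id: str
    paa_map: PAAMap
    geometry: ONHGeometry
    rnfl_profile: RNFLProfile
    age: float
    laterality: str = "OD"
    vessel_mask: np.ndarray | None = None
    onh_mask: np.ndarray | None = None
    group: str | None = None


@dataclass
class LandscapeOptimum:
    d_r: float
    w_r: float
    R_max: float
    region95: np.ndarray


@dataclass
class CorrelationLandscape:
    """Grid of age-controlled partial correlation over (d_r, w_r).

    ``R``, ``p`` and ``n`` are indexed ``[i_d, i_w]``; cells with fewer
    usable eyes than the minimum are NaN.
    """

    d_r_values: np.ndarray
    w_r_values: np.ndarray
    R: np.ndarray
    p: np.ndarray
    n: np.ndarray
    sector: str = "full"

    @property
    def optimum(self) -> LandscapeOptimum:
        return landscape_optimum(self)

    def to_dataframe(self) -> pd.DataFrame:
        dd, ww = np.meshgrid(self.d_r_values, self.w_r_values, indexing="ij")
        return pd.DataFrame(
            {
                "d_r": dd.ravel(),
                "w_r": ww.ravel(),
                "R": self.R.ravel(),
                "p": self.p.ravel(),
                "n": self.n.ravel(),
            }
        )


def partial_correlation(
    x: np.ndarray, y: np.ndarray, z: np.ndarray
) -> tuple[float, float]:
    """First-order partial Pearson correlation of x and y given z.

    Rows with any missing component are dropped (pairwise-complete).
    Zero variance in x or y raises; zero variance in the control falls
    back to the plain Pearson correlation with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.shape == y.shape == z.shape):
        raise ValueError("x, y, z must have equal length")
    keep = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    x, y, z = x[keep], y[keep], z[keep]
    n = len(x)
    if n < 4:
        raise ValueError("partial correlation needs at least 4 complete rows")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    if np.std(z) == 0:
        warnings.warn("control variable has zero variance; "
                      "falling back to plain Pearson correlation")
        r, p = sst.pearsonr(x, y)
        return float(r), float(p)
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    num = r_xy - r_xz * r_yz
    denom = np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    if min(1 - r_xz**2, 1 - r_yz**2) < 1e-12:
        # a variable is collinear with the control; its residual vanishes,
        # so nothing is left to correlate (e.g. y == z gives R = 0)
        if abs(num) < 1e-8:
            return 0.0, 1.0
        raise ValueError("a control correlation is +-1")
    r = float(np.clip(num / denom, -1.0, 1.0))
    return r, _partial_p(r, n)


def _partial_p(r, n):
    """Two-sided p for a first-order partial correlation (n-3 df)."""
    r = np.asarray(r, dtype=float)
    df = np.asarray(n, dtype=float) - 3
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1 - r**2))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2 * sst.t.sf(np.abs(t), np.maximum(df, 1)))
    return float(p) if p.ndim == 0 else p


class _RadialAccumulator:
    """Sorted radial distances + prefix sums of valid PAA for one eye.

    Lets an annulus-band mean be evaluated in O(log n) with exactly the
    same pixel-membership predicate as the rasterized annulus mask.
    """

    def __init__(self, eye: EyeSample, sector: str, temporal_left_for_od: bool):
        data = eye.paa_map.data
        h, w = data.shape
        rows, cols = np.mgrid[0:h, 0:w]
        rho = np.hypot(
            rows - eye.geometry.center[0], cols - eye.geometry.center[1]
        )
        sel = eye.paa_map.valid
        if eye.vessel_mask is not None:
            sel &= ~(np.asarray(eye.vessel_mask) > 0)
        if sector in ("temporal", "nasal"):
            temp = temporal_side(
                cols, eye.geometry.center[1], eye.laterality, temporal_left_for_od
            )
            sel &= temp if sector == "temporal" else ~temp
        rho = rho[sel]
        vals = data[sel]
        order = np.argsort(rho, kind="stable")
        self.rho = rho[order]
        self.cumsum = np.concatenate([[0.0], np.cumsum(vals[order])])
        self.radius = eye.geometry.radius

    def band_means(self, los: np.ndarray, his: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        i0 = np.searchsorted(self.rho, los, side="left")
        i1 = np.searchsorted(self.rho, his, side="right")
        counts = i1 - i0
        with np.errstate(invalid="ignore", divide="ignore"):
            means = (self.cumsum[i1] - self.cumsum[i0]) / counts
        means[counts == 0] = np.nan
        return means, counts


def correlation_landscape(
    eyes: list[EyeSample],
    d_r_values: np.ndarray | None = None,
    w_r_values: np.ndarray | None = None,
    sector: str = "full",
    min_eyes: int = 4,
    min_width_px: float = MIN_WIDTH_PX,
    temporal_left_for_od: bool = True,
) -> CorrelationLandscape:
    """Full-search grid of age-controlled partial correlation.

    For every (d_r, w_r) cell the annulus is matched to each eye's own ONH
    radius, the vessel-excluded pattern-mean PAA is paired with the
    angularly corresponding sector-mean RNFL thickness, and the partial
    correlation controlling for age is computed across eyes. Cells where
    fewer than ``min_eyes`` eyes contribute a valid pattern mean are NaN.
    """
    if sector not in ("full", "temporal", "nasal"):
        raise ValueError("landscape sector must be 'full', 'temporal' or 'nasal'")
    d_r_values = default_d_r_grid() if d_r_values is None else np.asarray(d_r_values, float)
    w_r_values = default_w_r_grid() if w_r_values is None else np.asarray(w_r_values, float)
    if d_r_values.size == 0 or w_r_values.size == 0:
        raise ValueError("empty parameter grid")
    if len(eyes) < min_eyes:
        raise ValueError("not enough eyes for a landscape")

    profile_sector = sector if sector != "full" else "full"
    x = np.array([rnfl_sector_mean(e.rnfl_profile, profile_sector, e.laterality)
                  for e in eyes])
    z = np.array([e.age for e in eyes], dtype=float)

    nd, nw = len(d_r_values), len(w_r_values)
    dd, ww = np.meshgrid(d_r_values, w_r_values, indexing="ij")
    cells_d = dd.ravel()
    cells_w = ww.ravel()
    n_cells = nd * nw

    V = np.empty((n_cells, len(eyes)))
    C = np.empty((n_cells, len(eyes)), dtype=np.int64)
    for j, eye in enumerate(eyes):
        acc = _RadialAccumulator(eye, sector, temporal_left_for_od)
        los, his = band_limits(cells_d, cells_w, acc.radius, min_width_px)
        V[:, j], C[:, j] = acc.band_means(los, his)

    R, p, n_used = _vectorized_partial(V, x, z, min_eyes)
    return CorrelationLandscape(
        d_r_values=d_r_values,
        w_r_values=w_r_values,
        R=R.reshape(nd, nw),
        p=p.reshape(nd, nw),
        n=n_used.reshape(nd, nw),
        sector=sector,
    )


def _vectorized_partial(V, x, z, min_eyes):
    """Per-cell partial correlation of V rows with x given z."""
    n_cells, n_eyes = V.shape
    R = np.full(n_cells, np.nan)
    p = np.full(n_cells, np.nan)
    n_used = np.zeros(n_cells, dtype=int)
    finite = np.isfinite(V)
    full = finite.all(axis=1)

    if full.any() and np.std(x) > 0 and np.std(z) > 0:
        vf = V[full]
        vc = vf - vf.mean(axis=1, keepdims=True)
        sv = np.sqrt((vc**2).sum(axis=1))
        xc = x - x.mean()
        zc = z - z.mean()
        sx = np.sqrt((xc**2).sum())
        sz = np.sqrt((zc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r_vx = vc @ xc / (sv * sx)
            r_vz = vc @ zc / (sv * sz)
        r_xz = float(xc @ zc / (sx * sz))
        with np.errstate(invalid="ignore", divide="ignore"):
            rr = (r_vx - r_vz * r_xz) / np.sqrt((1 - r_vz**2) * (1 - r_xz**2))
        rr = np.clip(rr, -1.0, 1.0)
        R[full] = rr
        n_used[full] = n_eyes
        p[full] = _partial_p(rr, np.full(rr.shape, n_eyes))

    # cells with missing eyes: handled individually
    rest = np.flatnonzero(~full)
    for idx in rest:
        keep = finite[idx]
        n_used[idx] = int(keep.sum())
        if n_used[idx] < max(min_eyes, 4):
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                R[idx], p[idx] = partial_correlation(V[idx, keep], x[keep], z[keep])
        except ValueError:
            continue
    too_few = n_used < min_eyes
    R[too_few] = np.nan
    p[too_few] = np.nan
    return R, p, n_used


def landscape_optimum(landscape: CorrelationLandscape) -> LandscapeOptimum:
    """Argmax cell of a landscape and its >=95%-of-maximum region.

    Ties are broken toward the smallest d_r, then the smallest w_r; all
    cells NaN raises ``ValueError``.
    """
    R = landscape.R
    if not np.isfinite(R).any():
        raise ValueError("landscape has no finite cell")
    r_max = np.nanmax(R)
    cand = np.argwhere(R == r_max)
    # lexicographic tie-break: smallest d_r index, then smallest w_r index
    i_d, i_w = min(map(tuple, cand))
    region95 = np.where(np.isfinite(R), R >= 0.95 * r_max, False)
    return LandscapeOptimum(
        d_r=float(landscape.d_r_values[i_d]),
        w_r=float(landscape.w_r_values[i_w]),
        R_max=float(r_max),
        region95=region95,
    )


def group_summary(
    records: pd.DataFrame, value_columns: list[str] | None = None
) -> pd.DataFrame:
    """Per-group median, quartiles and n for each value column.

    ``records`` must have a ``group`` column with labels from ``GROUPS``;
    groups absent from the cohort are reported with n = 0. Returns a tidy
    frame indexed by (group, variable).
    """
    if "group" not in records.columns:
        raise ValueError("records need a 'group' column")
    unknown = set(records["group"]) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    if value_columns is None:
        value_columns = [
            c for c in records.columns
            if c != "group" and pd.api.types.is_numeric_dtype(records[c])
        ]
    rows = []
    for g in GROUPS:
        sub = records.loc[records["group"] == g]
        for col in value_columns:
            vals = sub[col].dropna().to_numpy() if len(sub) else np.array([])
            rows.append(
                {
                    "group": g,
                    "variable": col,
                    "n": len(vals),
                    "median": np.median(vals) if len(vals) else np.nan,
                    "q1": np.percentile(vals, 25) if len(vals) else np.nan,
                    "q3": np.percentile(vals, 75) if len(vals) else np.nan,
                }
            )
    return pd.DataFrame(rows).set_index(["group", "variable"])
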
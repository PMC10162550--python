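"""File adapters: TIFF stacks, PNG masks, CSV tables, JSON manifests.

Video stacks travel as multi-page TIFF (frame order = time). The default
on-disk dtype is float32, which round-trips the in-memory stack losslessly;
``dtype="uint16"`` writes classic 16-bit interchange files (8- and 16-bit
inputs are promoted to the [0, 1] float range on read). Masks are 8-bit PNG
with 0 = background, 255 = mask; any other values are binarized at > 0 with
a warning.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .masks import ONHGeometry
from .paa import PAAMap
from .registration import FrameStack
from .stats import CorrelationLandscape

__all__ = [
    "tiff_stack_write",
    "tiff_stack_read",
    "png_mask_write",
    "png_mask_read",
    "cohort_csv_write",
    "cohort_csv_read",
    "rnfl_profile_write",
    "rnfl_profile_read",
    "geometry_csv_write",
    "paa_map_write",
    "paa_map_read",
    "landscape_csv_write",
    "landscape_plot",
    "manifest_write",
    "manifest_verify",
]

COHORT_REQUIRED = ["eye_id", "age", "laterality", "group", "rnfl_profile_path"]


def tiff_stack_write(path, stack: FrameStack, dtype: str = "float32") -> None:
    data = stack.data
    if dtype == "uint16":
        data = np.clip(data, 0, 1) * 65535.0 + 0.5
        data = data.astype(np.uint16)
    elif dtype == "float32":
        data = data.astype(np.float32)
    else:
        raise ValueError("dtype must be 'float32' or 'uint16'")
    meta = {"fps": stack.fps, "registered": stack.registered}
    tifffile.imwrite(path, data, description=json.dumps(meta),
                     photometric="minisblack")


def tiff_stack_read(path, fps: float | None = None) -> FrameStack:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if data.dtype == np.uint8:
        data = data.astype(np.float32) / 255.0
    elif data.dtype == np.uint16:
        data = data.astype(np.float32) / 65535.0
    fps = fps if fps is not None else float(meta.get("fps", 25.0))
    return FrameStack(
        data,
        fps=fps,
        provenance=str(path),
        registered=bool(meta.get("registered", False)),
    )


def png_mask_write(path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask) > 0).astype(np.uint8) * 255)


def png_mask_read(path) -> np.ndarray:
    raw = np.asarray(iio.imread(path))
    if raw.ndim == 3:
        raw = raw[..., 0]
    vals = np.unique(raw)
    if not set(vals.tolist()) <= {0, 255}:
        warnings.warn(f"{path}: mask values {vals.tolist()} binarized at > 0")
    return raw > 0


def cohort_csv_write(path, records: pd.DataFrame) -> None:
    records.to_csv(path, index=False)


def cohort_csv_read(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: cohort CSV missing columns {missing}")
    return df


def rnfl_profile_write(path, angles_deg: np.ndarray, thickness_um: np.ndarray) -> None:
    pd.DataFrame(
        {"angle_deg": angles_deg, "thickness_um": thickness_um}
    ).to_csv(path, index=False)


def rnfl_profile_read(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    for col in ("angle_deg", "thickness_um"):
        if col not in df.columns:
            raise ValueError(f"{path}: RNFL profile CSV missing column '{col}'")
    return df["angle_deg"].to_numpy(float), df["thickness_um"].to_numpy(float)


def geometry_csv_write(path, geometries: dict[str, ONHGeometry]) -> None:
    rows = [
        {
            "eye_id": eid,
            "center_row": g.center[0],
            "center_col": g.center[1],
            "radius_px": g.radius,
        }
        for eid, g in geometries.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def paa_map_write(path, paa: PAAMap, validity_path=None) -> None:
    """Float32 TIFF of the map plus an optional validity PNG."""
    tifffile.imwrite(
        path,
        paa.data.astype(np.float32),
        description=json.dumps({"n_pulses": paa.n_pulses}),
        photometric="minisblack",
    )
    if validity_path is not None:
        png_mask_write(validity_path, paa.valid)


def paa_map_read(path) -> PAAMap:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray().astype(float)
        desc = tf.pages[0].description
    n_pulses = 1
    if desc:
        try:
            n_pulses = int(json.loads(desc).get("n_pulses", 1))
        except (json.JSONDecodeError, TypeError):
            pass
    return PAAMap(data=data, n_pulses=n_pulses)


def landscape_csv_write(path, landscape: CorrelationLandscape) -> None:
    landscape.to_dataframe().to_csv(path, index=False)


def landscape_plot(landscape: CorrelationLandscape, path) -> None:
    """Contour plot of R over (d_r, w_r) with the 95%-of-max region outlined."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .stats import landscape_optimum

    opt = landscape_optimum(landscape)
    fig, ax = plt.subplots(figsize=(7, 4))
    dd, ww = np.meshgrid(landscape.d_r_values, landscape.w_r_values, indexing="ij")
    cf = ax.contourf(dd, ww, np.nan_to_num(landscape.R), levels=20, cmap="viridis")
    ax.contour(
        dd, ww, opt.region95.astype(float), levels=[0.5],
        colors="yellow", linewidths=1.5,
    )
    ax.plot(opt.d_r, opt.w_r, "r+", markersize=10)
    ax.set_xlabel("relative distance $d_r$")
    ax.set_ylabel("relative width $w_r$")
    ax.set_title(f"{landscape.sector}: R_max = {opt.R_max:.3f} "
                 f"at d_r = {opt.d_r:.3f}, w_r = {opt.w_r:.3f}")
    fig.colorbar(cf, ax=ax, label="partial R (age-controlled)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def manifest_write(run_dir, seed: int, params: dict) -> Path:
    """Record seed, parameters and a content hash of every output file."""
    run_dir = Path(run_dir)
    files = sorted(
        p for p in run_dir.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "seed": seed,
        "params": params,
        "files": {str(p.relative_to(run_dir)): _sha256(p) for p in files},
    }
    out = run_dir / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return out


def manifest_verify(run_dir) -> list[str]:
    """Return the relative paths whose content no longer matches the manifest."""
    run_dir = Path(run_dir)
    manifest = json.loads((run_dir / "manifest.json").read_text())
    bad = []
    for rel, digest in manifest["files"].items():
        p = run_dir / rel
        if not p.is_file() or _sha256(p) != digest:
            bad.append(rel)
    return bad
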
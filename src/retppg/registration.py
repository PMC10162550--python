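"""Two-stage rigid registration of fundus video sequences.

Eye movements during a ~10 s acquisition are compensated frame by frame so
that a sharp mean image and stable per-pixel time signals can be computed.
Stage 1 removes large shifts by phase correlation; stage 2 removes small
residual shifts and rotation with a Lucas-Kanade tracking step on adaptively
selected high-texture points, followed by a robust rigid fit.

Coordinate conventions: 0-based (row, col), origin top-left; ``dx`` is
positive rightward (col+), ``dy`` positive downward (row+); ``theta`` is in
degrees, positive in the direction that rotates the +row axis toward the
+col axis about the image center. The reference for a sequence is the
running mean of previously registered frames, initialized at frame 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.registration import phase_cross_correlation

__all__ = [
    "FrameStack",
    "MotionTrace",
    "phase_correlate",
    "lk_refine",
    "register_sequence",
    "rigid_warp",
]


@dataclass
class FrameStack:
    """A T x H x W intensity video with its frame rate.

    Intensities are kept as floats (nominally in [0, 1]); ``provenance``
    records the source path or generator and whether the stack has been
    registered.
    """

    data: np.ndarray
    fps: float
    provenance: str = "unknown"
    registered: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] < 2:
            raise ValueError("FrameStack requires a T x H x W array with T >= 2")
        if not np.all(np.isfinite(self.data)) or np.nanmin(self.data) < 0:
            raise ValueError("frame intensities must be finite and non-negative")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]


@dataclass
class MotionTrace:
    """Per-frame rigid transform relative to the reference, plus residuals."""

    dx: np.ndarray
    dy: np.ndarray
    theta: np.ndarray
    residual: np.ndarray
    flagged: np.ndarray

    def __len__(self) -> int:
        return len(self.dx)

    def as_array(self) -> np.ndarray:
        """(T, 3) array of (dx, dy, theta)."""
        return np.column_stack([self.dx, self.dy, self.theta])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self)),
                "dx": self.dx,
                "dy": self.dy,
                "theta": self.theta,
                "residual": self.residual,
                "flagged": self.flagged.astype(int),
            }
        )


def _rotation_matrix(theta_deg: float) -> np.ndarray:
    """Rotation matrix acting on (row, col) vectors."""
    th = np.deg2rad(theta_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s], [s, c]])


def rigid_warp(
    image: np.ndarray,
    dx: float,
    dy: float,
    theta: float,
    order: int = 1,
    mode: str = "nearest",
) -> np.ndarray:
    """Render ``image`` content moved by (dx, dy) and rotated by ``theta``.

    The forward model: a scene point q maps to p = R(theta) (q - c) + c + t
    in the output, with c the image center and t = (dy, dx). Bilinear
    interpolation by default; border samples replicate the edge.
    """
    image = np.asarray(image, dtype=float)
    c = (np.array(image.shape) - 1) / 2.0
    t = np.array([dy, dx])
    rinv = _rotation_matrix(-theta)
    offset = c - rinv @ (c + t)
    return ndimage.affine_transform(image, rinv, offset=offset, order=order, mode=mode)


def _unwarp(image: np.ndarray, dx: float, dy: float, theta: float) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`rigid_warp`: align a moved frame back to the scene.

    Returns the aligned frame (edge-replicated at the border) and a boolean
    validity mask that is False where samples fell outside the frame.
    """
    image = np.asarray(image, dtype=float)
    c = (np.array(image.shape) - 1) / 2.0
    t = np.array([dy, dx])
    r = _rotation_matrix(theta)
    offset = (c + t) - r @ c
    aligned = ndimage.affine_transform(image, r, offset=offset, order=1, mode="nearest")
    ones = np.ones_like(image)
    cover = ndimage.affine_transform(ones, r, offset=offset, order=1, mode="constant", cval=0.0)
    return aligned, cover > 0.999


def phase_correlate(
    frame: np.ndarray, reference: np.ndarray, upsample_factor: int = 20
) -> tuple[float, float]:
    """Translation (dx, dy) of ``frame`` relative to ``reference``.

    Maximizes the normalized cross-power-spectrum response (phase
    correlation), refined to subpixel resolution by local upsampled
    cross-correlation around the integer peak.

    Raises ``ValueError`` for mismatched shapes or constant inputs, for
    which the correlation surface is undefined.
    """
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if frame.shape != reference.shape:
        raise ValueError("frame and reference must have the same shape")
    if np.ptp(frame) == 0 or np.ptp(reference) == 0:
        raise ValueError("phase correlation is undefined for constant images")
    shift, _, _ = phase_cross_correlation(
        reference, frame, upsample_factor=upsample_factor, normalization="phase"
    )
    # skimage returns the (row, col) correction to apply to `frame`; the
    # displacement of the frame content is its negation.
    return float(-shift[1]), float(-shift[0])


def _select_points(
    reference: np.ndarray, n_points: int, margin: int, min_quantile: float
) -> np.ndarray:
    """Adaptive tracking-point selection: local gradient-magnitude maxima.

    Low-texture regions (gradient below the ``min_quantile`` quantile) are
    excluded, as are points closer than ``margin`` to the border.
    """
    gy, gx = np.gradient(reference)
    resp = np.hypot(gy, gx)
    local_max = ndimage.maximum_filter(resp, size=7)
    cand = np.argwhere((resp == local_max) & (resp > np.quantile(resp, min_quantile)))
    h, w = reference.shape
    keep = (
        (cand[:, 0] >= margin)
        & (cand[:, 0] < h - margin)
        & (cand[:, 1] >= margin)
        & (cand[:, 1] < w - margin)
    )
    cand = cand[keep]
    order = np.argsort(-resp[cand[:, 0], cand[:, 1]])
    return cand[order[:n_points]]


def lk_refine(
    frame: np.ndarray,
    reference: np.ndarray,
    initial_transform: tuple[float, float, float] = (0.0, 0.0, 0.0),
    n_points: int = 150,
    window: int = 10,
    iterations: int = 4,
    outlier_factor: float = 3.0,
    fallback_residual: float = 1.0,
    min_quantile: float = 0.7,
) -> tuple[float, float, float]:
    """Refine a rigid transform by Lucas-Kanade point tracking.

    Tracking points are local-gradient maxima on the reference (low-texture
    regions excluded). Each point's displacement is solved iteratively by
    least squares on the linearized brightness-constancy equation over a
    (2*window+1)^2 patch, starting from ``initial_transform``. A rigid
    transform is then fitted to the point displacements by orthogonal
    Procrustes about the image center, with residual-based outlier
    rejection.

    Falls back to ``initial_transform`` (with a warning) when fewer than 3
    tracking points survive or the rigid fit does not explain the tracked
    displacements (e.g. a pure-noise frame).
    """
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    dx0, dy0, th0 = initial_transform
    margin = window + 3 + int(np.ceil(max(abs(dx0), abs(dy0))))
    pts = _select_points(reference, n_points, margin, min_quantile).astype(float)
    if len(pts) < 3:
        warnings.warn("lk_refine: fewer than 3 tracking points; keeping initial transform")
        return (dx0, dy0, th0)

    c = (np.array(reference.shape) - 1) / 2.0
    r0 = _rotation_matrix(th0)
    # initial displacement of each reference point under the initial transform
    disp = (pts - c) @ r0.T + c + np.array([dy0, dx0]) - pts

    yy, xx = np.mgrid[-window : window + 1, -window : window + 1]
    patch_off = np.stack([yy.ravel(), xx.ravel()])  # (2, P)
    ipts = pts.astype(int)
    # template patches and gradients from the reference (points are on pixels)
    tpl = np.stack(
        [
            reference[r - window : r + window + 1, cc - window : cc + window + 1]
            for r, cc in ipts
        ]
    )
    g = np.gradient(tpl, axis=(1, 2))
    gy = g[0].reshape(len(pts), -1)
    gx = g[1].reshape(len(pts), -1)
    a11 = np.sum(gy * gy, axis=1)
    a12 = np.sum(gy * gx, axis=1)
    a22 = np.sum(gx * gx, axis=1)
    det = a11 * a22 - a12**2
    ok = det > 1e-12
    tvec = tpl.reshape(len(pts), -1)

    for _ in range(iterations):
        coords = (
            pts[:, :, None] + disp[:, :, None] + patch_off[None, :, :]
        )  # (N, 2, P)
        samp = ndimage.map_coordinates(
            frame,
            coords.transpose(1, 0, 2).reshape(2, -1),
            order=1,
            mode="nearest",
        ).reshape(len(pts), -1)
        b = samp - tvec
        b1 = -np.sum(gy * b, axis=1)
        b2 = -np.sum(gx * b, axis=1)
        step_y = np.where(ok, (a22 * b1 - a12 * b2) / np.where(ok, det, 1.0), 0.0)
        step_x = np.where(ok, (a11 * b2 - a12 * b1) / np.where(ok, det, 1.0), 0.0)
        disp[:, 0] += step_y
        disp[:, 1] += step_x

    valid = ok & np.all(np.isfinite(disp), axis=1)
    if valid.sum() < 3:
        warnings.warn("lk_refine: tracking failed; keeping initial transform")
        return (dx0, dy0, th0)

    def _rigid_fit(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        pc_ = p - c
        qc_ = q - c
        mu_p, mu_q = pc_.mean(0), qc_.mean(0)
        h = (pc_ - mu_p).T @ (qc_ - mu_q)
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        rmat = vt.T @ np.diag([1.0, d]) @ u.T
        t = mu_q - rmat @ mu_p
        resid = np.linalg.norm(qc_ - (pc_ @ rmat.T + t), axis=1)
        theta = float(np.degrees(np.arctan2(rmat[1, 0], rmat[0, 0])))
        return t, resid, theta

    p, q = pts[valid], pts[valid] + disp[valid]
    t, resid, theta = _rigid_fit(p, q)
    thr = max(outlier_factor * np.median(resid), 0.3)
    inliers = resid <= thr
    if inliers.sum() >= 3 and inliers.sum() < len(resid):
        p, q = p[inliers], q[inliers]
        t, resid, theta = _rigid_fit(p, q)
    if np.median(resid) > fallback_residual:
        warnings.warn("lk_refine: rigid fit does not explain tracked motion; "
                      "keeping initial transform")
        return (dx0, dy0, th0)
    return (float(t[1]), float(t[0]), theta)


def register_sequence(
    stack: FrameStack,
    flag_factor: float = 3.0,
    max_flagged_fraction: float = 0.5,
    n_passes: int = 2,
    **lk_kwargs,
) -> tuple[FrameStack, MotionTrace, np.ndarray]:
    """Register a sequence to its running-mean reference.

    Each frame passes through stage-1 phase correlation and stage-2
    Lucas-Kanade refinement; the aligned frame is accumulated into the
    running mean that serves as the reference for subsequent frames. With
    ``n_passes > 1``, subsequent passes re-refine every frame against the
    sharp mean of the previous pass, which removes the drift that the
    noisy early reference can leave behind.

    Frames whose residual (mean absolute difference to the reference,
    normalized by the reference dynamic range) exceeds ``flag_factor`` times
    the median residual are flagged (blinks, saccades) and excluded from the
    mean image. More than ``max_flagged_fraction`` flagged frames raises a
    ``RuntimeError`` (unusable sequence).

    Returns the registered stack, the motion trace, and the mean image
    (pixel-wise average of unflagged registered frames, border samples
    weighted by geometric validity).
    """
    data = np.asarray(stack.data, dtype=float)
    n = stack.n_frames
    dx = np.zeros(n)
    dy = np.zeros(n)
    theta = np.zeros(n)
    residual = np.zeros(n)
    registered = np.empty_like(data)
    cover = np.empty(data.shape, dtype=bool)

    registered[0] = data[0]
    cover[0] = True
    ref = data[0].copy()
    ref_n = 1
    span = max(np.ptp(ref), 1e-9)

    for i in range(1, n):
        frame = data[i]
        if np.ptp(frame) == 0:
            # degenerate frame (e.g. full blink): keep as-is, flag later
            registered[i] = frame
            cover[i] = True
            residual[i] = np.mean(np.abs(frame - ref)) / span
            continue
        pdx, pdy = phase_correlate(frame, ref)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tdx, tdy, tth = lk_refine(frame, ref, (pdx, pdy, 0.0), **lk_kwargs)
        dx[i], dy[i], theta[i] = tdx, tdy, tth
        aligned, valid = _unwarp(frame, tdx, tdy, tth)
        registered[i] = aligned
        cover[i] = valid
        residual[i] = np.mean(np.abs(aligned[valid] - ref[valid])) / span
        # grow the reference with frames that are consistent with it
        med = np.median(residual[1 : i + 1])
        if i < 5 or residual[i] <= flag_factor * max(med, 1e-9):
            ref = (ref * ref_n + aligned) / (ref_n + 1)
            ref_n += 1
            span = max(np.ptp(ref), 1e-9)

    for _ in range(max(n_passes - 1, 0)):
        ref = registered.mean(axis=0)
        span = max(np.ptp(ref), 1e-9)
        for i in range(n):
            frame = data[i]
            if np.ptp(frame) == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tdx, tdy, tth = lk_refine(
                    frame, ref, (dx[i], dy[i], theta[i]), **lk_kwargs
                )
            dx[i], dy[i], theta[i] = tdx, tdy, tth
            aligned, valid = _unwarp(frame, tdx, tdy, tth)
            registered[i] = aligned
            cover[i] = valid
            residual[i] = np.mean(np.abs(aligned[valid] - ref[valid])) / span

    med = np.median(residual[1:])
    flagged = np.zeros(n, dtype=bool)
    flagged[1:] = residual[1:] > flag_factor * max(med, 1e-9)
    # degenerate (constant) frames are unusable regardless of residuals
    flagged |= np.array([np.ptp(f) == 0 for f in data])
    if flagged.mean() > max_flagged_fraction:
        raise RuntimeError(
            f"{flagged.sum()}/{n} frames flagged; sequence unusable"
        )

    keep = ~flagged
    weights = cover[keep].astype(float)
    wsum = weights.sum(axis=0)
    mean_image = np.where(
        wsum > 0,
        (registered[keep] * weights).sum(axis=0) / np.maximum(wsum, 1e-12),
        registered[keep].mean(axis=0),
    )
    out = FrameStack(
        registered, fps=stack.fps, provenance=stack.provenance, registered=True
    )
    trace = MotionTrace(dx=dx, dy=dy, theta=theta, residual=residual, flagged=flagged)
    return out, trace, mean_image
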
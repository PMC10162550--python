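"""Synthetic fundus videos, masks, RNFL profiles and cohorts.

The study data behind this pipeline (fundus video sequences of 111 eyes
with OCT RNFL profiles) are not publicly deposited, so every downstream
stage is exercised on synthetic scenes that reproduce the statistical
structure the analysis assumes:

* heartbeat-modulated intensity ``I(x,y,t) = I0(x,y) (1 - A(x,y) g(t))``
  plus sensor noise, where ``g`` is a raised-cosine systolic pulse and
  ``A`` the planted attenuation-amplitude map;
* rigid eye motion as a bounded random walk;
* a procedural vessel tree and a bright ONH disc on mottled tissue;
* group-wise RNFL thickness distributions matching the published cohort
  (17/21/20/53 eyes; means 90.64/91.88/72.60/61.13 um), shaped by a
  double-hump angular template;
* a planted linear coupling between annulus-mean amplitude, sector-mean
  RNFL and age, concentrated at a known annulus (d_r*, w_r*) and stronger
  temporally than nasally.

In *fast mode* the cohort generator emits analytic PAA maps directly,
skipping video rendering, which keeps full-search landscape experiments at
desk scale. Everything is deterministic given (parameters, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .masks import ONHGeometry
from .paa import PAAMap
from .patterns import RNFLProfile, rnfl_sector_mean, temporal_side
from .registration import FrameStack, rigid_warp
from .stats import GROUPS, EyeSample

__all__ = [
    "PulseShape",
    "SceneParams",
    "SceneTruth",
    "CouplingParams",
    "SyntheticCohort",
    "pulse_waveform",
    "generate_eye_video",
    "generate_cohort",
    "rnfl_angular_template",
    "GROUP_SIZES",
    "RNFL_GROUP_STATS",
    "AGE_MEAN_SD",
]

#: per-group eye counts of the reference cohort (after quality exclusion).
GROUP_SIZES = {"G_norm": 17, "G_OHT": 21, "G_pre": 20, "G_per": 53}

#: per-group mean RNFL thickness and SD in micrometers.
RNFL_GROUP_STATS = {
    "G_norm": (90.64, 7.65),
    "G_OHT": (91.88, 12.55),
    "G_pre": (72.60, 16.09),
    "G_per": (61.13, 12.20),
}

#: cohort age distribution (years).
AGE_MEAN_SD = (67.0, 11.0)


@dataclass(frozen=True)
class PulseShape:
    """Raised-cosine systolic pulse with a short flat peak.

    ``rise``, ``peak_hold`` and ``decay`` are fractions of the cardiac
    period; the remainder of the cycle is a flat diastolic baseline at
    zero. The flat systolic hold (50 ms at 72 bpm) is at least one frame
    interval at 25 fps, so the sampled waveform attains 1 exactly every
    pulse and the generative identity ``1 - I_min/I_max = A`` holds
    without interpolation error.
    """

    rise: float = 0.30
    peak_hold: float = 0.06
    decay: float = 0.45

    def __post_init__(self) -> None:
        if min(self.rise, self.peak_hold, self.decay) < 0:
            raise ValueError("pulse shape fractions must be non-negative")
        if self.rise + self.peak_hold + self.decay > 1:
            raise ValueError("rise + peak_hold + decay must not exceed 1")


def pulse_waveform(
    t: np.ndarray | float, heart_rate: float, shape: PulseShape | None = None
) -> np.ndarray:
    """Normalized pulse waveform g(t) in [0, 1].

    ``g = 1`` at maximal blood volume (the intensity trough), ``g = 0`` in
    diastole; periodic with period ``60 / heart_rate`` seconds. A
    degenerate flat shape (rise = decay = 0) returns all zeros with a
    warning.
    """
    if heart_rate <= 0:
        raise ValueError("heart rate must be positive")
    if not 40 <= heart_rate <= 180:
        raise ValueError("heart rate outside the physiological range [40, 180] bpm")
    shape = shape or PulseShape()
    t = np.asarray(t, dtype=float)
    if shape.rise == 0 and shape.decay == 0 and shape.peak_hold == 0:
        warnings.warn("flat pulse shape: waveform is identically zero")
        return np.zeros_like(t)
    period = 60.0 / heart_rate
    ph = np.mod(t, period) / period
    g = np.zeros_like(ph)
    if shape.rise > 0:
        up = ph < shape.rise
        g[up] = 0.5 * (1 - np.cos(np.pi * ph[up] / shape.rise))
    hold_end = shape.rise + shape.peak_hold
    g[(ph >= shape.rise) & (ph < hold_end)] = 1.0
    if shape.decay > 0:
        dn = (ph >= hold_end) & (ph < hold_end + shape.decay)
        g[dn] = 0.5 * (1 + np.cos(np.pi * (ph[dn] - hold_end) / shape.decay))
    return g


@dataclass
class SceneParams:
    """Parameters of one synthetic fundus video scene."""

    height: int = 384
    width: int = 384
    fps: float = 25.0
    duration: float = 10.0
    heart_rate: float = 72.0
    pulse_shape: PulseShape = field(default_factory=PulseShape)
    #: additive Gaussian sensor noise, as a fraction of the [0, 1] range
    noise_sigma: float = 0.005
    #: bounded random-walk eye motion; 0 disables motion
    motion_max_shift: float = 4.0
    motion_max_rot: float = 0.25
    motion_step: float = 0.6
    motion_rot_step: float = 0.05
    #: explicit planted amplitude map (overrides amplitude_range and the
    #: vessel amplitude boost)
    amplitude_map: np.ndarray | None = None
    amplitude_range: tuple[float, float] = (0.01, 0.05)
    vessel_amplitude_boost: float = 0.05
    onh_radius: float | None = None
    tissue_brightness: float = 0.80
    onh_brightness: float = 0.92
    vessel_contrast: float = 0.55
    n_vessels: int = 7


@dataclass
class SceneTruth:
    """Ground truth for one generated video."""

    amplitude_map: np.ndarray
    baseline_image: np.ndarray
    vessel_mask: np.ndarray
    onh_mask: np.ndarray
    motion: np.ndarray  # (T, 3): dx, dy, theta
    pulse_windows: list[tuple[int, int]]
    heart_rate: float
    fps: float


def _vessel_tree(
    shape: tuple[int, int],
    center: tuple[float, float],
    rng: np.random.Generator,
    n_vessels: int,
    start_radius: float,
) -> np.ndarray:
    """Procedural radial vessel tree: sinuous paths stamped with discs."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    max_len = int(0.7 * max(h, w))
    for k in range(n_vessels):
        ang = 2 * np.pi * (k + rng.uniform(-0.25, 0.25)) / n_vessels
        pos = np.array(
            [center[0] + start_radius * np.sin(ang),
             center[1] + start_radius * np.cos(ang)]
        )
        width = rng.uniform(2.5, 5.5)
        for step in range(max_len):
            ang += rng.normal(0, 0.06)
            pos += np.array([np.sin(ang), np.cos(ang)])
            if not (0 <= pos[0] < h and 0 <= pos[1] < w):
                break
            rad = max(width * (1 - 0.6 * step / max_len), 1.0)
            rr = int(np.ceil(rad))
            r0, r1 = int(pos[0]) - rr, int(pos[0]) + rr + 1
            c0, c1 = int(pos[1]) - rr, int(pos[1]) + rr + 1
            r0c, c0c = max(r0, 0), max(c0, 0)
            yy, xx = np.mgrid[r0c : min(r1, h), c0c : min(c1, w)]
            mask[yy, xx] |= (yy - pos[0]) ** 2 + (xx - pos[1]) ** 2 <= rad**2
    return mask


def _smooth_field(
    shape: tuple[int, int], rng: np.random.Generator, scale_px: float
) -> np.ndarray:
    """Zero-mean smooth random field, unit peak-to-peak scale."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), scale_px)
    span = np.ptp(f)
    return (f - f.mean()) / (span if span > 0 else 1.0)


def _render_scene(
    params: SceneParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, ONHGeometry]:
    """Baseline image, amplitude map, vessel and ONH masks for one eye."""
    h, w = params.height, params.width
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    r_onh = params.onh_radius or 0.16 * min(h, w)
    rows, cols = np.mgrid[0:h, 0:w]
    rho = np.hypot(rows - center[0], cols - center[1])
    onh_mask = rho <= r_onh

    vessel_mask = _vessel_tree((h, w), center, rng, params.n_vessels,
                               start_radius=0.3 * r_onh)
    v_soft = ndimage.gaussian_filter(vessel_mask.astype(float), 0.8)

    mottle = _smooth_field((h, w), rng, scale_px=h / 10)
    baseline = params.tissue_brightness * (1 + 0.08 * mottle)
    onh_soft = ndimage.gaussian_filter(onh_mask.astype(float), 3.0)
    baseline += (params.onh_brightness - params.tissue_brightness) * onh_soft
    baseline *= 1 - (1 - params.vessel_contrast) * np.clip(v_soft, 0, 1)
    baseline = np.clip(baseline, 0.05, 0.98)

    if params.amplitude_map is not None:
        amp = np.asarray(params.amplitude_map, dtype=float)
        if amp.shape != (h, w):
            raise ValueError("amplitude_map shape does not match the scene")
    else:
        lo, hi = params.amplitude_range
        amp = lo + (hi - lo) * (0.5 + _smooth_field((h, w), rng, h / 6))
        amp = np.clip(amp, min(lo, hi), max(lo, hi))
        amp = amp + params.vessel_amplitude_boost * np.clip(v_soft, 0, 1)
    if np.any(amp < 0):
        raise ValueError("amplitude map must be non-negative")

    geom = ONHGeometry(center=center, radius=r_onh, source="synthetic")
    return baseline, amp, vessel_mask, onh_mask, geom


def _motion_walk(
    n_frames: int, params: SceneParams, rng: np.random.Generator
) -> np.ndarray:
    """Bounded rigid random walk (dx, dy, theta), identity at frame 0."""
    motion = np.zeros((n_frames, 3))
    if params.motion_max_shift <= 0 and params.motion_max_rot <= 0:
        return motion
    limits = np.array(
        [params.motion_max_shift, params.motion_max_shift, params.motion_max_rot]
    )
    steps = np.array([params.motion_step, params.motion_step, params.motion_rot_step])
    state = np.zeros(3)
    for i in range(1, n_frames):
        state = state + rng.normal(0, steps)
        # reflect at the bounds to keep the walk inside +-limits
        for j in range(3):
            if limits[j] > 0:
                state[j] = np.clip(state[j], -limits[j], limits[j])
            else:
                state[j] = 0.0
        motion[i] = state
    return motion


def true_pulse_windows(
    n_frames: int, fps: float, heart_rate: float, shape: PulseShape | None = None
) -> list[tuple[int, int]]:
    """Intensity-trough-to-trough frame intervals of the planted pulse."""
    shape = shape or PulseShape()
    period = 60.0 / heart_rate
    trough_times = []
    i = 0
    while True:
        tt = (i + shape.rise + shape.peak_hold / 2.0) * period
        f = int(round(tt * fps))
        if f >= n_frames:
            break
        trough_times.append(f)
        i += 1
    return [(s, e) for s, e in zip(trough_times[:-1], trough_times[1:])]


def generate_eye_video(
    scene_params: SceneParams | None = None, seed: int = 0
) -> tuple[FrameStack, SceneTruth]:
    """Render one heartbeat-modulated, noise- and motion-corrupted video.

    ``I(x, y, t) = warp(I0 (1 - A g(t)), motion_t) + N(0, sigma)``; the
    same (params, seed) pair yields a bit-identical stack.
    """
    params = scene_params or SceneParams()
    if params.height < 128 or params.width < 128:
        raise ValueError("scene must be at least 128 x 128 pixels")
    rng = np.random.default_rng(seed)
    baseline, amp, vessel_mask, onh_mask, _ = _render_scene(params, rng)

    n_frames = int(round(params.duration * params.fps))
    times = np.arange(n_frames) / params.fps
    g = pulse_waveform(times, params.heart_rate, params.pulse_shape)
    if np.max(amp) * np.max(g, initial=0.0) >= 1.0:
        raise ValueError("amplitude would drive intensity non-positive")

    motion = _motion_walk(n_frames, params, rng)
    frames = np.empty((n_frames, params.height, params.width), dtype=float)
    moving = np.any(motion != 0)
    for i in range(n_frames):
        img = baseline * (1.0 - amp * g[i])
        if moving and np.any(motion[i] != 0):
            img = rigid_warp(img, *motion[i])
        frames[i] = img
    if params.noise_sigma > 0:
        frames += rng.normal(0, params.noise_sigma, frames.shape)
    frames = np.clip(frames, 0.0, None)

    stack = FrameStack(
        frames, fps=params.fps, provenance=f"synthetic(seed={seed})"
    )
    truth = SceneTruth(
        amplitude_map=amp,
        baseline_image=baseline,
        vessel_mask=vessel_mask,
        onh_mask=onh_mask,
        motion=motion,
        pulse_windows=true_pulse_windows(
            n_frames, params.fps, params.heart_rate, params.pulse_shape
        ),
        heart_rate=params.heart_rate,
        fps=params.fps,
    )
    return stack, truth


def rnfl_angular_template(angles_deg: np.ndarray) -> np.ndarray:
    """Double-hump RNFL angular profile, normalized to mean 1.

    Superior and inferior maxima, an intermediate temporal shoulder (the
    papillomacular bundle) and the nasal minimum; angles follow the
    profile convention (0 deg temporal, counter-clockwise for OD).
    """
    th = np.deg2rad(np.asarray(angles_deg, dtype=float))

    def vm(mu_deg, kappa):
        return np.exp(kappa * (np.cos(th - np.deg2rad(mu_deg)) - 1.0))

    t = 0.62 + 0.55 * (vm(85.0, 3.0) + vm(275.0, 3.0)) + 0.18 * vm(0.0, 2.0)
    return t / t.mean()


@dataclass(frozen=True)
class CouplingParams:
    """Linear link between planted annulus amplitude, RNFL and age.

    The planted amplitude bump at the target annulus carries, per eye,
    ``c_sector = alpha_sector * z(RNFL_sector) + beta_age * z(age) + eps``
    (PAA units); the temporal slope exceeds the nasal slope, mirroring the
    anatomically denser temporal fiber bundle.
    """

    alpha_temporal: float = 0.004
    alpha_nasal: float = 0.0016
    beta_age: float = -0.002
    noise_sd: float = 0.004
    base_amplitude: float = 0.03
    #: per-eye baseline perfusion offset (uncorrelated with RNFL/age);
    #: spreads over the whole map, so diluting the planted annulus signal
    #: with off-annulus area genuinely lowers the correlation there
    background_sd: float = 0.004
    map_noise_sd: float = 0.001

    def __post_init__(self) -> None:
        if self.alpha_nasal > self.alpha_temporal:
            raise ValueError("temporal coupling must be >= nasal coupling")


@dataclass
class SyntheticCohort:
    """Generated cohort: tabular records plus per-eye analysis inputs."""

    records: pd.DataFrame
    eyes: list[EyeSample]
    truth: dict
    scene_truths: list[SceneTruth] | None = None
    videos: list[FrameStack] | None = None


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = np.std(v)
    return (v - np.mean(v)) / sd if sd > 1e-12 else np.zeros_like(v)


def generate_cohort(
    seed: int = 0,
    group_sizes: dict[str, int] | None = None,
    n_eyes: int | None = None,
    coupling: CouplingParams | None = None,
    planted_d_r: float = 0.5,
    planted_w_r: float = 0.05,
    fast: bool = True,
    make_maps: bool = True,
    map_shape: tuple[int, int] = (256, 256),
    onh_radius_mean: float | None = None,
    onh_radius_sd: float | None = None,
    n_angles: int = 256,
    rnfl_noise_sd: float = 4.0,
    scene_params: SceneParams | None = None,
    temporal_left_for_od: bool = True,
) -> SyntheticCohort:
    """Generate a cohort with a planted PAA-RNFL coupling.

    Defaults reproduce the reference cohort structure: group sizes
    17/21/20/53 (111 eyes), age ~ N(67, 11), group RNFL means/SDs as
    published, and a coupling concentrated at the annulus
    (``planted_d_r``, ``planted_w_r``) that is stronger temporally than
    nasally.

    In fast mode (default) each eye gets an analytic PAA map; with
    ``fast=False`` full videos are rendered from ``scene_params`` (slow -
    intended for small smoke cohorts). ``make_maps=False`` skips image
    synthesis entirely and returns records only (useful for cohort-moment
    checks at large n).
    """
    group_sizes = dict(group_sizes or GROUP_SIZES)
    unknown = set(group_sizes) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    total = sum(group_sizes.values())
    if n_eyes is not None and n_eyes != total:
        raise ValueError(
            f"n_eyes={n_eyes} inconsistent with group sizes (sum {total})"
        )
    if total < 8:
        raise ValueError("cohort needs at least 8 eyes")
    coupling = coupling or CouplingParams()
    if onh_radius_mean is None:
        # same ONH-to-image proportion as the rendered video scenes
        onh_radius_mean = 0.164 * min(map_shape)
    if onh_radius_sd is None:
        onh_radius_sd = 0.095 * onh_radius_mean
    rng = np.random.default_rng(seed)

    groups = [g for g in GROUPS if g in group_sizes for _ in range(group_sizes[g])]
    ages = np.clip(rng.normal(*AGE_MEAN_SD, size=total), 40.0, 92.0)
    lateralities = rng.choice(["OD", "OS"], size=total)
    angles = np.arange(n_angles) * (360.0 / n_angles)
    template = rnfl_angular_template(angles)

    profiles: list[RNFLProfile] = []
    for i, g in enumerate(groups):
        mu, sd = RNFL_GROUP_STATS[g]
        m = max(rng.normal(mu, sd), 20.0)
        wiggle = ndimage.gaussian_filter1d(
            rng.normal(0, rnfl_noise_sd, n_angles), 6.0, mode="wrap"
        )
        thickness = np.clip(m * template + wiggle, 5.0, None)
        profiles.append(RNFLProfile(angles_deg=angles, thickness_um=thickness))

    rnfl_full = np.array([p.thickness_um.mean() for p in profiles])
    rnfl_temp = np.array([rnfl_sector_mean(p, "temporal") for p in profiles])
    rnfl_nasal = np.array([rnfl_sector_mean(p, "nasal") for p in profiles])
    eps = rng.normal(0, coupling.noise_sd, total) if coupling.noise_sd > 0 else np.zeros(total)
    z_age = _zscore(ages)
    c_temp = coupling.alpha_temporal * _zscore(rnfl_temp) + coupling.beta_age * z_age + eps
    c_nasal = coupling.alpha_nasal * _zscore(rnfl_nasal) + coupling.beta_age * z_age + eps
    background = (
        rng.normal(0, coupling.background_sd, total)
        if coupling.background_sd > 0
        else np.zeros(total)
    )

    eyes: list[EyeSample] = []
    scene_truths: list[SceneTruth] | None = None
    videos: list[FrameStack] | None = None
    rows = []
    if make_maps and fast:
        for i in range(total):
            eyes.append(
                _analytic_eye(
                    f"eye_{i:03d}", rng, map_shape, onh_radius_mean, onh_radius_sd,
                    coupling, planted_d_r, planted_w_r, c_temp[i], c_nasal[i],
                    background[i], profiles[i], ages[i], lateralities[i],
                    groups[i], temporal_left_for_od,
                )
            )
    elif make_maps:
        scene_truths, videos = [], []
        base = scene_params or SceneParams()
        for i in range(total):
            params = _video_eye_params(
                base, rng, coupling, planted_d_r, planted_w_r,
                c_temp[i], c_nasal[i], background[i],
                lateralities[i], temporal_left_for_od,
            )
            stack, truth = generate_eye_video(params, seed=int(rng.integers(2**31)))
            videos.append(stack)
            scene_truths.append(truth)
            eyes.append(
                EyeSample(
                    eye_id=f"eye_{i:03d}", paa_map=None,  # filled by the pipeline
                    geometry=ONHGeometry(
                        center=((params.height - 1) / 2, (params.width - 1) / 2),
                        radius=params.onh_radius or 0.16 * min(params.height, params.width),
                        source="synthetic",
                    ),
                    rnfl_profile=profiles[i], age=float(ages[i]),
                    laterality=str(lateralities[i]),
                    vessel_mask=truth.vessel_mask, onh_mask=truth.onh_mask,
                    group=groups[i],
                )
            )

    for i in range(total):
        rows.append(
            {
                "eye_id": f"eye_{i:03d}",
                "age": float(ages[i]),
                "laterality": str(lateralities[i]),
                "group": groups[i],
                "rnfl_mean": float(rnfl_full[i]),
                "rnfl_temp": float(rnfl_temp[i]),
                "rnfl_nasal": float(rnfl_nasal[i]),
            }
        )
    records = pd.DataFrame(rows)
    truth = {
        "planted_d_r": planted_d_r,
        "planted_w_r": planted_w_r,
        "coupling": coupling,
        "c_temporal": c_temp,
        "c_nasal": c_nasal,
        "seed": seed,
    }
    return SyntheticCohort(
        records=records, eyes=eyes, truth=truth,
        scene_truths=scene_truths, videos=videos,
    )


def _planted_bump(rho_rel: np.ndarray, d_r: float, w_r: float) -> np.ndarray:
    """Raised-cosine radial bump of support ``w_r`` centered at ``d_r``."""
    if w_r <= 0:
        return np.zeros_like(rho_rel)
    x = (rho_rel - d_r) / w_r
    return np.where(np.abs(x) <= 0.5, 0.5 * (1 + np.cos(2 * np.pi * x)), 0.0)


def _analytic_eye(
    eye_id, rng, map_shape, r_mean, r_sd, coupling, d_r, w_r,
    c_temp, c_nasal, background, profile, age, laterality, group,
    temporal_left_for_od,
) -> EyeSample:
    """One fast-mode eye: analytic PAA map with the planted coupling."""
    h, w = map_shape
    center = (
        (h - 1) / 2.0 + rng.uniform(-4, 4),
        (w - 1) / 2.0 + rng.uniform(-4, 4),
    )
    radius = float(np.clip(rng.normal(r_mean, r_sd), 0.75 * r_mean, 1.25 * r_mean))
    rows, cols = np.mgrid[0:h, 0:w]
    rho_rel = np.hypot(rows - center[0], cols - center[1]) / radius
    bump = _planted_bump(rho_rel, d_r, w_r)
    temp_side = temporal_side(cols, center[1], laterality, temporal_left_for_od)
    amp = (coupling.base_amplitude + background
           + bump * np.where(temp_side, c_temp, c_nasal))
    if coupling.map_noise_sd > 0:
        amp = amp + rng.normal(0, coupling.map_noise_sd, (h, w))
    amp = np.clip(amp, 1e-4, 0.2)

    vessel_mask = _vessel_tree((h, w), center, rng, n_vessels=7,
                               start_radius=0.3 * radius)
    data = amp.copy()
    data[vessel_mask] += 0.08  # large-vessel pulsation: excluded via the mask
    onh_mask = rho_rel <= 1.0
    return EyeSample(
        eye_id=eye_id,
        paa_map=PAAMap(data=data, n_pulses=5),
        geometry=ONHGeometry(center=center, radius=radius, source="synthetic"),
        rnfl_profile=profile,
        age=float(age),
        laterality=str(laterality),
        vessel_mask=vessel_mask,
        onh_mask=onh_mask,
        group=group,
    )


def _video_eye_params(
    base: SceneParams, rng, coupling, d_r, w_r, c_temp, c_nasal,
    background, laterality, temporal_left_for_od,
) -> SceneParams:
    """Scene parameters with the planted coupling rendered into A(x, y)."""
    h, w = base.height, base.width
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    radius = base.onh_radius or 0.16 * min(h, w)
    rows, cols = np.mgrid[0:h, 0:w]
    rho_rel = np.hypot(rows - center[0], cols - center[1]) / radius
    bump = _planted_bump(rho_rel, d_r, w_r)
    temp_side = temporal_side(cols, center[1], laterality, temporal_left_for_od)
    amp = (coupling.base_amplitude + background
           + bump * np.where(temp_side, c_temp, c_nasal))
    amp = np.clip(amp, 1e-4, 0.2)
    return replace(base, amplitude_map=amp, onh_radius=radius)
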
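"""Pulsatile attenuation amplitude (PAA) maps.

During each cardiac cycle the retinal blood volume rises and falls, which
modulates the light attenuation of the tissue: image intensity is lowest at
peak blood volume. The per-pixel amplitude over one heartbeat is

    PAA = A_max = 1 - I_min / I_max,

with I_min and I_max the minimum and maximum pixel intensity during the
cycle. A spatial PAA(x, y) map is obtained per pulse and averaged across
the k best pulses (default 5).

Pulse windows are detected on a global region-of-interest signal (spatial
mean intensity per frame), band-passed to the cardiac band, and the same
windows are applied to every pixel; windows that overlap flagged frames
(blinks, saccades) are discarded. Per-pixel signals are smoothed with a
short centered moving average before taking extrema, which suppresses the
upward noise bias of raw min/max estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .registration import FrameStack

__all__ = [
    "PulseWindow",
    "PAAMap",
    "global_pulse_signal",
    "detect_pulses",
    "paa_single_pulse",
    "paa_map",
]

#: default centered moving-average width (frames) for per-pixel smoothing;
#: 0.28 s at 25 fps (about a third of a cardiac period at 72 bpm), chosen
#: to balance the upward extreme-value bias of noisy min/max against
#: attenuation of the true pulse extrema.
DEFAULT_SMOOTH_WINDOW = 7

#: intensities at or below this fraction of the nominal [0, 1] dynamic
#: range are treated as invalid (dark/saturated pixels).
INTENSITY_EPS = 0.01


@dataclass
class PulseWindow:
    """Half-open frame interval [start, end) covering one heartbeat."""

    start: int
    end: int
    quality: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("PulseWindow requires 0 <= start < end")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class PAAMap:
    """H x W map of averaged per-pulse amplitudes.

    Invalid pixels (vessels, border, dark/saturated) are NaN, never 0;
    ``n_pulses`` is the number of averaged heartbeat maps.
    """

    data: np.ndarray
    n_pulses: int = 1

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.data)


def global_pulse_signal(stack: FrameStack, roi: np.ndarray) -> np.ndarray:
    """Spatial mean intensity over ``roi`` per frame, linearly detrended."""
    roi = np.asarray(roi) > 0
    if not roi.any():
        raise ValueError("ROI is empty")
    if stack.n_frames < 2:
        raise ValueError("need at least 2 frames")
    series = stack.data[:, roi].mean(axis=1)
    return sps.detrend(series, type="linear")


def _dominant_frequency(x: np.ndarray, fps: float, band: tuple[float, float]) -> float:
    """Dominant in-band frequency; raises when no clear cardiac peak exists."""
    freqs, power = sps.periodogram(x - x.mean(), fs=fps)
    inband = (freqs >= band[0]) & (freqs <= band[1])
    if not inband.any() or np.ptp(x) == 0:
        raise ValueError("no cardiac signal: spectrum has no in-band content")
    ref = np.median(power[freqs > 0])
    peak = power[inband].max()
    if ref <= 0 or peak < 20 * ref:
        raise ValueError("no cardiac signal: no dominant spectral peak in band")
    return float(freqs[inband][np.argmax(power[inband])])


def detect_pulses(
    signal: np.ndarray,
    fps: float,
    flagged: np.ndarray | None = None,
    band: tuple[float, float] = (0.7, 3.0),
) -> list[PulseWindow]:
    """Trough-to-trough pulse windows from the global pulse signal.

    The signal is band-passed to the cardiac band and intensity troughs
    (peak blood volume) are located with peak detection, then refined on
    the lightly smoothed raw signal. Window quality scores amplitude
    consistency (peak-to-peak excursion vs. the median pulse). Windows that
    overlap frames marked in ``flagged`` are discarded, mirroring the use
    of undistorted pulses only.
    """
    signal = np.asarray(signal, dtype=float)
    n = len(signal)
    if n < 2 * fps:
        raise ValueError("signal shorter than two seconds")
    f0 = _dominant_frequency(signal, fps, band)

    high = min(band[1], 0.45 * fps)
    sos = sps.butter(3, [band[0], high], btype="bandpass", fs=fps, output="sos")
    filt = sps.sosfiltfilt(sos, signal - signal.mean())
    distance = max(int(0.6 * fps / f0), 2)
    troughs, _ = sps.find_peaks(-filt, distance=distance)
    if len(troughs) < 2:
        raise ValueError("no cardiac signal: fewer than two pulse troughs")

    # refine trough locations on the lightly smoothed raw signal
    smooth = uniform_filter1d(signal, 3, mode="nearest")
    refined = []
    for t in troughs:
        lo, hi = max(t - 3, 0), min(t + 4, n)
        refined.append(lo + int(np.argmin(smooth[lo:hi])))
    troughs = np.unique(refined)

    lengths = np.diff(troughs)
    med_len = np.median(lengths)
    windows: list[PulseWindow] = []
    ptps = [np.ptp(filt[s:e]) for s, e in zip(troughs[:-1], troughs[1:])]
    med_ptp = max(np.median(ptps), 1e-12)
    for (s, e), ptp in zip(zip(troughs[:-1], troughs[1:]), ptps):
        if not 0.5 * med_len <= (e - s) <= 1.5 * med_len:
            continue
        if flagged is not None and np.asarray(flagged)[s:e].any():
            continue
        quality = 1.0 / (1.0 + abs(ptp - med_ptp) / med_ptp)
        windows.append(PulseWindow(int(s), int(e), float(quality)))
    if not windows:
        raise ValueError("no usable pulse windows found")
    return windows


def _smoothed_slice(
    data: np.ndarray, window: PulseWindow, smooth_window: int
) -> np.ndarray:
    """Temporally smoothed samples inside the window (with edge margin)."""
    if smooth_window and smooth_window > 1:
        margin = smooth_window // 2
        lo = max(window.start - margin, 0)
        hi = min(window.end + margin, data.shape[0])
        sm = uniform_filter1d(
            data[lo:hi].astype(float), smooth_window, axis=0, mode="nearest"
        )
        return sm[window.start - lo : window.end - lo]
    return data[window.start : window.end].astype(float)


def paa_single_pulse(
    stack: FrameStack,
    window: PulseWindow,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    eps: float = INTENSITY_EPS,
) -> np.ndarray:
    """Per-pixel ``1 - I_min / I_max`` over one pulse window.

    Extrema are taken over the temporally smoothed samples inside the
    window (``smooth_window`` frames; <=1 disables smoothing, giving raw
    min/max). Pixels whose I_max does not exceed ``eps`` or whose I_min is
    non-positive are marked invalid (NaN).
    """
    if len(window) < 3:
        raise ValueError("pulse window shorter than 3 frames")
    if window.end > stack.n_frames:
        raise ValueError("pulse window exceeds stack length")
    seg = _smoothed_slice(stack.data, window, smooth_window)
    imin = seg.min(axis=0)
    imax = seg.max(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        amp = 1.0 - imin / imax
    amp[(imax <= eps) | (imin <= 0)] = np.nan
    return amp


def paa_map(
    stack: FrameStack,
    windows: list[PulseWindow],
    k: int = 5,
    vessel_mask: np.ndarray | None = None,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    eps: float = INTENSITY_EPS,
) -> PAAMap:
    """Average the single-pulse maps of the ``k`` highest-quality windows.

    Vessel pixels (and pixels invalid in any selected pulse) are marked
    invalid. Raises ``ValueError`` when fewer than ``k`` windows are
    available.
    """
    if len(windows) < k:
        raise ValueError(
            f"need {k} pulse windows, found only {len(windows)}"
        )
    chosen = sorted(windows, key=lambda w: (-w.quality, w.start))[:k]
    maps = [
        paa_single_pulse(stack, w, smooth_window=smooth_window, eps=eps)
        for w in chosen
    ]
    data = np.mean(maps, axis=0)
    if vessel_mask is not None:
        data = data.copy()
        data[np.asarray(vessel_mask) > 0] = np.nan
    return PAAMap(data=data, n_pulses=k)
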
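# Methods

This note documents the models, estimators and numerical choices behind
`retppg`, and what the synthetic-data experiments do and do not establish.

## Signal model

A video ophthalmoscope records intensity `I(x, y, t)` of the retina at a
wavelength strongly absorbed by blood. With baseline reflectance
`I0(x, y)`, attenuation amplitude `A(x, y)` and a normalized cardiac
waveform `g(t) ∈ [0, 1]` (1 at peak blood volume):

```
I(x, y, t) = I0(x, y) · (1 − A(x, y) · g(t))  [+ motion, + noise]
```

The pulsatile attenuation amplitude is recovered per pixel and per
heartbeat as `PAA = 1 − I_min / I_max`, which equals `A` exactly when the
waveform attains 0 and 1 within the analyzed window and noise is absent.
PAA is a ratio, hence invariant to global intensity rescaling; valid
values lie in `[0, 1)`.

## Registration

Two rigid stages per frame against a running-mean reference (initialized
at frame 0): phase correlation (normalized cross-power spectrum, subpixel
via upsampled local cross-correlation) for translation, then Lucas–Kanade
tracking for the residual translation and rotation. Tracking points are
local gradient-magnitude maxima above the 0.7 texture quantile; each
point's displacement is solved iteratively from the linearized
brightness-constancy equation over a 21×21 patch, and a rigid transform is
fitted by orthogonal Procrustes with residual-based outlier rejection
(threshold 3× median, floor 0.3 px). A second pass re-refines all frames
against the sharp first-pass mean; this removes the drift left by the
noisy early reference and roughly halves the recovery error. Frames whose
normalized residual exceeds 3× the median (and all constant frames) are
flagged and excluded from the mean image; a sequence with more than half
its frames flagged is rejected as unusable. Rotation is deliberately left
to the second stage: phase correlation handles translation only.

On synthetic 256×256 sequences with a planted bounded random walk
(≤ 8 px, ≤ 1°) and 0.5 % sensor noise, the recovered trace RMSE is
≈ 0.03–0.35 px and ≤ 0.08° (acceptance bound: 0.5 px, 0.1°).

## Vessel segmentation and ONH geometry

Vessels are detected with a bank of zero-mean Gaussian-profile line
kernels (FWHM widths 2/4/6/8 px, 12 orientations over 180°, L2-normalized,
dark-line-positive sign convention), taking the per-pixel maximum
response. Thresholding is hysteresis on a robust z-score of the response
(`median + k · 1.4826 · MAD`, defaults high k = 100, low k = 80), followed
by removal of objects under 30 px and a 2 px safety dilation, since the
mask's only downstream role is *exclusion* of vessel-contaminated pixels.
The default thresholds were calibrated once against the synthetic scenes'
ground-truth vessel masks (Dice 0.78–0.88 before dilation); they are
config-exposed and must be re-tuned for other imagery. A replaced
classifier stage is out of scope: only the mask's exclusion role matters
here. One caveat on the sign convention: the "bright vessel ⇒ non-positive
response" identity holds exactly for the orientation-matched kernel;
oblique rasterized kernels can leave residues of a few percent of the
vessel response where a ridge crosses the kernel support corners.

The ONH enters as a manually drawn (or synthetic) disc mask; its centroid
after morphological filling is the pattern origin, and the equivalent-area
radius `r = sqrt(area/π)` is the unit of the relative coordinates. Multiple
large components or an empty mask are errors, not guesses.

## Pulse windows and the PAA estimator

The global pulse signal is the spatial mean intensity per frame, linearly
detrended. A cardiac peak is required in the 0.7–3.0 Hz band (peak
periodogram power ≥ 20× the median spectral power; otherwise the sequence
has no usable pulse). The band-passed signal's troughs (zero-phase
Butterworth order 3, peak detection with a rate-adaptive minimum distance,
trough refinement on the lightly smoothed raw signal) delimit
trough-to-trough windows. Window quality scores amplitude consistency
against the median pulse; windows overlapping flagged frames are dropped.
The final map averages the per-pulse maps of the k = 5 highest-quality
windows (an explicit window list can be supplied instead, e.g. for
manually curated pulses).

Per pixel, `I_min`/`I_max` are extrema of the temporally smoothed samples
inside the window (centered moving average). The smoothing width trades
two biases: raw extrema of noisy samples are biased outward (extreme-value
selection), while wide smoothing attenuates the true pulse extrema. On
the default synthetic conditions (0.5 % noise, baseline ≈ 0.8, 72 bpm at
25 fps) the mean absolute relative error of the recovered amplitude over
planted A ∈ [0.01, 0.05] is U-shaped in the window: ≈ 26 % (3 frames),
11 % (5), **6 % (7)**, 14 % (9); the default is therefore 7 frames
(0.28 s). Smoothing is config-exposed and `smooth_window=0` gives the raw
estimator, which reproduces a noiseless planted amplitude to machine
precision. Pixels with `I_max` below 1 % of the dynamic range or
non-positive `I_min` are invalid (NaN, never 0), as are vessel pixels.

## Patterns and the correlation landscape

An evaluating pattern is an annulus of mid-line radius `d_r · r` and width
`max(w_r · r, 1 px)` around the ONH center — the 1 px floor reflects that
a rasterized ring is never thinner than one pixel. Sectors cut the annulus
at the vertical line through the center; the temporal side is image-left
for OD and image-right for OS by default (config-exposed: devices differ,
and the convention must be verified against any real dataset). Dividing-
line pixels tie-break to temporal, so temporal ∪ nasal partitions the
annulus exactly. RNFL profiles use 0° at the temporal horizontal,
counter-clockwise for OD (an eye-relative convention, so sector means are
laterality-independent); boundary samples at ±90° likewise tie to
temporal.

For each grid cell (d_r step 0.01 over [0, 1.5]; w_r step 0.004 over
[0, 0.25]) and each eye, the annulus is scaled to that eye's own ONH
radius, vessel and invalid pixels are excluded, and the pattern-mean PAA
is paired with the angularly corresponding RNFL sector mean. The
age-controlled partial correlation across eyes fills the landscape; eyes
with no valid pixel in a cell are dropped per cell (n is reported), and
cells with fewer than 4 eyes are NaN. The optimum is the argmax (ties
break to smaller d_r, then smaller w_r) and the ≥ 95 %-of-maximum region
is reported with it. For speed, per-eye pattern means over the ~9.5k cells
are computed from prefix sums over radially sorted valid pixels — exactly
the same membership predicate as the rasterized masks, so the two paths
agree to summation order. **No multiplicity correction is applied across
cells; the maximal R is selection-inflated**, and every pipeline report
repeats this caveat. p-values use the t reference with n − 3 degrees of
freedom.

## Synthetic data: what it emulates, and what it does not

The generator exists because the study cohort (fundus videos + OCT RNFL
profiles of 111 eyes) is not publicly deposited. It emulates the
*statistical structure* the analysis relies on:

* the multiplicative heartbeat modulation above, with an asymmetric
  raised-cosine systolic pulse (rise 0.30, flat peak 0.06, decay 0.45 of
  the period; default 72 bpm — the instrument's heart rates and SNR are
  unpublished, so these are plausible placeholders). The flat systolic
  peak spans at least one frame interval at 25 fps, so the sampled
  waveform attains its extrema exactly and the generative identity is
  testable to machine precision at finite frame rate;
* additive Gaussian sensor noise, σ = 0.5 % of the dynamic range;
* rigid eye motion as a bounded, reflected random walk (default ≤ 4 px,
  ≤ 0.25°; configurable up to blink-scale excursions);
* a procedural radial vessel tree (dark, sinuous, tapering) and a bright
  ONH disc on low-frequency mottled tissue (~0.8 baseline reflectance);
* cohort structure matching the published groups: sizes 17/21/20/53
  (G_norm/G_OHT/G_pre/G_per), RNFL means ± SD 90.64±7.65 / 91.88±12.55 /
  72.60±16.09 / 61.13±12.20 µm, age 67 ± 11 years. Angular RNFL profiles
  follow a double-hump template (superior/inferior maxima, temporal
  shoulder, nasal minimum) scaled per eye;
* a planted coupling at a known annulus (default d_r* = 0.5, w_r* = 0.05,
  raised-cosine radial bump): per eye, the bump amplitude is
  `α_sector · z(RNFL_sector) + β · z(age) + ε`, with temporal slope
  α_t = 0.004 > nasal α_n = 0.0016 (PAA units per SD), β = −0.002,
  σ_ε = 0.004, plus a per-eye background amplitude offset (σ = 0.004)
  uncorrelated with RNFL. The background term matters: without it, any
  annulus touching the bump correlates equally and the optimum is
  unidentifiable; with it, diluting the planted signal with off-annulus
  area genuinely costs correlation, as baseline perfusion differences do
  in real eyes. These defaults put the maximal temporal R near 0.5–0.65
  at n = 111, the regime the method is meant for.

Fast mode emits analytic PAA maps directly (256² by default, ONH radius
≈ 0.164 × image size), skipping video rendering; video mode renders full
sequences through the same planted amplitude fields.

What passing tests on this generator *show*: the estimators recover their
own generative model (identity, registration, pulse timing), the search
machinery localizes a planted coupling at n = 111 under realistic noise,
and the temporal > nasal ordering survives sampling variability. What
they *do not show*: performance under real optical blur, non-rigid
distortion, illumination drift, vessel pulsation spill-over, OCT
segmentation error, or any clinical effect size — the clinical R values
cannot be validated without the original data.

## Numerical choices and degenerate inputs

* Relative→absolute conversion rounds half away from zero to one decimal
  (`0.55 × 171 → 94.1 px`).
* Warping uses bilinear interpolation; border samples replicate the edge
  and are excluded from mean images by geometric validity weights.
* A control variable with zero variance degrades the partial correlation
  to plain Pearson (with a warning); a control collinear with either
  variable yields R = 0 by the residual-limit convention; zero variance in
  x or y is an error.
* Degenerate pattern/pixel cases (empty ROI, fully vessel-covered
  pattern, dark pixels, constant frames, flat pulse shape) return NaN
  with diagnostics or raise, never silently return 0.
* All stochastic steps take explicit seeds; reruns of a pipeline config
  are byte-identical, and the run manifest records the seed, parameters
  and a SHA-256 hash of every artifact.

## Problem sizes used in the test suite

Unit and acceptance tests run at deliberately modest scales chosen to
exercise every contract while keeping the suite quick to iterate on:
128–256 px frames, 10 s videos at 25 fps, 111-eye fast-mode cohorts for
landscape experiments (10 seeds), and 8-eye rendered-video cohorts for
end-to-end file-based runs. All scale parameters are plain function
arguments, so larger experiments need no code changes.

## Known limitations

* Rigid-only registration; torsional or elastic retinal motion is out of
  scope.
* The vessel segmenter is threshold-based and calibrated to the synthetic
  contrast regime; it is not a learned segmenter and will need retuning
  (or replacement behind the same interface) for clinical imagery.
* Pulse timing is sequence-global; per-pixel pulse-transit differences
  are ignored.
* The temporal/nasal image-side convention is an assumption to be checked
  per device.
* The landscape maximum is reported without multiplicity correction,
  matching the analysis it implements; treat R_max as an in-sample upper
  bound.
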
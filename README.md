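# retppg

Retinal video photoplethysmography (PPG) analysis: from fundus video
sequences to **pulsatile attenuation amplitude (PAA)** maps, and from PAA
maps to the optic-nerve-head (ONH) annulus pattern whose mean PAA best
tracks retinal nerve fiber layer (RNFL) thickness.

## Who this is for

Researchers working with video ophthalmoscopes that record heartbeat-
modulated intensity of the retina (e.g. at wavelengths strongly absorbed
by blood). Each cardiac cycle raises the retinal blood volume, increasing
light absorption and lowering image intensity. The per-pixel amplitude of
that modulation over one heartbeat,

```
PAA(x, y) = A_max = 1 − I_min / I_max,
```

is a perfusion-related statistic: it falls where the microcapillary blood
supply falls, which in glaucoma accompanies RNFL thinning. The package
answers the question *where around the ONH should PAA be sampled so that
it correlates best with RNFL thickness?* — by a full search over annulus
patterns in ONH-relative coordinates, scoring each pattern with the
age-controlled partial Pearson correlation

```
R = (r_xy − r_xz r_yz) / sqrt((1 − r_xz²)(1 − r_yz²)),   z = age,
```

between per-eye pattern-mean PAA (x) and sector-mean RNFL thickness (y).

## Pipeline

1. **registration** — two-stage rigid stabilization of each video: phase
   correlation for large shifts, then Lucas–Kanade point tracking with a
   robust rigid fit for small shifts and rotation; blink/saccade frames
   are flagged.
2. **masks** — matched-filter vessel segmentation (large vessels are
   *excluded*: the analysis targets micro-capillary tissue), and ONH
   geometry (centroid + equivalent-area radius) from a drawn disc mask.
3. **paa** — cardiac pulse windows detected on the global intensity
   signal; per-pulse amplitude maps averaged over the 5 best pulses.
4. **patterns** — annulus / semi-annulus (temporal, nasal) / whole-ONH
   masks parameterized by relative distance `d_r` and width `w_r`
   (normalized by each eye's own ONH radius); angularly matched RNFL
   sector means from circular-scan profiles.
5. **stats** — the (d_r, w_r) correlation landscape, its optimum, and the
   ≥95 %-of-maximum region; per-group summaries.
6. **synthetic** — a first-class generator of fundus videos, masks, RNFL
   profiles and whole cohorts with a *planted*, known PAA–RNFL coupling,
   so every stage is testable without clinical data.

## Worked example

```python
import numpy as np
from retppg import (generate_cohort, correlation_landscape,
                    landscape_optimum, relative_to_absolute)

cohort = generate_cohort(seed=1)          # 111 synthetic eyes, fast mode
mean_r = np.mean([e.geometry.radius for e in cohort.eyes])

for sector in ("full", "temporal", "nasal"):
    L = correlation_landscape(cohort.eyes, sector=sector)
    opt = landscape_optimum(L)
    print(f"{sector:9s} R_max={opt.R_max:.3f} at d_r={opt.d_r:.3f} "
          f"(d={relative_to_absolute(opt.d_r, mean_r)} px), w_r={opt.w_r:.3f}")
```

prints

```
full      R_max=0.331 at d_r=0.500 (d=20.9 px), w_r=0.000
temporal  R_max=0.471 at d_r=0.500 (d=20.9 px), w_r=0.000
nasal     R_max=0.158 at d_r=0.500 (d=20.9 px), w_r=0.020
```

The generator planted its coupling at `d_r = 0.5`, stronger on the
temporal side; the search recovers the annulus position exactly (one grid
step is 0.01) and reproduces the temporal > 360° > nasal ordering of the
maximal correlations. `d = 20.9 px` is the absolute annulus distance at
this cohort's mean ONH radius (~42 px on the 256-px synthetic maps). Note
that a maximal R selected over ~9500 grid cells is selection-inflated; the
pipeline prints this caveat with every run.

A full run (synthetic or file-based) with all artifacts (landscape CSVs,
contour plots, per-eye pattern means, group summaries, manifest):

```bash
retppg run --outdir myrun --seed 1          # synthetic fast mode
retppg simulate --outdir data --seed 1      # synthetic *video* dataset
retppg register --video data/eye_000_video.tiff --outdir reg
```

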
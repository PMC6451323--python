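# zvasc

Tools for quantifying embryonic vascular growth from multi-sample
light-sheet (SPIM) imaging of zebrafish. The package covers the full
computational path from raw acquisition mosaics to growth-law parameters:

1. **Mosaic planning** — tile positions along the embryo with a fixed
   overlap (30% by default), plus acquisition data-rate arithmetic.
2. **Stitching** — phase-correlation registration of overlapping tiles
   initialized from stage positions, global least-squares placement, and
   linear-blending fusion; 3D stacks are registered on their maximum
   intensity projections.
3. **Self-supervised vessel segmentation** — the central method. Vessels
   are hollow tubes with heterogeneous wall signal, so plain thresholding
   of the endothelial marker (*Tg(kdrl:EGFP)*) fails. Circulating red
   blood cells (*Tg(GATA1a:dsRed)*) are an inherent luminal marker: a
   filtered, Otsu-thresholded RBC channel provides training labels for
   free. Six per-voxel features of the endothelial channel — raw signal,
   x/y/z gradients, total gradient ‖∇I‖, and the inverse-gradient-weighted
   image I/(1+‖∇I‖) — are combined linearly with weights solved by SVD
   against N = 5000 luminal and 5000 non-luminal sample points. The score
   image is binarized with the Triangle threshold and cleaned by
   morphological opening.
4. **ROI tracking** — anatomical regions (head, tail, plexus) drawn once
   on the last frame are propagated backward through the projection
   series by per-boundary-point normalized cross-correlation template
   matching (70×70 px templates in 140×140 px search windows) with
   median-of-7 shift regularization.
5. **Quantification** — masks are resampled to isotropic voxels
   (nearest neighbour), counted, converted to µm³, averaged over the two
   ±60° viewing angles, and temporally aligned across fish.
6. **Growth models** — vascular volume V(t) follows laws built on a
   logarithmic rescaling of time:

   - scaled cumulative log-logistic: `V(t) = A + V_L / (1 + (t/α)^(−β))`
   - scaled cumulative log-normal: `V(t) = A + V_L · Φ((ln t − µ)/σ)`

   with offset `A` (volume at observation start), scale `V_L`
   (asymptotic added volume), and Φ the standard normal CDF. Gompertz,
   logistic, Weibull and Richards models (same A/V_L asymptote
   semantics) serve as comparison models; fits are ranked by residual
   sum of squares (RSS). Fitting is Levenberg–Marquardt on
   log-transformed positive parameters with seeded multi-start
   initialization. Growth-rate curves dV/dt and peak-rate times (closed
   form where available) come with every fit.

A first-class synthetic-data module generates two-channel vascular
phantoms with ground-truth wall/lumen masks, tile sets with known
offsets, and noisy growth series, so the whole pipeline is testable
without terabytes of raw imagery.

## Worked example

```python
import numpy as np
from zvasc import (PhantomSpec, generate_vessel_phantom, segment_volume,
                   SegmentationConfig, measure_volume, GrowthSeriesSpec,
                   generate_growth_series, compare_models, peak_growth_time)
from zvasc.segmentation import dice_coefficient

# segment a 96³ two-channel phantom using its own RBC channel as supervision
ph = generate_vessel_phantom(PhantomSpec(shape=(96, 96, 96), n_vessels=3, seed=5))
mask, model = segment_volume(ph.endothelial, ph.rbc, SegmentationConfig(seed=0))
print(round(dice_coefficient(mask.voxels, ph.truth_vessel), 3))  # 0.895
print(measure_volume(mask))                                      # 42803.0 µm³

# fit all six growth models to a noisy log-logistic volume series
series = generate_growth_series(GrowthSeriesSpec(
    params={"A": 2.0e6, "V_L": 1.2e7, "alpha": 32.0, "beta": 3.0},
    noise_sigma=2.4e5, seed=1))
fits = compare_models(series, ["log_logistic", "log_normal", "gompertz",
                               "logistic", "weibull", "richards"], seed=0)
for f in fits:
    print(f"{f.model_id:13s} rss={f.rss:.4g}")
best = fits[0]
print(round(peak_growth_time(best.model_id, best.params), 1))    # 26.0 hpf
```

Output of the comparison (RSS ascending — the log-time models lead):

```
log_logistic  rss=4.122e+12
log_normal    rss=4.153e+12
gompertz      rss=4.237e+12
richards      rss=4.237e+12
logistic      rss=4.344e+12
weibull       rss=4.468e+12
```

The Dice coefficient scores the mask against the phantom's ground-truth
vessel volume; the fitted parameters (here A≈2.23×10⁶ µm³,
V_L≈1.17×10⁷ µm³, α≈32.4, β≈3.1) recover the generating law, and the
peak of dV/dt falls at 26 hpf — early in the second day of development.

A command-line front end mirrors the library:
`zvasc plan`, `zvasc stitch`, `zvasc segment`, `zvasc quantify`,
`zvasc fit`, `zvasc phantom`, and `zvasc run` for a whole experiment
folder (see `zvasc --help`).

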
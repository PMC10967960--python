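# octvit

Quantification of vitreous immune activity from OCT B-scan stacks.

Latest-generation OCT devices resolve individual immune cells (hyalocyte-like
Iba1+ cells) floating in the vitreous as small hyperreflective opacities.
`octvit` turns a stack of cross-sectional B-scans of one eye into quantitative
immune readouts, for researchers studying ocular inflammation and experimental
glaucoma models:

1. **Layer segmentation** — per column of each B-scan, locates the inner
   limiting membrane (ILM) and the inner/outer boundaries of the retinal
   pigment epithelium (RPE) from the axial intensity profile, delimiting the
   vitreous and RPE compartments.
2. **VIT/RPE relative intensity** — mean vitreous intensity divided by mean
   RPE intensity per B-scan, averaged over the stack: a device-gain-free
   proxy for bulk vitreous turbidity.
3. **Opacity morphometry** — background speckle inside the vitreous is
   suppressed with a robust threshold `T = median + k·σ_MAD` (k = 6 by
   default); each surviving 8-connected component becomes an opacity record
   with

   - area `A = n_px · a_px` (default `a_px` = 3.815 µm²/pixel, i.e. a 3 mm /
     1536-column scan of 1536 × 496 px covering 2.906 mm²),
   - mean intensity,
   - eccentricity `e = √(1 − λ₂/λ₁)` and major-axis orientation
     `θ = ½·atan2(2µ₁₁, µ₂₀ − µ₀₂) ∈ (−90°, 90°]` from the second central
     moments (ellipse of inertia) of the pixel set,
   - an activation-state size class: isolated cells (< 10 µm²),
     non-activated cells (10–50 µm²), activated cells (50–250 µm²),
     cell complexes (> 250 µm²).
4. **Per-eye summaries and cohort statistics** — total cell area, mean
   number/area of opacities, class percentages and per-class shape averages;
   Kolmogorov–Smirnov normality checks, per-week one-way ANOVA with
   Bonferroni-adjusted pairwise comparisons, and lagged Pearson correlations
   (e.g. IOP at week 2 vs vitreous signal at week 24).
5. **Synthetic phantom** — a generator that renders the same acquisition
   geometry (layered scene, multiplicative gamma speckle, injected elliptical
   blobs) with exact ground truth, used to validate every step above.

## Worked example

```python
from octvit import PhantomConfig, end_to_end_recovery

config = PhantomConfig(
    height_px=400, width_px=1024, n_frames=3, ilm_row_mean=260,
    retina_thickness_px=80, rpe_thickness_px=16,
    class_counts={"isolated": 10, "non_activated": 20, "activated": 20, "complex": 10},
    seed=4,
)
report = end_to_end_recovery(config)
print(report.recall, report.precision, report.class_accuracy)
print(report.designed_vit_rpe, round(report.recovered_vit_rpe, 4))
print(round(report.boundary_rms_rows, 2))
```

prints

```
1.0 1.0 1.0
0.12 0.1251
0.54
```

meaning: every injected blob of at least 2 px was detected with no false
positives, every matched blob landed in its true size class, the designed
VIT/RPE ratio 0.12 was recovered to 0.0051 (the small excess is the bright
opacities themselves, which the ratio deliberately includes), and the layer
boundaries were located to about half a pixel row RMS.

The `examples/` directory has one short script per capability (phantom
generation, segmentation + VIT/RPE, detection + taxonomy, end-to-end
validation, cohort statistics); each prints the numbers it computes with a
note on what they mean.

A thin CLI covers batch use: `octvit info`, `octvit analyze`,
`octvit simulate`, `octvit stats` (see `--help`).

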
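# Methods

This note documents the models, algorithms and numerical choices behind
`octvit`, and what the phantom-based validation does and does not show.

## Image model and coordinates

A B-scan is a 2-D raster with rows = axial depth (row 0 = innermost
vitreous) and columns = lateral position. Intensities are normalised to
[0, 1] on read by dividing by the maximum representable value of the stored
integer dtype, so every threshold in the package is bit-depth independent.
Colour frames are reduced to greyscale by an unweighted channel mean — a
reproducible, codec-independent choice for video exports whose channels are
nominally identical.

The default per-pixel area is 3.815 µm². The acquisition protocol covers a
3 mm lateral scan with 1536 columns, i.e. square pixels of
3000/1536 = 1.953125 µm; the square is 3.8147 µm² (printed as 3.815) and the
whole 1536 × 496 frame covers 2.90625 mm² (printed as 2.906). A stated
nominal resolution of "3 µm/pixel" is inconsistent with this geometry and is
treated as a rounding artefact; `pixel_area_from_scan()` derives the exact
value, and `pixel_area_um2` is an explicit, overridable parameter
everywhere.

## Layer segmentation

Per-column axial profiles are smoothed **laterally only** (moving average
across `smoothing_window` = 15 columns). Lateral smoothing suppresses
speckle as effectively as axial smoothing (speckle is i.i.d. per pixel) but
leaves axial step edges unmoved, so boundary positions are not displaced by
the filter. A global Otsu threshold separates the dark compartments
(vitreous, below-RPE) from the bright retinal band.

Per column, supra-threshold runs are extracted; dark gaps shorter than a
sustained transition (< `min_band_rows` = 5 rows) are closed first, since a
dip that brief is speckle, not anatomy. The **longest** sustained run is
taken as the retinal band: its first row is the ILM and its last row the
outer RPE. Using the longest run rather than literally the first
supra-threshold run makes the detector indifferent to bright opacities
floating in the vitreous, which form short runs well above the ILM; on
blob-free frames the two rules coincide. The RPE inner boundary is found
within the band from an additionally axially-smoothed profile
(window = `min_band_rows`): the run of rows containing the band's peak that
stays above the midpoint of the band median and the peak — the RPE being, by
construction of OCT retinal images, the brightest sustained band.

Columns without a sustained run are filled by linear interpolation from
valid neighbours; if more than 50% of columns fail (e.g. a uniform frame),
segmentation raises an error. All three boundary curves are median-smoothed
across columns with the same window, then clipped to maintain
`ilm < rpe_inner ≤ rpe_outer`. On curved phantoms at 4:1 retina:vitreous
contrast the worst boundary RMS error observed over 40 speckle seeds is
about 1.05 rows.

The vitreous mask is everything strictly above `ilm − margin_rows`
(default margin 2 rows, excluding ILM-adherent pixels whose membership is
ambiguous) with an optional `top_margin_rows` cut for acquisition artefacts
at the frame top (default 0).

## VIT/RPE relative intensity

Per B-scan: mean intensity over the vitreous mask divided by mean intensity
over the RPE band; per eye: the unweighted mean over B-scans. The measure is
invariant under global intensity scaling. The vitreous region deliberately
**includes** opacities — the ratio is a bulk turbidity measure computed
independently of detection, which also means a heavily infiltrated eye shows
a slightly higher ratio than its cell-free background would. Frames whose
segmentation fails are excluded from the mean and reported, not imputed.

## Opacity detection and morphometry

Background suppression uses a robust threshold computed inside the vitreous
mask: `T = median + k_sigma · 1.4826 · MAD` with `k_sigma` = 6. Robust
statistics make `T` insensitive to the opacities themselves and to overall
gain; a constant region yields no detections rather than an error. Connected
components (8-neighbour by default, so diagonal speckle of one cell does not
split; 4-neighbour available) of at least `min_area_px` = 1 pixel become
opacity records.

Shape descriptors come from the second central moments of the pixel set
(the ellipse of inertia), computed in (x, y) = (col, −row) so angles are
counter-clockwise from the image horizontal: eccentricity
`√(1 − λ₂/λ₁)` from the covariance eigenvalues, orientation
`½·atan2(2µ₁₁, µ₂₀ − µ₀₂)` mapped to (−90°, 90°]. A single pixel is defined
as eccentricity 0, orientation 0 (degenerate moments). Size classes use
half-open, lower-inclusive intervals — [0, 10) isolated, [10, 50)
non-activated, [50, 250) activated, [250, ∞) complexes — so an exact
boundary area joins the upper class.

Per-eye aggregation: total area, mean count per B-scan, mean area overall
and per class, class percentages, and per-class mean eccentricity/intensity/
orientation. Mean orientation is the **signed arithmetic mean**, not a
circular mean: a population oriented towards one retinal locus shows a net
shift, while mixed orientations cancel back to 0 — the interpretation the
per-class orientation summary is designed to carry.

### Noise floor of single-pixel detections

With multiplicative gamma speckle (shape 4) and `k_sigma` = 6, roughly
1 × 10⁻⁴ of background pixels exceed `T`. These exceedances are almost
always isolated single pixels: per-pixel they are rare, and two adjacent
exceedances are rarer by four orders of magnitude. Consequently single-pixel
detections — the same footprint as the smallest isolated cells — sit partly
in the noise floor, while detections of ≥ 2 px are effectively noise-free.
Validation metrics (recall/precision) are therefore reported over ≥ 2-px
blobs, and analyses that need a clean detection list can set
`min_area_px=2` at the cost of the 1-px end of the isolated-cell class.

## Cohort statistics

The cohort table is long-format, keyed by (animal, eye, week) with weeks on
the study grid {0, 2, 4, 6, 8, 12, 18, 24}; each row is treated as one
observation (no repeated-measures modelling, matching the original design).
Normality: one-sample Kolmogorov–Smirnov against a normal with the sample
mean/SD (n ≥ 5, non-constant). Group comparisons: one-way ANOVA per
(measure, week); the degenerate all-identical case is reported as F = 0,
p = 1 rather than 0/0. Post-hocs are pairwise **Welch** t-tests (robust to
the unequal group sizes typical of animal cohorts) with Bonferroni
adjustment `min(1, m·p)` and α = 0.05. Correlations: Pearson r on animals
having both measurements, with strength labels |r| < 0.4 weak, 0.4–0.7
moderate, > 0.7 strong (a documented convention, prefixed "inverse" for
negative r). Since no real cohort data are distributable, this layer is
validated by simulation: type-I/power patterns of the ANOVA post-hocs,
KS acceptance of normal samples, null and ρ = 0.85 correlation recovery.

## Phantom generator

The phantom renders the full acquisition geometry (496 × 1536 px, 61
B-scans, 3.815 µm²/px by default) as a layered scene: vitreous intensity
0.054, retina 0.25, RPE 0.45 (designed VIT/RPE = 0.12, retina:vitreous
contrast ≈ 4.6:1), boundaries curved sinusoidally (amplitude 15 px, period
512 px, random phase per frame), everything multiplied by gamma speckle with
shape 4 and unit mean — a standard surrogate for fully developed OCT
speckle. Values are clipped to [0, 1]; at these intensities clipping biases
the RPE mean by < 0.004, i.e. the realised VIT/RPE sits within ~0.001 of the
design before opacities are added.

Blobs are filled rotated ellipses whose semi-axes follow from the requested
area and eccentricity; targets below ~4 px are realised as 1–3 pixel strips
(below the rasterisation limit). Blob intensity is added on top of the local
background as a multiple of the vitreous mean (default 6×, comfortably above
the 6σ suppression threshold at ~3.9× the vitreous mean). Placement is
rejection-sampled inside the vitreous with a 3-px separation ring (so
8-connectivity cannot merge blobs), an 8-row clearance above the ILM and a
5-row top clearance; impossible configurations raise an error. Per-class
area sampling ranges are kept clear of the 10/50/250 µm² boundaries so that
±1–2 px of rasterisation cannot flip a blob's true class.

Ground truth stores **post-rasterisation** values — pixel count × pixel
area, and eccentricity/orientation re-measured on the rasterised mask with
the same moment definitions the detector uses — so feature-recovery tests
are exact rather than aliasing-limited; the requested analytic values are
kept alongside.

`end_to_end_recovery()` chains generate → segment → suppress → detect →
summarise and scores recall/precision (≥ 2-px blobs, see noise floor above),
a 4 × 4 class-confusion matrix over ground-truth-matched detections (greedy
nearest-centroid matching within 2.5 px + the blob's equivalent radius),
per-feature mean absolute errors, VIT/RPE error versus the design, and
ILM/outer-RPE RMS versus the true curves.

### What the phantom does and does not emulate

It reproduces the geometry, intensity ordering, multiplicative speckle and
opacity morphology that the pipeline's correctness depends on. It has no
physical OCT forward model: no point-spread function, attenuation or
shadowing, no motion or registration artefacts, no intermediate retinal
layers, and blobs are ideal ellipses rather than ramified cell somata.
Passing phantom tests therefore demonstrates that the measurement chain is
correct and unbiased under the stated noise model — not that segmentation or
detection thresholds are optimal for any particular device's real images.

## Problem sizes in tests and validation

Tests and the acceptance script run the same physics at reduced size —
typically 400 × 1024 px frames, 1–4 B-scans per stack, 10 speckle seeds,
100 blobs per detection run — which the package treats as its standard
validation configuration; nothing in the pipeline depends on frame count or
frame size. Video (AVI) input is supported best-effort via imageio; since
lossy codecs do not round-trip intensities, lossless image stacks
(multipage float32 TIFF, PNG/TIFF directories) are the reference path and
the one exercised by tests.

## Known limitations

- Opacities touching the ILM margin are excluded by the 2-row default
  margin; whether such cells should count is a biological judgement exposed
  as `margin_rows`.
- Single-pixel detections include a small speckle-noise component at the
  default `k_sigma` (see noise floor above).
- Analysis is strictly 2-D per B-scan; one cell spanning adjacent B-scans
  is counted once per scan (no 3-D linking), and no cell tracking is done
  across visits.
- The statistics layer validates operating characteristics by simulation;
  it does not reproduce any particular cohort's effect sizes.
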
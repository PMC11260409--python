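# Methods

This note documents the models behind each stage of `voidspot`, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic tests do and do not demonstrate
about real assay data.

## Synthetic scene model

The generator emulates the geometry and photometry of a void spot assay
recording — bright, near-circular urine spots on dark filter paper under
UV light — not its chemistry.

**Spot profile.** Each spot is a disc of peak intensity `peak_intensity`
on background `background_level`, with a cosine smoothstep rim of width
1 px *centred on the nominal radius*. The half-contrast contour
therefore coincides with the truth boundary (pixel centres strictly
inside the radius), which ties the generator's contrast model to the
detector's assumptions: thresholding a noise-free spot at
`(background + peak)/2` recovers the truth mask with IoU ≥ 0.95.
Overlapping spots combine by maximum — wet paper saturates rather than
adds. Truth masks are recorded before noise.

**Diffusion law.** A spot appearing at frame `t0` grows as

    r(t) = final_radius · (1 − exp(−(t − t0 + 1) / τ)),   t ≥ t0,

with one elapsed frame at appearance and a 1.5 px visibility floor: a
freshly deposited drop is never sub-pixel, areas are strictly zero
before `t0` and positive from `t0`, and the τ → 0 limit reproduces the
static disc. The law is monotone and bounded with a single timescale
parameter τ (frames); it is a phenomenological stand-in for paper
wicking, chosen for those three properties rather than fitted to fluid
physics. By convention a one-frame scene is a finished still (spots at
final radius), identical to `render_image`.

**Noise.** Additive Gaussian with standard deviation `noise_sd`,
clipped to [0, 1]. This stresses thresholding and scoring without
modelling camera physics (no shot noise, vignetting, or motion blur).

**Defaults.** 720 × 1280 px frames (the acquisition convention of the
assay's video camera); background 0.08; peak 0.85; `noise_sd` 0 unless
set. All randomness flows from one integer scene seed. Tests and the
acceptance script use 240 × 320 to 360 × 480 rasters — the geometry is
scale-free, and the smaller scenes keep the suites fast.

**What passing tests do not show.** Synthetic scenes contain no mouse:
no occlusion of spots by the animal, no locomotion streaks, no
non-urine fluorescent artefacts, no uneven illumination. Results on
real recordings depend on contrast and artefact rates the generator
does not emulate; the COCO proposal loader exists precisely so a
trained segmentation network can replace the classical detector when
those effects dominate.

## Detection

Threshold (fixed, default 0.5, or Otsu) → binary opening (disc radius
1 px; removes single-pixel noise) → 8-connected component labelling
(diagonal wicking along paper fibres keeps one spot one component) →
discard components below `min_area_px` (default 12 px). The score of an
instance is its mean foreground intensity, clipped to [0, 1] — any
monotone confidence works for PR-curve purposes, and brightness is the
natural one for UV fluorescence. The detector is deterministic.

## Watershed splitting of merged spots

Markers are local maxima of the euclidean distance transform of the
blob mask, separated by at least `min_seed_distance` (default 8 px,
roughly 0.6 × the smallest expected spot radius) and at least `h_min`
(default 3 px) deep. The depth guard is the standard remedy for
watershed over-segmentation: shallow maxima from boundary roughness
never seed a region. If every maximum is shallower than `h_min` (a
small fresh spot), the global maximum is kept so each blob retains one
seed. Marker extraction by distance-transform peaks is equivalent in
effect to iterative erosion to centres of mass, but better conditioned.

Flooding uses the negated distance transform by default; on binary
masks the intensity gradient is degenerate, and the distance surface is
the standard choice for overlapping round objects. A `gradient` surface
(Sobel magnitude of the intensity image) is available for images with
informative shading. Flooding is restricted to the mask with
8-connectivity, so every foreground pixel is assigned to exactly one
component: pixel conservation and component-count = marker-count hold
exactly and are asserted, not approximated. Concentric overlaps are a
documented degeneracy — one round mask, one marker, one component.

## Tracking

State vector `(row, col, area, d_area)`: urine spots do not translate,
they spread, so position is static and area grows linearly between
frames with a tracked rate. Measurement is `(row, col, area)` of each
detected instance.

Noise scales (all configurable): process position 0.5 px/frame, process
area 10 px²/frame, process area-rate 15 px²/frame², measurement
position 2 px, measurement area 25 px². The two area terms additionally
scale with the current area estimate (5% for measurement, 10% for the
rate): a 4000 px² spot changes by hundreds of pixels per frame early in
its growth, and fixed floors sized for small spots would otherwise
reject valid matches and fragment tracks. New tracks start with wide
covariance, widest on the unobserved growth rate.

Candidate (track, detection) pairs are gated by squared Mahalanobis
distance under the innovation covariance at the chi-square 0.95
quantile for 3 degrees of freedom (7.815) *and* by non-zero mask
overlap; assignment minimises `1 − mask IoU` over gated pairs with the
Hungarian algorithm (maximum feasible cardinality, then minimum cost).
Motion gating plus IoU suffices because spots are visually homogeneous
and static; no appearance embedding is used — a deliberate
simplification relative to general-purpose multi-object trackers.

Tracks are never deleted: a spot cannot leave the paper, and deleting a
stale track would double-count the spot on re-detection. A track is
confirmed after `n_init` = 3 hits; the appearance time of an event is
`first_frame / fps`, so appearance recovery is accurate to the frame at
which the spot first exceeds the detector's minimum area. The session
report lists, per confirmed track, the appearance time, final centroid,
final area (px and cm²) and calibrated volume, plus the event count,
voiding frequency (events/hour) and inter-void intervals (successive
differences of sorted appearance times).

## Calibration

Ordinary least squares of volume (µL) on area (cm²), free intercept by
default — paper wicking can produce a non-zero offset; a zero-intercept
mode exists. The regression direction follows use: volume is what is
predicted from a measured area. Points above the 100 µL validity
ceiling are excluded with a warning (the volume-area relation is linear
only below it), conversions that land above it are flagged as
extrapolation, and negative predictions (tiny spots with a positive
intercept) are clamped to zero with a warning. `R² = 1 − SS_res/SS_tot`
on the retained points. The pixel-to-cm scale is user-supplied; it
cannot be inferred from an image without a fiducial.

## Evaluation metrics

Matching is greedy in descending score order at a given IoU threshold
(mask IoU by default — the quantities of interest are pixel-level;
bbox mode is provided). Score ties are broken by larger best-IoU, then
input order; IoU ties keep the last candidate, following the reference
COCO implementation so the two agree exactly. `AP = ∫ P dR` is computed
two ways: the COCO 101-point interpolation of the precision envelope
(default, and the convention behind AP50/AP75/mAP) and an exact step
integral (each true positive at rank k contributes `precision(k)/n`),
kept separate so oracle tests can check the raw integral. With the
single "spot" category, mAP equals AP averaged over IoU thresholds
0.50:0.05:0.95.

Area stratification uses bounding-box area with bands at 32² and 96²
px². Out-of-band truths are *ignored*, not removed: predictions matched
to them are dropped from the ranking, as are unmatched predictions
whose own box lies outside the band, so a stray large prediction does
not poison AP_S. A band with no truth yields an explicit undefined
(`None`) rather than zero — on a dataset of exclusively large spots,
AP_S and AP_M are meaningless, and reporting 0 would misread as failure.

## Numerical and degenerate-input choices

- Coordinates `(row, col)`, 0-based; boxes half-open `[r0,r1)×[c0,c1)`.
- Masks serialised as uncompressed column-major COCO RLE (lossless
  round trip); polygons accepted on read and rasterised (exact up to
  the 1 px boundary rim). JPEG is read-only; fixtures are PNG so
  bit-exact assertions hold.
- Empty detection result is a value (empty list), not an error; an
  empty image, an empty mask, an empty dataset split, a degenerate
  calibration (all areas equal) and AP with no ground truth are errors.
- Singular innovation covariance falls back to a small ridge
  regularisation before solving.
- `split_dataset` uses Python's `round` for the train size (banker's
  rounding at .5) and a seeded permutation.

## Known limitations

- The classical detector assumes high-contrast spots on a darker
  background; it has no defence against fluorescent artefacts, uneven
  illumination, or occlusion by the animal. Use the COCO proposal
  loader with a trained network for such recordings.
- Concentric or near-concentric overlaps cannot be split (one distance
  maximum); deeply overlapping same-size pairs lose accuracy as the
  centre distance approaches the radius.
- Appearance times are bounded below by the detector's minimum area:
  a slowly growing spot is timestamped when it first becomes
  detectable, not when the void began.
- Voiding frequency extrapolates events/hour from the recording length;
  for very short clips the figure is noisy by construction.
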
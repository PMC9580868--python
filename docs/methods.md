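# Methods

This note records the models, conventions and design choices behind
voxelearn, and what the synthetic benchmarks do and do not demonstrate.

## Coordinate and ID conventions

Volumes are stored `(z, y, x)` in memory — element `[0, 0, 0]` is the first
pixel of the first slice of a TIFF/NIfTI file — while public dimensions are
`(n_x, n_y, n_z)`.  A voxel's linear ID is `x + n_x (y + n_y z)` (x
fastest).  NIfTI volumes, which are x-fastest on disk, are transposed on
read/write so the same ID scheme applies to both formats.  Annotation and
transfer-function files are plain JSON and portable across bit depths
(transfer functions address intensities normalised by the volume's
min/max).

## Stroke rasterisation

A stroke tags every voxel whose centre lies within the brush radius of the
polyline.  This is computed with the exact point-to-segment distance,
vectorised over the stroke's bounding box, rather than by sampling the
polyline at fixed arc-length steps: the exact form has no discretisation
gap to tune and is directly checkable against a whole-volume brute-force
scan (the property tests do exactly that on 10³ volumes).  Out-of-volume
voxels are clipped.  Within one iteration a voxel may carry only one label;
the conflicting case is rejected because a headless API, unlike an
interactive front end, can be handed contradictory input.  Erasing keeps
the event in the log so correction rounds remain auditable.

## The 56-feature bank

The bank is `PIXEL_VALUE` plus 11 filter kinds × 5 kernel sizes
{3, 5, 7, 9, 11} = 56 features, covering smoothing (Gaussian, mean,
median), order statistics (minimum, maximum, range), texture (standard
deviation) and differential geometry (gradient magnitude, Laplacian of
Gaussian, difference of Gaussians, largest Hessian eigenvalue — the latter
aimed at tubular structures).  Numerical conventions:

- Gaussian σ = k/6, so ±3σ spans the kernel; all Gaussian-family kernels
  are *sampled and truncated to the k³ window* and smoothing kernels are
  renormalised to unit sum.  Truncation makes the k³ neighbourhood fully
  determine every response, which is what lets a brute-force window
  enumeration serve as an independent oracle in the tests.
- Derivative kernels are exactly zero-sum (the second-derivative kernel is
  recentred after truncation), so every non-smoothing feature vanishes on a
  constant field.
- DoG = G(σ) − G(2σ), both truncated to the same window.
- Borders use mirror padding (symmetric reflection about the edge), which
  avoids zero-halo artefacts at tagged voxels near faces.
- Features are computed in 64-bit floats on intensities cast to real, with
  no normalisation: tree learners are scale-free and `PIXEL_VALUE` stays in
  native units for interpretable importance reports.

Dense computation runs each filter over the whole volume
(`scipy.ndimage`); sparse computation extracts mirror-padded patches and
evaluates window statistics directly.  The two paths are independent
implementations and are cross-checked in the tests.  Blockwise (tiled)
computation pads the full volume once with a halo equal to the maximum
kernel radius (5 voxels for the default bank) and crops each tile's
interior, so tiling is exact; blocks smaller than the halo are rejected.

## Classifiers

Defaults (all overridable, chosen for sub-second fits on stroke-sized
training sets): RFC 100 trees, unlimited depth; XGB 100 rounds, depth 3,
learning rate 0.1; MLP one hidden layer of 64 units, ≤300 iterations; SVM
RBF with probability outputs; Gaussian NB.  MLP and SVM are fitted behind
an internal standardiser (z-scoring estimated on the training rows) —
intensity-scale inputs otherwise stall MLP convergence and distort the RBF
kernel; tree and NB learners consume raw features.  All estimators are
seeded; the whole train → persist → predict path is reproducible and
asserted bitwise in the tests.

The strong learner's weak quartet is {RFC, MLP, SVM, NBC} with gradient
boosting as the meta model.  Weak probabilities appended to the meta
training matrix are computed on the training voxels themselves: the
annotation setting deliberately "overfits" the volume being explored, and
in-sample stacking is the cheaper and more decisive choice there.  A
stratified 3-fold out-of-fold mode is available behind a flag for users
who want leakage-free stacking.

Models persist as a zip archive holding a JSON manifest (kind, feature
schema, training metadata) plus a joblib payload; the manifest is verified
against the payload on load, and predicting on a mismatching feature
schema raises.

Impurity-based importance (share of total Gini reduction, in percent,
summing to 100) is defined for RFC and XGB only; other kinds raise.

## Inference, overlay, evaluation

Dense inference evaluates the bank (optionally tiled) and applies the
model in chunks; the probability map matches sparse per-voxel prediction
to float tolerance regardless of tiling.  Log-probabilities are floored at
log(1e-12).  Overlay composites up to four channels back-to-front with the
"over" operator on straight alpha; the default probability transfer
function interpolates linearly from transparent blue (p = 0) through
magenta to opaque red (p = 1) — the exact colour spline is a free choice.
Dice uses threshold 0.5 with ties counting positive, empty-vs-empty
scoring 1; RMSE compares raw probabilities to the binary reference over
all voxels (no ROI restriction).

## Synthetic phantoms and what they show

Two families emulate the method's target structures: bulky ellipsoidal
blobs (tumour-like) and thin tubular networks grown as momentum random
walks (persistence 0.9) dilated to a 1.5-voxel radius (neurite-like).
Intensities are two-level (background 10, object 200) plus Gaussian noise;
the noisy fixtures use σ = 38, i.e. 20 % of the contrast; a Poisson mode
is available for shot-noise realism.  The default blob half-axes are
non-integer fractions of the dims (0.26, 0.225, 0.19) so the voxelized
surface has no degenerate single-voxel tips whose neighbourhoods are
indistinguishable from background.

The stroke simulator plays the user: positive strokes are short walks
along the object; negative strokes are long streaks swept across the
scene, aimed loosely at the object so near-boundary background is sampled
— short, far-from-object negative strokes leave the classifier with no
example of the partial-volume shell around objects and produce a
systematic false-positive rim.  All simulated tags are intersected with
the ground truth, so the supervision is label-consistent by construction.

Frozen fixtures (`blob_clean` 32³ noiseless, `blob_noisy` 32³ σ=38,
`tubes_noisy` 48³ with 3 tubes) regenerate bit-identically from their
recorded seeds.  On them the standard pipeline reaches Dice 1.0
(noiseless blob, 20+20 strokes), ≥ 0.99 (noisy blob, 2+2 strokes) and
≈ 0.96 (noisy tubes, 2+2 strokes, stroke seed 0); with only two positive
strokes the tubes result varies substantially with stroke placement
(≈ 0.57–0.96 across seeds), which is the method's genuine sensitivity to
where a user strokes, not numerical noise.

These phantoms have sharp two-level contrast, stationary noise and simple
geometry; passing on them shows the machinery (features → training →
dense inference → scoring) is correct and reproducible, not that the
method reaches any particular accuracy on clinical CT/MRI or real
microscopy, whose textures, intensity inhomogeneities and anisotropic
point-spread functions the generator does not emulate.

On the phantoms the importance reports reproduce the method's
characteristic structure: the raw `PIXEL_VALUE` contributes only a few
percent, and the importance-weighted mean kernel size is larger for blobs
(≈ 7.2 voxels) than for tubes (≈ 5.6) — bulky structures reward larger
smoothing scales, thin ones smaller.

## Learning service

The job service is an in-process store with one worker thread per
launched job; state transitions are `created → running → done|error`
(`created` added so uploads-before-launch are well defined).  The HTTP
layer is a small stdlib `http.server` application; payload dialects
(training JSON, `.vxl` model archive, TIFF volumes) are the package's
own, documented in the module.  Remote execution is bit-compatible with
local execution given identical inputs and seeds, and concurrent jobs are
isolated — both asserted in the tests.

## Problem sizes

Tests and the acceptance script run on 32³–48³ volumes with hundreds of
tagged voxels; these sizes exercise every code path (tiling included)
while keeping a full run in the tens of seconds.  Larger volumes go
through the same blockwise machinery with identical results by
construction.
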
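# Methods

This note records the model, the parameter choices and the numerical
conventions behind `exprfeat`, including the decisions taken where the
published descriptions of these operators leave details open.

## Pipeline and assumptions

The pipeline assumes a single, roughly frontal face per image whose
position is given by a standard 68-point landmark set.  Landmarks are an
*input* (sidecar file, manifest column, or the synthetic generator);
fitting a landmark detector is out of scope, and an external pretrained
detector can be plugged in by producing the same 68-point format.

Stages: crop → LBP histograms → region-balanced ORB → per-block Z-score
fusion → SVM.  Every constant lives in `PipelineConfig`; nothing reads a
tunable value from anywhere else.

### Face region

The crop is the axis-aligned bounding box of points 1–27 (jaw plus both
eyebrows).  A polygon mask was considered and rejected: masking zeroes
pixels that the texture and corner operators would otherwise use, and the
rectangle is the simpler reading of how landmark-guided cropping is
usually illustrated.  Color is reduced by BT.601 luminance
(0.299 R + 0.587 G + 0.114 B, rounded); resizing to 130 × 130 uses
bilinear interpolation with edge padding and re-quantizes to uint8.
Internally everything is 0-based (row, col); the 1-based point numbering
appears only in the public landmark API, matching the field's convention.

### LBP

`s(u) = 1` for `u ≥ 0`: ties count as 1, which makes the operator
invariant to adding a constant or scaling intensities by a positive
factor (only difference signs matter).  The neighbor-to-bit assignment is
clockwise from the top-left of the 3 × 3 neighborhood; the convention is
arbitrary (any fixed order permutes bits without affecting uniform-pattern
membership) but pinned by tests.  Uniform codes (≤ 2 circular
transitions; exactly 58 of 256, verified by enumeration) take bins 0–57
in ascending code order; all others share bin 58.

"16 × 16 patches with a resolution of 8 × 8" admits two readings; the
default is 16 × 16-pixel patches in an 8 × 8 grid (64 patches, 3776
dims).  The other reading (8 × 8-pixel patches, 256 of them, 15104 dims)
is `PipelineConfig(lbp_patch_size=8)`.  Histograms carry raw counts —
each 59-bin block sums to the patch area — and all scaling is deferred to
the fusion stage.

### FAST score and detection

The score sums, over the circle pixels beyond the ±t band, the absolute
difference minus t per pixel: `max(Σ_bright (I_x − I_p − t),
Σ_dark (I_p − I_x − t))`.  (Placing the −t outside the sum instead would
break monotonicity in contrast and disagree with the FAST literature.)
Pixels exactly at `I_p ± t` belong to the bright/dark sets but contribute
zero.  Non-maximal suppression keeps a corner only if its score is the
strict maximum of its 3 × 3 neighborhood; score ties break to the earlier
row-major position, making detection fully deterministic.

A consequence of the 12-contiguous-pixel rule worth knowing: a perfect
90° corner of a large uniform square is *not* detected (its dark arc is
11 pixels); FAST-12 needs corners sharper than a right angle, or isolated
structures (a 3 × 3 blob yields a full dark ring of 16).  The synthetic
generator therefore plants 3 × 3 blobs as its corner features.

### Region-balanced budgeting

With an M × N division and a total budget n, the per-region quota is
`T = ⌊n/(MN)⌋`.  Threshold relaxation is geometric, `t ← max(1, ⌊t/2⌋)`,
stopping at t = 1 — this terminates on flat regions where a literal
"lower and repeat" loop would not.  Division-remainder slots go one each
to the regions whose best surplus candidate scores highest.  If some
regions cannot fill their quota even at t = 1, the residual deficit is
filled from the remaining NMS-surviving candidates image-wide by
descending score, so exactly n corners are returned whenever n exist;
only when the whole image is too flat does the output fall short, with a
warning and zero-padded descriptor slots (validity mask False).

Candidates are restricted to ≥ 17 pixels from every border so the full
35 × 35 descriptor subimage always fits; corners that cannot be described
are never detected in the first place.

### Orientation and BRIEF

Orientation is the intensity centroid: `θ = atan2(m01, m10)` over a
radius-15 disc, with θ = 0 when both first moments vanish.  The BRIEF
pattern draws 256 offset pairs i.i.d. from Gaussian(0, S²/25), S = 31,
clipped to the 31 × 31 window, from a fixed seed shipped with the library
(`DEFAULT_PATTERN_SEED`) — the distribution is standard, but descriptors
are only comparable across runs if the realized pattern is frozen.
Intensities are 5 × 5 box-smoothed before comparison; steering rotates
the pair offsets by θ with nearest-pixel rounding before lookup (the
standard rotated-BRIEF construction).  Bits are 1 iff the first smoothed
value is strictly less than the second, so equal values give 0 and the
descriptor is invariant to positive affine intensity maps.

Defaults n = 160 keypoints on a 4 × 4 grid, t₀ = 30, orientation radius
15: these are the package's own choices (published accounts of this
method do not state their values) sized so that a 130 × 130 face
comfortably supplies 10 describable corners per tile.  The fixed-length
SVM input — descriptors concatenated in region-scan order, descending
score within a region, zero-padded — is likewise this package's
construction; how variable keypoint sets become fixed-length inputs is
not specified anywhere authoritative.

No image pyramid is implemented: the feature families used here are
defined single-scale, and no scale machinery is described for this
pipeline that could be implemented faithfully.

### Fusion

Each block is standardized to mean C and *population* SD K over its own
entries (the per-vector scope: the standardization index runs over one
feature vector).  K = 100 by default; C is 0 (the offset constant has no
published value).  A zero-variance block maps to the constant C.  Note
the max-normalization of the LBP block before standardization is
numerically redundant for a single vector — standardization removes
scale — and is kept as part of the documented flow; a regression test
asserts the redundancy.  A per-dataset scope (column-wise over the
training set) is available as `BlockZScoreFuser(scope="dataset")`.

### SVM and cross-validation

RBF kernel, one-vs-one.  C is searched over powers of two spanning
2⁻³…2¹⁰ (subsampled in steps of 4×).  γ is searched over powers-of-two
multipliers (2⁻⁴…2⁴) of the scale heuristic `1/(d · Var(X_train))` rather
than over absolute values: with ~45k-dimensional vectors standardized to
SD 100, squared distances are of order 10⁹ and any absolute γ grid in the
classical LibSVM range underflows the kernel to zero.  The multiplier
grid keeps the search meaningful for any feature dimension and spread.

Model selection is nested — a stratified inner CV (default 3-fold;
5-fold available via `svm_inner_k`) on each outer training fold — so
hyperparameters never see test data.  Grid ties break to the earliest
grid entry.  All kernels are evaluated from one precomputed pairwise
squared-distance matrix, which makes the nested search cheap enough to
run the full protocol on one CPU.

SD folds are stratified by label and rerolled (fresh derived seed) if a
class is absent from a training fold; SI folds partition subjects, where
stratification is impossible, and a missing class is accepted with a
note.  Folds are computed on records sorted by path, so results are
invariant to manifest row order.  The pooled confusion matrix is 7 × 7 in
fixed alphabetical label order (anger, disgust, fear, happy, neutral,
sad, surprise); mean accuracy is its trace over its total.

## Synthetic corpus

The generator emulates the *structure* a posed-expression corpus gives
this method, not its photometric realism: an oval face whose 68 landmarks
come from a canonical template under a per-subject similarity warp (±5%
scale, ±3° rotation, ±2 px translation) plus a per-subject brightness
offset (±25 levels); a class signal carried both by an oriented sinusoidal
grating (orientation π·c/7, angular frequency varying with class — an
LBP-sensitive cue) and by a class-specific constellation of 12 bright
3 × 3 corner blobs (an ORB-sensitive cue); dark ellipses at the eye,
brow, nose and mouth landmarks; additive Gaussian noise of SD 8 gray
levels; replicates differ by ±1 px micro-jitter and fresh noise.  The
default 10 subjects × 7 classes × 3 replicates = 210 images mirrors the
scale of the classic 10-subject posed corpus these protocols were
designed around.  Everything derives from one seed through disjoint child
seed sequences, so images are bit-identical across runs and platforms.

What it does not emulate: identity-specific facial morphology beyond the
similarity warp, illumination gradients, pose changes, occlusion,
demographic variation.  Passing tests on this corpus therefore establish
that the implementation is correct and that the protocols behave as
designed (SI ≤ SD, fusion ≥ each single family), *not* that the method
reaches any particular accuracy on real faces.  On the default corpus the
class signal dominates the nuisance and all feature sets hit ceiling
under both protocols, so the SD/SI ordering holds as an equality; the
subject-nuisance test in the CV suite uses a harder synthetic construction
with a dominant subject shift to exercise a strict gap.

## Problem sizes and runtime choices

The shipped evaluation runs use 2 repetitions of 10-fold CV (the
`repeats` field accepts any count; per-repeat accuracies on the synthetic
corpus are near-deterministic, so the mean is stable at 2).  Oracle-
equivalence checks run the naive per-pixel implementations over 100
random 130 × 130 faces (LBP) and every interior pixel of 50 random
64 × 64 images at three thresholds (FAST).  Feature extraction for the
210-image corpus takes ~20 s and the full six-way CV grid a further
~1–2 min on one CPU.

## Known limitations

- Single-scale features; no pyramid, no scale invariance.
- The landmark detector is external by design; landmark noise is not
  modeled by the generator.
- Per-vector Z-scoring makes each sample's block moments identical (C, K);
  discrimination rests entirely on the *shape* of the vector, which is
  intended, but means the fused representation carries no overall-energy
  information.
- The region-balance remainder rule and deficit fill are deterministic
  but tie-break by score then position; on images with large exactly-flat
  areas the returned set can fall below n.
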
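# Methods

## Problem and data model

The package quantifies the spatial relationship between the pulmonary
veins (PV) and left atrium (LA) on labeled 3D volumes reconstructed from
fetal cardiac sweep-scan ultrasound. A volume is an integer grid with axis
order (depth, height, width); depth is the sweep direction, so slice k is
frame k. Canonical labels: 0 background, 1 LA, 2 PV, 3 confluent vein.
Labels are mutually exclusive by construction (one value per voxel); an
input dialect that presented overlapping PV/LA masks would be rejected at
validation rather than given a zero distance, preserving the PLD floor of
1.00. The confluent vein — the common venous channel behind the LA in
TAPVC — is the PV-class structure anatomically, so it is merged into the
PV mask by default for index computation; `merge_vein=False` keeps it
separate.

Voxel spacing metadata is read and ignored: all distances are isotropic
pixel units, which is the scale on which the indices are defined and
reported. Slice indices are 0-based internally, 1-based in result records.

## PLD

Per shared slice k (both structures non-empty), d_k is the exact minimum
Euclidean distance over all PV×LA pixel pairs, computed with a k-d tree
over the LA pixels queried by the PV pixels; distances are in-plane only,
never across slices. The quantile threshold t_q uses linear interpolation
between order statistics (numpy's `linear` method); `nearest` is available
behind the same interface and every output names the rule used. Inclusion
into D_q is `d ≤ t_q` — strict inequality would empty the subset for a
constant distance set. The default q = 100 retains every shared slice;
q is a parameter because small distance outliers (e.g. a single badly
segmented frame) can otherwise dominate a mean, and each result records q,
t_q and |D_q|.

## PLA

The PV orientation in a slice is the major axis of the moment-equivalent
ellipse: the principal eigenvector of the 2×2 second central-moment matrix
of the PV pixel coordinates. A slice is degenerate when the PV is a single
pixel or its two eigenvalues agree within a relative 1e-9 (isotropic
region, e.g. a filled square — no unique major axis), or when the PV and
LA centroids coincide within 1e-9 px. Degenerate slices are excluded and
reported with reasons; if all shared slices are degenerate the index is an
error, not a number. The folded angle is computed as
arccos(|cos θ|) with the cosine clamped to [−1, 1], which implements
min(θ, 180° − θ) and makes the result independent of the eigenvector's
sign.

## Dice and HD95

Dice is voxelwise 2TP/(2TP+FP+FN) over the whole volume for PV, LA and
the PV∪LA aggregate; both-empty masks give an undefined-metric flag, never
a silent 0 or 1. Surfaces are foreground voxels with at least one
background 6-neighbor, with out-of-bounds neighbors counted as background;
6-connectivity is the common voxel-surface convention and is stated here
because other choices change HD95 on thin structures. HD95 pools the two
directed nearest-surface distance sets and takes a single 95th percentile
of the union (same percentile rule as PLD), which is symmetric by
construction; the exact Hausdorff distance (max of directed maxima) is
also provided and upper-bounds HD95 — the test suite asserts this on
random pairs. Group summaries report mean Dice two ways, averaged over
the PV and LA structure scores and computed on the aggregate mask, since
per-video "mean Dice" can denote either; the columns are labeled
distinctly.

## Screening

The ROC positive class is TAPVC and the direction higher-is-positive for
both indices, fixed a priori from the indices' construction (divergence
raises both). A data-estimated direction would hide a model that inverts
the clinical trend; with the fixed direction such a model shows
AUC < 0.5. The threshold sweep and trapezoidal AUC come from
scikit-learn/numpy; every AUC is cross-checked at runtime against the
tie-corrected Mann-Whitney statistic U/(n₁n₀) (ties counted ½) and a
disagreement beyond 1e-12 is an error — the two are the same quantity, so
this guards the sweep against tie-handling mistakes. Group summaries use
the sample SD (n−1), undefined at n = 1. MAE matches model rows to
ground-truth rows by case and index and errors loudly on orphans. When
several sweep videos map to one case, `aggregate_per_case` averages them
under an explicit video→case map before ROC. A seeded percentile
bootstrap CI for the AUC is available but off by default.

## Phantom generator

The generator renders, per slice, the LA as a filled ellipse and the PV as
a horizontal bar (major axis = column direction), identical across a
centered band of `shared_slices` slices; the LA spans all slices so K is
exactly the band. The target angle is realized by placing the ellipse
center at bearing (sin α, cos α) from the bar centroid; the target
separation by scanning candidate ellipse offsets in 0.25-px steps,
rasterizing each and measuring the true nearest-pixel distance, keeping
the candidate closest to gap + 1. For gap = 0 the generator prefers a
placement with an exact distance-1 (4-adjacent) pair; when rasterization
at an oblique bearing never produces one, it instead overlaps the ellipse
minimally with the bar and carves the overlap out of the LA (PV wins),
which guarantees adjacency in every shared slice. With odd bar dimensions
the bar centroid has integer coordinates and the ellipse rasterization is
mirror-symmetric about its center, so the 0° and 90° configurations
realize their angles exactly; oblique angles carry rasterization error,
measured in tests at ≲ 0.3° and covered by the ±2° recovery guarantee
(gap recovery: ±0.5 px around gap + 1).

`jitter_sd` is a per-voxel boundary flip probability (clipped to [0, 1]):
boundary foreground pixels are removed and adjacent background pixels
added, each with probability p/2, so the expected geometry is unbiased;
flips never enter the other structure and never empty one. 0 is the
exact-geometry mode used by all analytic tests.

Cohort defaults emulate the clinically observed index regimes: normal
cases touch (gap ≡ 0) with angles N(37.8°, 7.72°); TAPVC cases draw gap
from N(1.64, 0.667) px — putting PLD near 2.64 ± 0.67 — and angles from
N(55.1°, 14.5°), with a confluent vein. Draws are truncated by clipping
(gap to [0, 12] px, angle to [0°, 90°]); per-case seeds are spawned
deterministically from one master seed, so a cohort is byte-identical
across runs.

What the phantoms do **not** emulate: grayscale ultrasound appearance,
speckle and shadowing, fetal cardiac motion between frames, anatomical
shape variation (the PV is always a straight bar, the LA an ellipse), and
segmentation-model failure modes beyond the provided erode / dilate /
translate / drop-slice perturbations. Passing phantom tests therefore
demonstrates the correctness of the measurement pipeline under its
geometric assumptions, not clinical screening performance; the tail of the
default TAPVC gap distribution can even reach 0 (a touching "TAPVC"
case), so perfect separation is not guaranteed on every sampled cohort.

## Numerical choices

- Percentile rule: linear interpolation, centralized so the nearest-rank
  alternative is a parameter, not a code change.
- Degeneracy tolerances: eigenvalue ratio 1 + 1e-9, centroid coincidence
  1e-9 px; cosines clamped before arccos.
- ROC/Mann-Whitney agreement tolerance 1e-12 (an internal consistency
  check, not a fit tolerance).
- Ranking ties in model comparison break by model name for determinism.
- NIfTI axis convention: the file's slowest-varying axis is depth, with a
  `depth_axis` override; the writer stores depth there so round trips are
  voxel-exact. The expected clinical resize of 128×128×160 is not
  enforced — shape is free.

## Problem sizes in the test suite

Oracle-equivalence suites run 100 seeded instances per operation with
masks of at most a few hundred foreground voxels, where brute-force
all-pairs computation is exact and fast. Screening behavior is checked on
50+50-case cohorts of 12×96×96 phantoms; the chance-level check averages
the AUC over three seeded replicate cohorts because a single 50+50 null
draw of the AUC has a standard deviation of about 0.06. These sizes make
the whole suite run in well under a minute while keeping every comparison
exact or statistically well-powered.

## Known limitations

- PLD/PLA are 2D-per-slice constructions; no 3D inter-slice distance
  variant is provided, matching the indices' definitions.
- Anisotropic voxel spacing is ignored by design; an in-plane spacing
  weighting would change the pixel-unit interpretation of the 1.00 floor.
- With the confluent vein merged into the PV class, the vein blob shifts
  the PV centroid and major axis, so TAPVC PLA values reflect the merged
  geometry rather than the bar's configured bearing — visible in the
  phantom cohorts as compressed TAPVC PLA variance.
- The moment major axis is undefined for isotropic regions; volumes whose
  PV is isotropic in every shared slice yield an error rather than an
  arbitrary angle.
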
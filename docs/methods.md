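# Methods

## The length estimator

The core quantity is the radicle length of a young (0–96 h) germinating
seed, read from a binary instance mask.  The estimator is *half the outer
contour length*: trace the mask's outer boundary, sum Euclidean distances
between consecutive boundary pixels (axis steps contribute 1 px, diagonal
steps √2), convert with the scale calibration `r` (mm per pixel), and halve.
For an elongated tube of arc length `L` and width `w`, the outer contour is
`2L + πw` up to digitization, so the estimate is `L + πw/2·r` — an additive
excess of roughly half the tube circumference (≈1.1–1.7 mm for 7–11 px
tubes at r = 0.1 mm/px), plus a small multiplicative digitization
overestimate (a few percent, angle-dependent for 8-connected boundaries).
The validation regression on synthetic radicles (5–50 mm) shows slope
≈ 1.05, intercept ≈ 1.4 mm, R² ≈ 0.998.

Conventions:

* units — `r` is physical-length-per-pixel (mm/px); perimeter = `Sp·r`;
  length `L = Sp·r/2`.  With this reading every row of the measurement has
  length units.
* tracing — 8-connected Moore boundary following on the **largest**
  connected foreground component; smaller fragments are discarded with a
  warning; interior holes are filled before tracing (the outer contour is
  the defined quantity).  Contour length is the Euclidean polygon length of
  the ordered boundary pixels, not a pixel count.
* degenerate masks (a single pixel, anything with fewer than three boundary
  points) yield `Sp = 0`, `L = 0`, with a warning rather than an error.
* no sub-pixel smoothing is applied by default, which keeps the tracer
  exactly checkable against an independent boundary-following oracle.

The estimator is valid while roots are unbranched and not entangled — the
early-germination regime.  It is *not* a skeleton length: no medial-axis
computation is involved, and late-stage laterals would inflate the contour.

## Synthetic trays

The generator emulates the study conditions end to end: trays of 36 seeds
on a 6×6 grid (±5 px jitter) on dark noisy filter paper (background ≈ 18 ±
5 grey levels), bright seed-body ellipses, and radicles rendered as
centerline polylines dilated to a 7–11 px width.  Images are 1800×1800 px
at r = 0.1 mm/px.

* **Germination**: per-seed Bernoulli draw; control probability 0.70.
  Onset times are lognormal (median 36 h, σ = 0.30), truncated to
  [12 h, 96 h] by resampling.
* **Elongation**: logistic in time after onset,
  `L(t) = Lmax·σ(rate·(t − tg − midpoint))` with rate 0.15 h⁻¹ and midpoint
  30 h, so length is exactly half the maximum 30 h after onset.  Per-seed
  maxima vary lognormally (CV 0.15) around the arm mean (control 40 mm).
* **Geometry**: each radicle coils outward around its own seed as an
  Archimedean spiral (start radius 37 px, inter-turn spacing 26 px, mild
  radial noise) — the curling of dish-confined radicles.  This confines
  every instance to its own grid cell, so instances never overlap and the
  tube never self-intersects (spacing > width), which keeps the
  half-contour estimator unbiased by construction.  A pixel-level overlap
  check with bounded re-jittering backs the guarantee.
* **Dose–response**: arms carry multiplicative modifiers of germination
  probability and mean maximum length.  The `paper_calibrated` preset sets
  the optimal-dose arm to control × 1.28 (probability) and × 1.42 (mean
  maximum length), with intermediate and supra-optimal doses shaped
  accordingly — so recovering those increases from the pipeline is a
  parameter-recovery experiment with known truth.
* **Randomness**: one master seed spawns per-(replicate, slot, channel)
  substreams via stable hashing.  Biology channels deliberately omit the
  arm from the key (common random numbers): paired arm contrasts are then
  estimated with far less sampling noise, and dose effects are coupled
  monotonically (raising the probability can only add germinating seeds).
  Even so, the germination-rate contrast at 108 seeds per arm retains an
  inherent SD of ~5 percentage points of relative increase — the honest
  binomial noise of the study size.
* **Schedule**: the preset captures every 8 h (12 frames over 96 h).  The
  planner itself handles any interval that divides the duration (the
  15–20 min intervals of real acquisition included); the coarse preset
  schedule is sufficient because the recovery analyses consume final rate
  and length plus onset times at frame resolution.

What the generator does **not** emulate: photorealistic texture, lighting
gradients, occlusion, root entanglement, branching, detection failures, or
segmentation noise beyond polygon quantization.  Passing recovery tests
therefore demonstrate correctness of the measurement chain on faithful
masks, not robustness of any upstream detector on real imagery.

Labels are written in the one-line-per-instance polygon dialect (class id
followed by vertex coordinates normalized by image width/height, six
decimals).  Polygons are taken from the 0.5 iso-contour of each mask and
simplified at 0.3 px tolerance; the round trip back to a mask keeps
IoU ≥ 0.95.

## Tracking and vigor metrics

Detections are assigned per frame to grid slots greedily by centroid
distance with a cap of half the grid pitch; a contested slot keeps the
nearer instance and the loser is reported.  A slot with no detection stays
at length 0 until first seen; later missing frames carry the last observed
length forward with a gap flag, and tracks with more than 25% gap frames
are excluded from dish summaries (count reported).

Defaults, all configurable: germination threshold 2 mm of measured radicle
(a common laboratory criterion); germination energy evaluated at 72 h;
germination-index days are 24 h bins with a partial final day counting as a
full day number.

## Statistics

Shapiro–Wilk (per group) and Levene's test (scipy default, median-centered)
are always computed and reported; deviations produce a warning but never
stop the ANOVA — the protocol relies on F-statistic robustness under the
balanced design, and the report keeps the caveat visible.  Two-way tables
use type-II sums of squares (identical to the textbook balanced
decomposition when cells are balanced; unbalanced input warns).  The
all-constant degenerate case is reported as F = 0, p = 1.  Tukey HSD uses
the studentized range at family level α; compact letters use the
insert-and-absorb construction and are provably consistent with the
significance matrix.

## Detector evaluation

AP uses all-point interpolation of the precision–recall curve (the integral
form), not 11-point sampling.  Matching is greedy per class in descending
confidence, one-to-one, best unmatched IoU above the threshold.  Box IoU is
computed on axis-aligned polygon bounds; mask IoU on polygon rasterizations
at label resolution.  The class mean runs over the union of predicted and
ground-truth classes; a class predicted with no ground truth contributes
AP 0.  The reference accuracy of a trained detector on real imagery is not
reproducible here (no dataset, no training); the evaluator is instead
verified on exactly solvable cases and invariants (perfect predictions →
1.0; hand-computed PR curves; added false positives never raise AP;
mAP50-95 ≤ mAP50).

## Architecture blocks

The ghost/SE/attention components are provided as standalone, composable
units with explicit weights rather than as an assembled trained network —
the verifiable surface is the cost algebra and the forward contracts.  Cost
and parameter accounting exclude biases and normalization parameters (the
convention is printed in the report).  The cheap ghost operation is a
depthwise d×d kernel per intrinsic map.  The shifted window variant uses a
cyclic shift without cross-window attention masking, so wrapped tokens
attend together — sufficient for the locality and shape contracts checked
here, simpler than a masked implementation.  Patch merging concatenates 2×2
neighborhoods (a pure value-preserving reshuffle) before the 4C→2C
projection.

## Problem sizes

Tests and the acceptance script run the calibrated recovery at its natural
size (2 arms × 3 dishes × 36 seeds, 12 frames) and the validation
regression at 100 radicles; dataset generation skips PNG encoding where
only labels and ground truth are consumed.  A full recovery run completes
in about a minute on one CPU.

## Known limitations

* The half-contour estimator carries an additive width-dependent excess;
  on the calibrated preset this biases the recovered length effect
  downward by ~1–3 percentage points of relative increase (ratio of two
  positively offset means).
* Tracking assumes a fixed grid; free-floating seeds or dish movement are
  out of scope.
* The generator's coiled geometry avoids entanglement by design; the
  toolkit does not attempt to resolve entangled late-stage roots.
* Germination-rate contrasts inherit binomial noise at the study's n; see
  the common-random-numbers note above.
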
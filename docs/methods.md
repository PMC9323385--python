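# Methods

This note documents the models, parameters, numerical choices and known
limitations of `toothbox` — what the procedure assumes, what the synthetic
phantom does and does not emulate, and where the design was genuinely open.

## The detection procedure

### Layer labeling and the anti-noise switch

A bottom-to-top axial CBCT stack traverses five z-regions in a fixed
anatomical order: lower no-tooth → lower crown → overlap (both dentitions
visible) → upper crown → upper no-tooth. A per-slice classifier only sees
three appearance classes (no-tooth / crown / overlap), so the 5-region
labeling is recovered by a monotone state machine: starting in the lower
no-tooth state, the machine advances to the next region at the first slice
of a run of at least `confirm_run` identical labels equal to the next
region's expected class. Labels that do not match the next expected class
are treated as noise and can never advance the state; the state never
retreats.

Assumptions: the scan actually is z-ordered bottom-to-top (a
`top_to_bottom` flag flips the sequence first), every region's class
appears in the stated order, and classifier errors are independent across
slices. Under independence, defeating the switch requires `confirm_run`
consecutive identical errors, probability `p**confirm_run` — 0.25% at
`p = 0.05, k = 2` and 0.0125% at `k = 3`.

Parameters: `confirm_run` defaults to 3 (the changed slice plus two
confirming followers); 2 trades a little noise robustness for one slice
less boundary latency. The switch index is defined as the *first* slice of
the confirmed run — the alternative (the slice after confirmation) would
systematically bias boundaries upward by `confirm_run − 1` slices.

Known limitation: a misclassification *adjacent to a true boundary* is
indistinguishable from a late/early transition; the boundary then shifts by
up to the burst length. This is intrinsic to any run-length rule. The only
transition where the shift is costly is crown → overlap, where a delayed
switch leaves an overlap slice holding one jaw's boxes instead of both.

### Key slices and propagation

Detection runs only on the 10th and 10th-from-last slice (1-based) of each
crown region. For crown regions shorter than 20 slices the offsets clamp
into the region and deduplicate, with a warning — clinically a crown region
at sub-half-millimeter slice spacing is ≥ 20 slices, so clamping marks an
unusually thin region rather than a normal case. Every other slice inherits
the box set of the nearest key slice of its own jaw (ties to the smaller
index); overlap slices take the union of the nearest lower-jaw and
upper-jaw sets. The nearest-key rule is a design choice; any slice-to-key
assignment that respects jaw identity would serve.

### Hierarchical detection

The detector is a *contract*: `detect(image, target, slice_index=None,
origin=(0,0)) → [(box, label, score)]`. The pipeline calls it twice per key
slice — once for the main area on the full image, once for the five blocks
on the main-area crop (results are mapped back to full-image coordinates
and clamped). Per block only the highest-scoring candidate above the score
threshold (default 0.5) survives; blocks without a candidate are *reported
missing*, never extrapolated from symmetry, and downstream division simply
skips them.

Two reference backends ship with the package:

- **Oracle backend** (tests, regression baselines): replays ground-truth
  boxes, optionally displaced by a uniform per-axis jitter in
  `[−j, +j]` px, seeded per slice and target. Jitter is positional (the
  box translates, its size is preserved), which gives the closed-form
  worst-case IoU `(W−j)(H−j) / ((W+j)(H+j))` against truth — ≈ 0.945 at
  2 px for the phantom's main box, hence the tested `> 0.9` bound.
- **Heuristic backend** (runs the pipeline without any training): 3-class
  Otsu threshold to isolate enamel-bright pixels, connected components
  above a minimum area, a parabola fitted to component centroids as the
  arch model, and assignment of each component to the nearest of 16
  canonical arc-length slots (slot widths proportional to mesiodistal
  crown widths), which map onto the 3+3+4+3+3 block layout. It assumes
  bright teeth on darker bone/background — phantom-like contrast — and is
  not a clinical detector.

A trainable single-stage CNN detector (416×416×3 input, 13×13 grid at
32 px stride, grayscale replicated to three channels) fits the same
contract; it is deliberately not part of the package's test surface
because no trained weights can ship with it.

The slice classifier is likewise a contract
(`classify(image, slice_index=None) → class`). The reference
`ThresholdSliceClassifier` thresholds the stack-normalized image at 0.65
and classifies by bright-area fraction (≥ 10% overlap, ≥ 2% crown, else
no-tooth) — values sized to the phantom's geometry, where one dentition's
crowns cover ~7% of the slice and two dentitions ~12%. Classifier
preprocessing is bilinear resize to 128×128 with per-stack min–max
normalization to [0, 1].

### Proportion-based division

A point inside a block box is addressed by the ratio
`λx = (x − x1)/(x2 − x)`, i.e. `x = (x1 + λx·x2)/(1 + λx)` (and likewise
for y). Each tooth stores a `(λx, λy)` pair for its box's left-top and
right-bottom corners plus a fractional safety margin `enlarge`
(default 0.05 per side, applied after the proportional corners, before
clamping to the image). An entry may instead carry an explicit affine form
`corner = a·near + b·far`; the shipped tooth-45 entry stores the published
coefficients (0.83/0.17, 0.72/0.28, 0.17/0.83, 0.28/0.72) exactly, with
the margin folded in. The affine and raw-lambda paths are both provided
and are *not* claimed to coincide: the published tooth-45 coefficients
differ from the raw evaluation of its published λ values ((1/6, 2/9) and
(5/6, 4/9) give x-fractions ≈ 0.143/0.857 and y-fractions ≈ 0.182/0.308),
because the published numbers absorb a calibration adjustment and an
unspecified enlargement.

The default (pre-calibration) table divides each block uniformly: the k-th
of n teeth (left→right in image coordinates, radiological convention —
configurable chirality, since display convention is not standardized) spans
width fractions `[k/n, (k+1)/n]`, nudged into (0, 1) by 0.005 because a
fraction of exactly 0 or 1 has no finite λ. The vertical span is
`[2/9, 4/9]` of block height for the lower jaw (the span implied by the
tooth-45 example's λy values) mirrored to `[5/9, 7/9]` for the upper jaw.
This table is a starting point, not a clinical fit.

**Calibration** is per-tooth, derivative-free coordinate descent on the
four λ values (multiplicative steps starting at ×2, halved when no
coordinate improves, stopping below 1e−4; λ clipped to [1e−4, 1e4]). The
objective is the mean IoU between the *pre-margin* generated box and the
ground-truth box across calibration samples, plus a 1e−3-weighted
normalized corner-distance term whose only job is to give the search a
direction while boxes are still disjoint (IoU ≡ 0 is a flat plateau); the
reported and stopping metric is pure mean IoU. Calibration stops once the
table-wide mean IoU reaches the target (default 0.85) or every step
underflows; failure to reach the target is a warning, not an exception.
Fitting the pre-margin box and adding `enlarge` afterwards keeps the margin
from being optimized away — the margin exists to absorb scan rotation,
malocclusion and detector jitter at prediction time, not to improve the
calibration score. Affine entries are converted losslessly to λ form
before fitting (rows sum to 1, so the far-corner coefficient is the
corner's fraction); a recalibrated affine entry receives the standard 0.05
margin because its own folded-in margin is not recoverable.

Division skips missing teeth without touching the other entries, so a
tooth's box is independent of any other tooth's missing-status by
construction.

### Evaluation

Matching is greedy in descending score with same-label, same-image
constraints at an IoU threshold (default 0.5); each ground-truth box is
consumed at most once. Precision, recall and F1 return 0 on 0/0. Average
precision integrates the monotone precision envelope over recall
(all-point interpolation; an 11-point variant is available since the mAP
protocol is a convention, not a fixed rule), and mAP averages over labels
with at least one ground-truth box. OIR rasterizes the detected box by the
pixel-center rule (pixel (i, j) inside iff `L ≤ j+0.5 < R` and
`T ≤ i+0.5 < B`), consistent with the half-open box-area convention
`area = (R−L)(B−T)`; an undetected tooth scores 0 and a truly missing
tooth is skipped from the per-image mean.

## The synthetic phantom

The generator renders what the pipeline actually consumes: a z-ordered
stack with five regions (default lengths (7, 10, 6, 10, 7) of 40 slices —
crown regions scaled down from clinical thickness to keep the default
stack small, and an overlap region comfortably longer than `confirm_run`,
since at 2–3 mm the occlusal overlap should not be defeatable by a single
misclassified slice), two parabolic arches (lower: apex (128, 45),
curvature 0.021, width 190 px; upper nested inside: apex (128, 82),
curvature 0.034, width 130 px), and elliptical crowns with anatomical
mesiodistal widths (≈ 7.5/6.5/7/7/7/10.5/10/9.5 mm for positions 1–8 at
the default 0.4 mm pixel spacing; upper teeth scaled ×0.8 so the nested
arches stay resolvable). Teeth sit at arc-length positions proportional to
their widths. Intensities before noise are 0.1 (background), 0.4 (bone
band), 0.9 (teeth) of the dynamic range; additive Gaussian noise
(σ = 0.02 of range) and uint8 output by default, uint16 optionally.
Metal artefacts are bright rays (plus a couple of near-black bands) drawn
from a chosen tooth's center to the image border at seeded random angles on
every slice where that tooth exists; ground truth is unchanged.

Ground truth is exact by construction: the mask is the rasterized ellipse,
the tooth box is the tight bounding box of the mask (so mask ⊆ box holds
identically under the pixel-center rule), block boxes are unions of member
tooth boxes, and the main area is the union of all tooth boxes.

What the phantom does **not** emulate — and therefore what passing tests
do not demonstrate about clinical data: reconstruction physics
(beam-hardening, scatter, partial-volume edges), root anatomy and
multi-rooted cross-sections, inter-patient anatomical variation, tilted or
malonccluded scans, adherent tooth edges, and intensity inhomogeneity.
Tests against the phantom validate the *procedure* (state machine,
geometry, calibration, propagation, metrics), not clinical detector
accuracy.

The truth-backed oracles define the synthetic study regime used by the
end-to-end checks: a classifier with 5% independent seeded label flips and
a detector with 2 px positional jitter. Under that regime the pipeline's
per-image mean OIR on toothed slices is typically ≈ 0.98–0.99; the
occasional flip adjacent to the crown→overlap boundary produces one or two
slices holding only half the expected boxes, which is the failure mode
discussed under layer labeling.

## Numerical and degenerate-input choices

- Box coordinates are continuous, origin top-left, half-open in both axes;
  VOC XML (1-based inclusive integers) converts via `L = xmin−1,
  T = ymin−1, R = xmax, B = ymax`, which preserves widths exactly.
- IoU of two zero-area boxes is 0 (not NaN); degenerate block boxes divide
  into degenerate tooth boxes with a warning rather than an error.
- Calibration tie-break: a candidate must improve the objective by more
  than 1e−12 to be accepted, making the descent deterministic.
- DICOM reading accepts only single-frame grayscale series; slices sort by
  `ImagePositionPatient[2]` (then `SliceLocation`), falling back to
  filename order with a warning when positions are absent; mixed shapes
  are a hard error.
- Problem sizes in the shipped tests: a 40-slice 256×256 phantom,
  calibration on 2–14 slices, 10³–10⁴ randomized property-test instances —
  sizes chosen so the full suite exercises every stage in seconds.

## Known limitations

- Proportion-based division presumes the block box is axis-aligned with
  the dental arch; rotated or severely maloccluded scans shift every tooth
  box (no perspective correction is attempted).
- Runs of ≥ 3 continuously missing teeth undermine the block detector's
  spatial prior; the procedure reports missing blocks but does not
  recover them.
- The heuristic backend's arc-slot assignment assumes a near-complete
  dentition; with edge teeth missing, normalization against the remaining
  span misassigns boundary teeth.
- The calibration stop-at-target rule means a table calibrated to the 0.85
  default can leave individual teeth poorly fitted once the *mean* crosses
  the target; request a higher target when per-tooth quality matters.
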
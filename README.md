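# toothbox

Hierarchical teeth detection on axial cone-beam CT (CBCT) slice stacks.

Locating every tooth with its own FDI-numbered bounding box is the first
step of most digital-dentistry pipelines (segmentation, implant planning,
automated charting), but detecting single teeth directly is fragile: teeth
of the same type look alike, missing teeth scramble label order, and metal
restorations throw bright streak artefacts across their neighbors.
`toothbox` implements a combined procedure that sidesteps these failure
modes by never asking a detector to tell tooth 16 from tooth 17:

1. **Layer labeling.** Each axial slice is classified into three appearance
   classes (no-tooth / crown / overlap) and the z-sequence is lifted into
   five anatomical regions (lower no-tooth, lower crown, overlap, upper
   crown, upper no-tooth) by an **anti-noise switch**: the region label
   advances only after a confirmed run of `k` consecutive identical
   new-class labels. With per-slice error rate `p` under an independent
   error model, a spurious switch needs `k` consecutive identical errors,
   probability `p**k` — 0.25% for `p = 0.05, k = 2`, 0.0125% for `k = 3`.
2. **Key slices.** Detection runs only on the 10th and 10th-from-last slice
   of each crown region (four slices per stack).
3. **Hierarchical detection.** On each key slice a pluggable detector first
   finds the *main area* (a tight box around all teeth), then the five
   anatomical *blocks* per jaw (incisors, right/left canine+premolars,
   right/left molars) inside its crop. Blocks are large, well-separated
   objects a single-stage grid detector (13×13 cells of 32 px on a 416 px
   input) handles comfortably.
4. **Proportion-based division.** Each block box `(L0, T0, R0, B0)` is cut
   into per-tooth boxes using position ratios: a point with ratio
   `λ = (x − x1)/(x2 − x)` lies at `x = (x1 + λ·x2)/(1 + λ)`. Every tooth
   stores one `(λx, λy)` pair per box corner; the shipped entry for tooth
   45 reproduces the published affine mapping
   `L = 0.83·L0 + 0.17·R0`, `T = 0.72·T0 + 0.28·B0`,
   `R = 0.17·L0 + 0.83·R0`, `B = 0.28·T0 + 0.72·B0`.
   Lambda tables are calibrated against ground-truth boxes by per-tooth
   coordinate descent until the mean IoU crosses a target (default 0.85),
   then enlarged by a small safety margin. A missing tooth is simply
   skipped — the other boxes do not move.
5. **Propagation.** All remaining slices inherit the tooth boxes of the
   nearest key slice of their own jaw; overlap slices take the union of
   both jaws' nearest key sets.
6. **Evaluation.** Precision, recall, F1, VOC-style mAP, and the **object
   inclusion ratio** `OIR = |A_M ∩ D_M| / |A_M|` — the fraction of a
   tooth's true pixel area covered by its detected box, with truly missing
   teeth skipped from the per-image mean.

Because clinical CBCT data cannot ship with the package, a first-class
synthetic **phantom generator** renders anatomically sized dental arches
(parabolic arches, elliptical crowns with realistic mesiodistal widths,
bone bands, metal-artefact streaks, noise) together with exact ground
truth, plus truth-backed oracle backends to exercise every stage
deterministically.

## Worked example

```python
import warnings
import numpy as np

from toothbox import (
    PhantomConfig, generate_stack, OracleSliceClassifier, OracleDetector,
    calibrate_lambdas, default_lambda_table, run_pipeline, block_teeth,
    OirInput, per_image_oir,
)

cfg = PhantomConfig(seed=7)                      # 40-slice, 256x256 phantom
stack, truth = generate_stack(cfg)

# calibrate the lambda table on one lower and one upper crown slice
samples = [
    (bbox, {t: truth.boxes[sl][t] for t in block_teeth(bid)})
    for sl in (10, 25)
    for bid, bbox in truth.block_boxes[sl].items()
]
table, mean_iou = calibrate_lambdas(samples, default_lambda_table(),
                                    target_mean_iou=0.99)
print(f"calibration mean IoU: {mean_iou:.4f}")

# realistic imperfection: 5% classifier label flips, 2 px detector jitter
classifier = OracleSliceClassifier(truth.class_labels, error_rate=0.05, seed=0)
detector = OracleDetector(truth, jitter_px=2.0, seed=0)
result = run_pipeline(stack, classifier, detector, table)
print(f"region boundaries: {result.labeling.boundaries}")
print(f"key slices: {result.key_slices}")

oirs = []
for i, boxes in result.tooth_boxes.items():
    if truth.masks[i]:
        bmap = dict(boxes)
        oirs.append(per_image_oir(
            [OirInput(truth.masks[i][t], bmap.get(t)) for t in truth.masks[i]]
        ))
print(f"mean OIR over {len(oirs)} toothed slices: {np.mean(oirs):.4f}")
```

Output:

```
calibration mean IoU: 0.9996
region boundaries: [8, 17, 23, 33]
key slices: [8, 16, 23, 32]
mean OIR over 26 toothed slices: 0.9888
```

Reading: the calibrated table reproduces the phantom's tooth boxes almost
exactly; despite the injected classifier flips the five z-regions are
recovered (boundaries at slices 8/17/23/33 vs. true 7/17/23/33 — one slice
of delay at a noisy transition), detection ran on only four key slices, and
after propagation the detected boxes cover ~98.9% of every tooth's true
pixel area on average.

The same flow is available from the shell:

```bash
toothbox simulate --out phantom/ --seed 7 --write-masks
toothbox calibrate --input phantom/ --out table.yaml --target-mean-iou 0.99
toothbox run --input phantom/ --out result.json --detector oracle \
    --lambda-table table.yaml
toothbox evaluate --pred pred.json --truth truth.json --masks phantom/
```

`--detector heuristic` swaps in the training-free reference backend
(Otsu threshold → connected components → arch fit → block grouping), which
also runs the pipeline end to end on phantom-like images.

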
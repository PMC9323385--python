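"""Proportion-based division of block boxes into per-tooth FDI boxes.

A point inside a block box ``(L0, T0, R0, B0)`` is addressed by position
ratios ``lambda_x = (x - x1) / (x2 - x)`` (and analogously for y), so the
point itself is ``x = (x1 + lambda_x * x2) / (1 + lambda_x)``.  Each tooth
of a block stores one lambda pair for its box's left-top corner and one for
its right-bottom corner; applying them to any detected block box yields the
tooth box, optionally enlarged by a fractional margin to absorb scan
rotation and malocclusion.

A tooth entry may instead carry an explicit affine form
``corner = a * near + b * far`` on the block coordinates, used for
published coefficient sets where margins were already folded in.  The
shipped lower-right second premolar (FDI 45) entry is such a set:
``L = 0.83 L0 + 0.17 R0``, ``T = 0.72 T0 + 0.28 B0``, ``R = 0.17 L0 +
0.83 R0``, ``B = 0.28 T0 + 0.72 B0``.

Lambda tables are calibrated against ground-truth tooth boxes by per-tooth
derivative-free coordinate descent maximizing mean IoU, stopping once the
table-wide mean IoU reaches a target (default 0.85) or the search step
underflows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml
from sklearn.base import BaseEstimator

from .geometry import (
    ALL_BLOCKS,
    BlockId,
    Box,
    Chirality,
    FdiTooth,
    Jaw,
    block_teeth,
    iou,
)
from .layers import LayerLabel, LayerLabeling

__all__ = [
    "LambdaPair",
    "ToothProportion",
    "LambdaTable",
    "TOOTH_45_AFFINE",
    "proportional_point",
    "tooth_box_from_block",
    "divide_block",
    "calibrate_lambdas",
    "propagate_boxes",
    "default_lambda_table",
    "ProportionDivider",
]

# Published affine coefficients for tooth 45: rows (L, T, R, B), each row
# (coefficient of near corner, coefficient of far corner) on (L0,R0) for x
# rows and (T0,B0) for y rows.
TOOTH_45_AFFINE: Tuple[Tuple[float, float], ...] = (
    (0.83, 0.17),
    (0.72, 0.28),
    (0.17, 0.83),
    (0.28, 0.72),
)


@dataclass(frozen=True)
class LambdaPair:
    """Position ratios of one point: ``lx = (x - x1)/(x2 - x)``, same for y."""

    lx: float
    ly: float

    def __post_init__(self) -> None:
        if not (self.lx > 0 and self.ly > 0):
            raise ValueError(f"lambdas must be positive, got {self!r}")
        if not (math.isfinite(self.lx) and math.isfinite(self.ly)):
            raise ValueError(f"lambdas must be finite, got {self!r}")

    @classmethod
    def from_fractions(cls, fx: float, fy: float) -> "LambdaPair":
        """Lambda pair of the point at width/height fractions (fx, fy)."""
        if not (0 < fx < 1 and 0 < fy < 1):
            raise ValueError("fractions must lie strictly inside (0, 1)")
        return cls(fx / (1 - fx), fy / (1 - fy))


@dataclass
class ToothProportion:
    """How one tooth's box is carved out of its block box."""

    tooth: FdiTooth
    left_top: LambdaPair
    right_bottom: LambdaPair
    enlarge: float = 0.0
    affine: Optional[Tuple[Tuple[float, float], ...]] = None

    def __post_init__(self) -> None:
        if self.enlarge < 0:
            raise ValueError("enlarge must be >= 0")
        if self.affine is not None:
            self.affine = tuple(tuple(float(v) for v in row) for row in self.affine)
            if len(self.affine) != 4 or any(len(r) != 2 for r in self.affine):
                raise ValueError("affine form needs 4 rows of 2 coefficients")

    def to_lambda_form(self) -> "ToothProportion":
        """Equivalent lambda-form entry (lossless when affine rows sum to 1).

        An affine row ``corner = a*near + b*far`` with ``a + b = 1`` places
        the corner at fraction ``b`` of the block extent, i.e.
        ``lambda = b / (1 - b)``; the margin is already folded into the
        coefficients, so the converted entry carries ``enlarge = 0``.
        """
        if self.affine is None:
            return self
        (_, fL), (_, fT), (_, fR), (_, fB) = self.affine
        return ToothProportion(
            self.tooth,
            LambdaPair.from_fractions(fL, fT),
            LambdaPair.from_fractions(fR, fB),
            enlarge=0.0,
        )


def proportional_point(box: Box, lp: LambdaPair) -> Tuple[float, float]:
    """The point at position ratios ``lp`` inside ``box``.

    ``x = (x1 + lx * x2) / (1 + lx)`` with ``x1 = L``, ``x2 = R``; y
    analogously with ``y1 = T``, ``y2 = B``.
    """
    x = (box.L + lp.lx * box.R) / (1.0 + lp.lx)
    y = (box.T + lp.ly * box.B) / (1.0 + lp.ly)
    return x, y


def tooth_box_from_block(
    block_box: Box,
    prop: ToothProportion,
    image_shape: Optional[Tuple[int, int]] = None,
) -> Box:
    """Apply one tooth's proportion entry to a detected block box.

    Lambda form: both corners via :func:`proportional_point`, then symmetric
    enlargement by ``prop.enlarge`` of the width/height per side.  Affine
    form: the stored coefficients applied directly (margins folded in).
    The result is clamped to the image bounds when given.
    """
    if block_box.area == 0.0:
        warnings.warn(
            f"degenerate block box {block_box.as_tuple()} for tooth "
            f"{prop.tooth.code}",
            stacklevel=2,
        )
    if prop.affine is not None:
        (aL, bL), (aT, bT), (aR, bR), (aB, bB) = prop.affine
        L = aL * block_box.L + bL * block_box.R
        T = aT * block_box.T + bT * block_box.B
        R = aR * block_box.L + bR * block_box.R
        B = aB * block_box.T + bB * block_box.B
    else:
        L, T = proportional_point(block_box, prop.left_top)
        R, B = proportional_point(block_box, prop.right_bottom)
        mw, mh = prop.enlarge * (R - L), prop.enlarge * (B - T)
        L, R = L - mw, R + mw
        T, B = T - mh, B + mh
    box = Box(min(L, R), min(T, B), max(L, R), max(T, B))
    if image_shape is not None:
        h, w = image_shape
        box = box.clamp(w, h)
    return box


@dataclass
class LambdaTable:
    """Per-tooth proportion entries, covering whole blocks."""

    entries: Dict[FdiTooth, ToothProportion] = field(default_factory=dict)

    def __contains__(self, tooth: FdiTooth) -> bool:
        return tooth in self.entries

    def __getitem__(self, tooth: FdiTooth) -> ToothProportion:
        return self.entries[tooth]

    def covered_blocks(self) -> List[BlockId]:
        return [
            b
            for b in ALL_BLOCKS
            if all(t in self.entries for t in block_teeth(b))
        ]

    # --- YAML serialization -------------------------------------------------

    def to_yaml(self, path) -> None:
        from pathlib import Path

        obj = {}
        for tooth, p in sorted(self.entries.items(), key=lambda kv: kv[0].code):
            entry = {
                "lt": [p.left_top.lx, p.left_top.ly],
                "rb": [p.right_bottom.lx, p.right_bottom.ly],
                "enlarge": p.enlarge,
            }
            if p.affine is not None:
                entry["affine"] = [list(r) for r in p.affine]
            obj[tooth.code] = entry
        Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "LambdaTable":
        from pathlib import Path

        obj = yaml.safe_load(Path(path).read_text())
        entries = {}
        for code, e in obj.items():
            tooth = FdiTooth.from_code(int(code))
            entries[tooth] = ToothProportion(
                tooth,
                LambdaPair(*[float(v) for v in e["lt"]]),
                LambdaPair(*[float(v) for v in e["rb"]]),
                enlarge=float(e.get("enlarge", 0.0)),
                affine=e.get("affine"),
            )
        return cls(entries)


def default_lambda_table(
    enlarge: float = 0.05, chirality: Chirality = Chirality.RADIOLOGICAL
) -> LambdaTable:
    """The pre-calibration table.

    The k-th of n teeth of a block (left to right in image coordinates)
    spans width fractions ``[k/n, (k+1)/n]`` (edges nudged into (0, 1) for a
    finite lambda) and height fractions [2/9, 4/9] for the lower jaw,
    mirrored to [5/9, 7/9] for the upper jaw — the vertical span of the
    published tooth-45 example's raw lambdas.  The published tooth-45
    affine entry overrides its slot.  Intended as a calibration starting
    point, not a clinically tuned table.
    """
    eps = 0.005
    entries: Dict[FdiTooth, ToothProportion] = {}
    for block in ALL_BLOCKS:
        teeth = block_teeth(block, chirality)
        n = len(teeth)
        fy_t, fy_b = (2 / 9, 4 / 9) if block.jaw is Jaw.LOWER else (5 / 9, 7 / 9)
        for k, tooth in enumerate(teeth):
            fx_l = max(k / n, eps)
            fx_r = min((k + 1) / n, 1 - eps)
            entries[tooth] = ToothProportion(
                tooth,
                LambdaPair.from_fractions(fx_l, fy_t),
                LambdaPair.from_fractions(fx_r, fy_b),
                enlarge=enlarge,
            )
    t45 = FdiTooth.from_code(45)
    entries[t45] = ToothProportion(
        t45,
        entries[t45].left_top,
        entries[t45].right_bottom,
        enlarge=0.0,
        affine=TOOTH_45_AFFINE,
    )
    return LambdaTable(entries)


def divide_block(
    block_box: Box,
    block: BlockId,
    table: LambdaTable,
    missing: FrozenSet[FdiTooth] = frozenset(),
    chirality: Chirality = Chirality.RADIOLOGICAL,
    image_shape: Optional[Tuple[int, int]] = None,
) -> List[Tuple[FdiTooth, Box]]:
    """One labeled box per non-missing tooth of the block.

    Each tooth's box depends only on its own table entry and the block box,
    so skipping a missing tooth never shifts its neighbors.
    """
    out = []
    for tooth in block_teeth(block, chirality):
        if tooth in missing:
            continue
        if tooth not in table:
            raise KeyError(
                f"lambda table has no entry for tooth {tooth.code} of {block!r}"
            )
        out.append((tooth, tooth_box_from_block(block_box, table[tooth], image_shape)))
    return out


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def _no_margin(prop: ToothProportion) -> ToothProportion:
    p = prop.to_lambda_form()
    return ToothProportion(p.tooth, p.left_top, p.right_bottom, enlarge=0.0)


def _tooth_mean_iou(
    prop: ToothProportion, samples: Sequence[Tuple[Box, Box]]
) -> float:
    """Mean IoU of the pre-margin proportional box against truth."""
    prop = _no_margin(prop)
    return float(
        np.mean([iou(tooth_box_from_block(bb, prop), truth) for bb, truth in samples])
    )


def _tooth_objective(
    prop: ToothProportion, samples: Sequence[Tuple[Box, Box]]
) -> float:
    """Search objective: mean IoU, with a small corner-proximity term so the
    descent has a direction to follow while generated and truth boxes are
    still disjoint (IoU identically 0 is a flat plateau)."""
    vals = []
    prop = _no_margin(prop)
    for bb, truth in samples:
        gen = tooth_box_from_block(bb, prop)
        v = iou(gen, truth)
        diag = math.hypot(bb.width, bb.height) or 1.0
        dist = sum(
            abs(g - t) for g, t in zip(gen.as_tuple(), truth.as_tuple())
        ) / (4.0 * diag)
        vals.append(v - 1e-3 * dist)
    return float(np.mean(vals))


def _optimize_tooth(
    prop: ToothProportion,
    samples: Sequence[Tuple[Box, Box]],
    min_step: float,
    lam_bounds: Tuple[float, float] = (1e-4, 1e4),
) -> ToothProportion:
    """Multiplicative coordinate descent on the 4 lambda values."""
    # an affine entry's folded-in margin does not survive refitting; the
    # recalibrated entry gets the standard division-time margin instead
    enlarge = 0.05 if prop.affine is not None else prop.enlarge
    prop = prop.to_lambda_form()
    prop = ToothProportion(prop.tooth, prop.left_top, prop.right_bottom, enlarge)
    params = [
        prop.left_top.lx,
        prop.left_top.ly,
        prop.right_bottom.lx,
        prop.right_bottom.ly,
    ]

    def build(p) -> ToothProportion:
        return ToothProportion(
            prop.tooth,
            LambdaPair(p[0], p[1]),
            LambdaPair(p[2], p[3]),
            enlarge=prop.enlarge,
        )

    best = _tooth_objective(build(params), samples)
    step = 1.0
    while step >= min_step:
        improved = False
        for i in range(4):
            for factor in (1.0 + step, 1.0 / (1.0 + step)):
                cand = params.copy()
                cand[i] = float(np.clip(cand[i] * factor, *lam_bounds))
                val = _tooth_objective(build(cand), samples)
                if val > best + 1e-12:
                    best, params = val, cand
                    improved = True
        if not improved:
            step *= 0.5
    return build(params)


def calibrate_lambdas(
    blocks_with_truth: Sequence[Tuple[Box, Mapping[FdiTooth, Box]]],
    init: LambdaTable,
    target_mean_iou: float = 0.85,
    min_step: float = 1e-4,
) -> Tuple[LambdaTable, float]:
    """Adjust lambda values until generated boxes fit ground truth.

    ``blocks_with_truth``: calibration samples, each a detected/true block
    box together with the true boxes of (some of) its teeth.  Per tooth, a
    derivative-free coordinate descent on its 4 lambda values maximizes the
    mean IoU between the generated *pre-margin* proportional box and truth
    (the safety enlargement is applied afterwards, at division time, to
    absorb scan rotation and detector jitter); calibration stops once the
    mean IoU over all covered teeth reaches ``target_mean_iou`` or every
    tooth's search step underflows.  Returns the table and the achieved
    mean IoU; failing to reach the target warns rather than raises.
    """
    per_tooth: Dict[FdiTooth, List[Tuple[Box, Box]]] = {}
    for block_box, truths in blocks_with_truth:
        for tooth, truth_box in truths.items():
            per_tooth.setdefault(tooth, []).append((block_box, truth_box))
    if not per_tooth:
        raise ValueError("no calibration samples supplied")
    for tooth in per_tooth:
        if tooth not in init:
            raise KeyError(f"init table has no entry for tooth {tooth.code}")

    table = LambdaTable(dict(init.entries))

    def overall() -> float:
        return float(
            np.mean(
                [_tooth_mean_iou(table[t], s) for t, s in per_tooth.items()]
            )
        )

    achieved = overall()
    for tooth, samples in sorted(per_tooth.items(), key=lambda kv: kv[0].code):
        if achieved >= target_mean_iou:
            break
        table.entries[tooth] = _optimize_tooth(table[tooth], samples, min_step)
        achieved = overall()
    if achieved < target_mean_iou:
        warnings.warn(
            f"lambda calibration reached mean IoU {achieved:.4f} "
            f"< target {target_mean_iou}",
            stacklevel=2,
        )
    return table, achieved


# ---------------------------------------------------------------------------
# Propagation across slices
# ---------------------------------------------------------------------------

def propagate_boxes(
    key_slice_boxes: Mapping[int, Sequence[Tuple[FdiTooth, Box]]],
    labeling: LayerLabeling,
) -> Dict[int, List[Tuple[FdiTooth, Box]]]:
    """Share the key slices' tooth boxes with every slice of the stack.

    Slices in a crown region or the adjacent no-tooth region take the box
    set of the nearest key slice of their own jaw; overlap-region slices
    take the union of the nearest lower-jaw and upper-jaw key sets.  Ties
    break toward the smaller slice index.
    """
    if not key_slice_boxes:
        raise ValueError("no key slices to propagate from")
    jaw_keys: Dict[Jaw, List[int]] = {Jaw.LOWER: [], Jaw.UPPER: []}
    for k in sorted(key_slice_boxes):
        label = labeling.layer_labels[k]
        if label == LayerLabel.LOWER_CROWN:
            jaw_keys[Jaw.LOWER].append(k)
        elif label == LayerLabel.UPPER_CROWN:
            jaw_keys[Jaw.UPPER].append(k)
        else:
            raise ValueError(f"key slice {k} lies outside the crown regions")

    def nearest(keys: List[int], i: int) -> int:
        if not keys:
            raise ValueError("no key slices available for this jaw")
        return min(keys, key=lambda k: (abs(k - i), k))

    jaw_of_region = {
        LayerLabel.LOWER_NO_TOOTH: Jaw.LOWER,
        LayerLabel.LOWER_CROWN: Jaw.LOWER,
        LayerLabel.UPPER_CROWN: Jaw.UPPER,
        LayerLabel.UPPER_NO_TOOTH: Jaw.UPPER,
    }
    out: Dict[int, List[Tuple[FdiTooth, Box]]] = {}
    for i, label in enumerate(labeling.layer_labels):
        if label == LayerLabel.OVERLAP:
            boxes = list(key_slice_boxes[nearest(jaw_keys[Jaw.LOWER], i)]) + list(
                key_slice_boxes[nearest(jaw_keys[Jaw.UPPER], i)]
            )
        else:
            boxes = list(key_slice_boxes[nearest(jaw_keys[jaw_of_region[label]], i)])
        out[i] = boxes
    return out


# ---------------------------------------------------------------------------
# sklearn-style wrapper
# ---------------------------------------------------------------------------

class ProportionDivider(BaseEstimator):
    """Estimator wrapper: ``fit`` calibrates the lambda table, ``predict``
    divides block boxes into per-tooth boxes.

    Parameters
    ----------
    init_table : LambdaTable or None
        Calibration starting point; ``None`` uses the shipped default.
    target_mean_iou : float
        Calibration stop threshold on the mean IoU over all teeth.
    enlarge : float
        Fractional per-side margin of the default table's entries.
    chirality : Chirality
        Image display convention for left-to-right tooth order.

    Attributes (after ``fit``)
    --------------------------
    table_ : LambdaTable — the calibrated table.
    mean_iou_ : float — achieved calibration mean IoU.
    """

    def __init__(
        self,
        init_table: Optional[LambdaTable] = None,
        target_mean_iou: float = 0.85,
        enlarge: float = 0.05,
        chirality: str = Chirality.RADIOLOGICAL.value,
    ):
        self.init_table = init_table
        self.target_mean_iou = target_mean_iou
        self.enlarge = enlarge
        self.chirality = chirality

    def fit(self, X: Sequence[Tuple[Box, Mapping[FdiTooth, Box]]], y=None):
        init = self.init_table or default_lambda_table(
            self.enlarge, Chirality(self.chirality)
        )
        self.table_, self.mean_iou_ = calibrate_lambdas(
            X, init, target_mean_iou=self.target_mean_iou
        )
        return self

    def predict(
        self,
        X: Sequence[Tuple[BlockId, Box]],
        missing: FrozenSet[FdiTooth] = frozenset(),
        image_shape: Optional[Tuple[int, int]] = None,
    ) -> List[List[Tuple[FdiTooth, Box]]]:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "table_")
        return [
            divide_block(
                box,
                block,
                self.table_,
                missing=missing,
                chirality=Chirality(self.chirality),
                image_shape=image_shape,
            )
            for block, box in X
        ]
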
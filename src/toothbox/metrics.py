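"""Detection evaluation: matching, precision/recall/F1, mAP, and OIR.

Definitions: ``precision = N_TP / (N_TP + N_FP)``, ``recall = N_TP /
(N_TP + N_FN)``, ``F1 = 2 P R / (P + R)``; zero-denominator cases return 0.
Average precision is the area under the precision-recall curve of the
score-ranked detections (all-point interpolation by default, the 11-point
variant optionally), and mAP averages it over labels with at least one
ground-truth box.

OIR (object inclusion ratio) measures whether a detected box covers its
object: ``OIR = |A_M intersect D_M| / |A_M|`` for the true pixel area A_M of
object M and its detected box D_M; a box containing none of the object
scores 0, and teeth missing from an image are skipped when averaging.
Boxes are rasterized by the pixel-center rule (pixel (i, j) is inside iff
``L <= j + 0.5 < R`` and ``T <= i + 0.5 < B``), consistent with the
half-open box area convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .geometry import Box, iou

__all__ = [
    "MatchResult",
    "match_detections",
    "precision_recall_f1",
    "average_precision",
    "mean_average_precision",
    "OirInput",
    "oir",
    "per_image_oir",
    "rasterize_box",
]

# Prediction: (label, box, score); Truth: (label, box).  For multi-image
# evaluation, prepend the image id to the label-matching via the
# ``image_ids`` arguments of the AP helpers.
Pred = Tuple[str, Box, float]
Truth = Tuple[str, Box]


@dataclass
class MatchResult:
    n_tp: int
    n_fp: int
    n_fn: int
    pairs: List[Tuple[int, int, float]] = field(default_factory=list)
    """Matched (prediction index, truth index, IoU) triples."""


def match_detections(
    pred: Sequence[Pred],
    truth: Sequence[Truth],
    iou_thresh: float = 0.5,
    score_thresh: float = 0.5,
) -> MatchResult:
    """Greedy matching in descending score order.

    Predictions scoring below ``score_thresh`` are negatives.  A positive
    prediction is a true positive if some not-yet-matched ground-truth box
    with the same label has IoU >= ``iou_thresh`` (the best such box is
    consumed); otherwise a false positive.  Unmatched truths are false
    negatives.
    """
    if not 0.0 < iou_thresh <= 1.0:
        raise ValueError(f"iou_thresh must be in (0, 1], got {iou_thresh}")
    order = sorted(
        range(len(pred)), key=lambda i: (-pred[i][2], i)
    )  # stable by input order on ties
    matched_truth = [False] * len(truth)
    pairs: List[Tuple[int, int, float]] = []
    n_tp = n_fp = 0
    for i in order:
        label, box, score = pred[i]
        if score < score_thresh:
            continue
        best_j, best_iou = -1, 0.0
        for j, (tlabel, tbox) in enumerate(truth):
            if matched_truth[j] or tlabel != label:
                continue
            v = iou(box, tbox)
            if v >= iou_thresh and v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            matched_truth[best_j] = True
            pairs.append((i, best_j, best_iou))
            n_tp += 1
        else:
            n_fp += 1
    n_fn = matched_truth.count(False)
    return MatchResult(n_tp, n_fp, n_fn, pairs)


def precision_recall_f1(m: MatchResult) -> Tuple[float, float, float]:
    """Precision, recall and F1 from match counts; 0/0 cases return 0."""
    p = m.n_tp / (m.n_tp + m.n_fp) if (m.n_tp + m.n_fp) else 0.0
    r = m.n_tp / (m.n_tp + m.n_fn) if (m.n_tp + m.n_fn) else 0.0
    f1 = 2 * p * r / (p + r) if (p + r) else 0.0
    return p, r, f1


def _ranked_tp_flags(
    preds: Sequence[Tuple[int, Box, float]],
    truths: Sequence[Tuple[int, Box]],
    iou_thresh: float,
) -> List[bool]:
    """TP/FP flag per prediction in descending score order (one label).

    Entries carry their image id; matching never crosses images and each
    truth box is consumed at most once.
    """
    order = sorted(range(len(preds)), key=lambda i: (-preds[i][2], i))
    matched = [False] * len(truths)
    flags = []
    for i in order:
        img, box, _ = preds[i]
        best_j, best_iou = -1, 0.0
        for j, (timg, tbox) in enumerate(truths):
            if matched[j] or timg != img:
                continue
            v = iou(box, tbox)
            if v >= iou_thresh and v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            matched[best_j] = True
            flags.append(True)
        else:
            flags.append(False)
    return flags


def average_precision(
    preds: Sequence[Tuple[int, Box, float]],
    truths: Sequence[Tuple[int, Box]],
    iou_thresh: float = 0.5,
    interp: str = "all",
) -> float:
    """Average precision for one label over (image id, box[, score]) entries.

    ``interp='all'``: area under the monotone precision envelope over
    recall (VOC 2010 style).  ``interp='11point'``: mean of the envelope at
    recalls 0, 0.1, ..., 1.
    """
    if not truths:
        raise ValueError("average_precision needs at least one ground-truth box")
    flags = _ranked_tp_flags(preds, truths, iou_thresh)
    tp = np.cumsum([f for f in flags]) if flags else np.array([])
    n = np.arange(1, len(flags) + 1)
    recall = tp / len(truths) if len(flags) else np.array([])
    precision = tp / n if len(flags) else np.array([])

    mrec = np.concatenate([[0.0], recall, [recall[-1] if len(recall) else 0.0]])
    mpre = np.concatenate([[0.0], precision, [0.0]])
    # monotone non-increasing precision envelope
    for k in range(len(mpre) - 2, -1, -1):
        mpre[k] = max(mpre[k], mpre[k + 1])
    if interp == "all":
        idx = np.where(mrec[1:] != mrec[:-1])[0]
        return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))
    if interp == "11point":
        levels = np.linspace(0.0, 1.0, 11)
        vals = []
        for r in levels:
            sel = mrec[1:-1] >= r - 1e-12
            vals.append(float(mpre[1:-1][sel].max()) if sel.any() else 0.0)
        return float(np.mean(vals))
    raise ValueError(f"unknown AP interpolation {interp!r}")


def mean_average_precision(
    preds: Sequence[Tuple[int, str, Box, float]],
    truths: Sequence[Tuple[int, str, Box]],
    iou_thresh: float = 0.5,
    interp: str = "all",
) -> Tuple[float, Dict[str, float]]:
    """Unweighted mean AP over labels with >= 1 ground-truth box.

    Entries are ``(image id, label, box[, score])``; returns (mAP, per-label
    AP).
    """
    labels = sorted({t[1] for t in truths})
    if not labels:
        raise ValueError("mean_average_precision needs ground-truth boxes")
    per_label = {}
    for label in labels:
        p = [(img, box, s) for img, lbl, box, s in preds if lbl == label]
        t = [(img, box) for img, lbl, box in truths if lbl == label]
        per_label[label] = average_precision(p, t, iou_thresh, interp)
    return float(np.mean(list(per_label.values()))), per_label


# ---------------------------------------------------------------------------
# Object inclusion ratio
# ---------------------------------------------------------------------------

@dataclass
class OirInput:
    """One tooth's true pixel mask and its detected box (None = undetected)."""

    mask: np.ndarray
    box: Optional[Box]
    missing: bool = False


def rasterize_box(box: Box, shape: Tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the box."""
    h, w = shape
    ys = np.arange(h) + 0.5
    xs = np.arange(w) + 0.5
    inside_y = (ys >= box.T) & (ys < box.B)
    inside_x = (xs >= box.L) & (xs < box.R)
    return inside_y[:, None] & inside_x[None, :]


def oir(inp: OirInput) -> float:
    """Fraction of the object's true area covered by its detected box."""
    mask = np.asarray(inp.mask, dtype=bool)
    total = int(mask.sum())
    if total == 0:
        if inp.missing:
            raise ValueError("missing teeth are skipped, not scored")
        raise ValueError("empty object mask for a tooth not flagged missing")
    if inp.box is None:
        return 0.0
    covered = int((mask & rasterize_box(inp.box, mask.shape)).sum())
    return covered / total


def per_image_oir(inputs: Sequence[OirInput]) -> float:
    """Mean OIR over the non-missing teeth of one image."""
    vals = [oir(inp) for inp in inputs if not inp.missing]
    if not vals:
        raise ValueError("no non-missing teeth to evaluate")
    return float(np.mean(vals))
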
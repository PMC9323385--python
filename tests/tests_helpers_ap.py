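"""Independent average-precision oracle used by the test suite.

Enumerates the precision-recall curve prefix by prefix, recomputing TP/FP
from scratch for every prefix of the score-ranked predictions, and
integrates the monotone precision envelope over the observed recall steps.
Deliberately naive (O(n^3)) and written without reference to the library's
AP implementation.
"""

from toothbox.geometry import iou


def brute_force_ap_reference(preds, truths, iou_thresh):
    order = sorted(range(len(preds)), key=lambda i: (-preds[i][2], i))
    points = []
    for cut in range(1, len(order) + 1):
        used = set()
        tp = 0
        for i in order[:cut]:
            img, box, _ = preds[i]
            best, best_iou = None, 0.0
            for j, (timg, tbox) in enumerate(truths):
                if j in used or timg != img:
                    continue
                v = iou(box, tbox)
                if v >= iou_thresh and v > best_iou:
                    best, best_iou = j, v
            if best is not None:
                used.add(best)
                tp += 1
        points.append((tp / len(truths), tp / cut))
    ap = 0.0
    prev_r = 0.0
    for r in sorted({r for r, _ in points}):
        if r <= prev_r:
            continue
        ap += (r - prev_r) * max(p for rr, p in points if rr >= r)
        prev_r = r
    return ap
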
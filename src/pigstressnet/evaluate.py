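"""Detection evaluation: AP@0.5, PR curves, and a confusion matrix.

Matching is per class and greedy: predictions are sorted by descending
confidence (ties broken by box index for determinism) and each is
matched to the unmatched ground truth of the same class with the
highest IoU, provided it reaches the threshold.  AP uses 101-point
interpolation by default (11-point selectable).  The confusion matrix
has one extra row/column for background: entry (i, j) counts ground
truths of class i predicted as class j; unmatched ground truths count
in (i, background); unmatched predictions count in (background, j).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .losses import iou as box_iou


@dataclass
class EvalResult:
    per_class_ap: dict
    map50: float
    precision: dict          # class -> array over the PR sweep
    recall: dict
    confusion: np.ndarray    # (C+1, C+1), last index = background

    def normalized_confusion(self) -> np.ndarray:
        m = self.confusion.astype(np.float64)
        rows = m.sum(axis=1, keepdims=True)
        return np.divide(m, rows, out=np.zeros_like(m), where=rows > 0)


def _match_greedy(preds, gts, iou_thr):
    """preds: (conf-sorted) list of boxes; returns list of matched gt index or -1."""
    taken = set()
    matches = []
    for pb in preds:
        best, best_iou = -1, iou_thr
        for gi, gb in enumerate(gts):
            if gi in taken:
                continue
            v = box_iou(np.asarray(pb, dtype=np.float64), np.asarray(gb, dtype=np.float64))
            if v >= best_iou:
                best, best_iou = gi, v
        if best >= 0:
            taken.add(best)
        matches.append(best)
    return matches


def average_precision(tp: np.ndarray, conf: np.ndarray, n_gt: int,
                      n_points: int = 101) -> tuple:
    """AP by interpolated precision over recall; returns (ap, precision, recall).

    ``tp`` flags each prediction (confidence-descending) as true
    positive; ``n_gt`` is the number of ground-truth objects.
    """
    if n_gt == 0:
        return (0.0, np.zeros(0), np.zeros(0))
    order = np.lexsort((np.arange(len(conf)), -conf))
    tp = np.asarray(tp, dtype=np.float64)[order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1.0 - tp)
    recall = cum_tp / n_gt
    precision = cum_tp / np.maximum(cum_tp + cum_fp, 1e-12)
    levels = np.linspace(0.0, 1.0, n_points)
    interp = np.zeros_like(levels)
    for i, r in enumerate(levels):
        mask = recall >= r
        interp[i] = precision[mask].max() if mask.any() else 0.0
    return float(interp.mean()), precision, recall


def evaluate(predictions, ground_truths, n_classes: int = 5,
             iou_thr: float = 0.5, n_points: int = 101) -> EvalResult:
    """Evaluate detections against labels over a set of images.

    ``predictions``: per image, a list of dicts {box, cls, conf};
    ``ground_truths``: per image, a list of dicts {box, cls}.
    """
    per_class_records = {c: [] for c in range(n_classes)}   # (conf, tp)
    n_gt = {c: 0 for c in range(n_classes)}
    confusion = np.zeros((n_classes + 1, n_classes + 1), dtype=np.int64)

    for preds, gts in zip(predictions, ground_truths):
        order = sorted(range(len(preds)),
                       key=lambda i: (-preds[i]["conf"], i))
        preds_sorted = [preds[i] for i in order]
        for c in range(n_classes):
            n_gt[c] += sum(1 for g in gts if g["cls"] == c)
        # per-class greedy matching for the PR statistics
        for c in range(n_classes):
            pc = [p for p in preds_sorted if p["cls"] == c]
            gc = [g["box"] for g in gts if g["cls"] == c]
            matches = _match_greedy([p["box"] for p in pc], gc, iou_thr)
            for p, m in zip(pc, matches):
                per_class_records[c].append((p["conf"], 1.0 if m >= 0 else 0.0))
        # class-agnostic localisation matching for the confusion matrix
        matches = _match_greedy([p["box"] for p in preds_sorted],
                                [g["box"] for g in gts], iou_thr)
        gt_seen = set()
        for p, m in zip(preds_sorted, matches):
            if m >= 0:
                confusion[gts[m]["cls"], p["cls"]] += 1
                gt_seen.add(m)
            else:
                confusion[n_classes, p["cls"]] += 1
        for gi, g in enumerate(gts):
            if gi not in gt_seen:
                confusion[g["cls"], n_classes] += 1

    per_class_ap, precision, recall = {}, {}, {}
    for c in range(n_classes):
        rec = per_class_records[c]
        conf = np.array([r[0] for r in rec])
        tp = np.array([r[1] for r in rec])
        ap, p_arr, r_arr = average_precision(tp, conf, n_gt[c], n_points)
        per_class_ap[c] = ap
        precision[c], recall[c] = p_arr, r_arr
    present = [c for c in range(n_classes) if n_gt[c] > 0]
    map50 = float(np.mean([per_class_ap[c] for c in present])) if present else 0.0
    return EvalResult(per_class_ap, map50, precision, recall, confusion)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float = 0.45):
    """Greedy non-maximum suppression; returns kept indices."""
    if len(boxes) == 0:
        return np.zeros(0, dtype=np.int64)
    order = np.lexsort((np.arange(len(scores)), -scores))
    b = np.asarray(boxes, dtype=np.float64)[order]
    x1, y1, x2, y2 = b[:, 0], b[:, 1], b[:, 2], b[:, 3]
    areas = (x2 - x1) * (y2 - y1)
    keep = []
    alive = np.ones(len(b), dtype=bool)
    for i in range(len(b)):
        if not alive[i]:
            continue
        keep.append(order[i])
        rest = np.nonzero(alive[i + 1:])[0] + i + 1
        if rest.size == 0:
            continue
        iw = np.clip(np.minimum(x2[i], x2[rest]) - np.maximum(x1[i], x1[rest]), 0, None)
        ih = np.clip(np.minimum(y2[i], y2[rest]) - np.maximum(y1[i], y1[rest]), 0, None)
        inter = iw * ih
        iou_v = inter / np.maximum(areas[i] + areas[rest] - inter, 1e-12)
        alive[rest[iou_v > iou_thr]] = False
    return np.array(keep, dtype=np.int64)
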
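"""Detection evaluation: IoU, greedy matching, P/R, AP, mAP, confusion matrix.

Conventions: predictions are matched to ground truth per image, greedily in
descending confidence, requiring the same class and IoU at or above the
threshold; each ground-truth box is matched at most once.  Precision is
TP/(TP+FP) and recall TP/(TP+FN), both defined as 1.0 when their
denominator is empty.  Average precision integrates the precision envelope
over recall with 101-point interpolation (an all-point variant is
available), mAP50:95 averages AP over IoU 0.50..0.95 in 0.05 steps, and
class means are unweighted.  Classes without ground truth are excluded
from the mean.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "BoxPred",
    "BoxGT",
    "EvalCounts",
    "EvalSummary",
    "iou",
    "match_detections",
    "precision",
    "recall",
    "average_precision",
    "map50_95",
    "confusion_matrix",
    "evaluate_detections",
    "write_report_csv",
    "IOU_GRID",
]

IOU_GRID = tuple(np.round(np.arange(0.5, 0.96, 0.05), 2))


@dataclass(frozen=True)
class BoxPred:
    """One prediction: corner-format box (pixels), class and confidence."""

    image_id: int
    class_id: int
    confidence: float
    box: tuple[float, float, float, float]  # x1, y1, x2, y2


@dataclass(frozen=True)
class BoxGT:
    image_id: int
    class_id: int
    box: tuple[float, float, float, float]


@dataclass
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0


def iou(a, b) -> float:
    """Intersection-over-union of two corner-format boxes; 0 for degenerate."""
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    area_a = max(ax2 - ax1, 0.0) * max(ay2 - ay1, 0.0)
    area_b = max(bx2 - bx1, 0.0) * max(by2 - by1, 0.0)
    union = area_a + area_b - inter
    return float(inter / union) if union > 0 else 0.0


def _greedy_match(preds, gts, iou_thr, same_class=True):
    """Greedy confidence-descending matching.

    Returns (tp_flags aligned with confidence-sorted preds, sorted pred
    order, matches as (pred_idx, gt_idx) pairs in original indexing).
    """
    order = sorted(range(len(preds)), key=lambda i: -preds[i].confidence)
    taken = [False] * len(gts)
    tp_flags = np.zeros(len(preds), dtype=bool)
    matches = []
    for rank, pi in enumerate(order):
        p = preds[pi]
        best, best_iou = -1, iou_thr
        for gi, g in enumerate(gts):
            if taken[gi] or g.image_id != p.image_id:
                continue
            if same_class and g.class_id != p.class_id:
                continue
            v = iou(p.box, g.box)
            if v >= best_iou:
                best, best_iou = gi, v
        if best >= 0:
            taken[best] = True
            tp_flags[rank] = True
            matches.append((pi, best))
    return tp_flags, order, matches


def match_detections(preds, gts, iou_thr: float = 0.5):
    """Counts plus the (pred, gt) assignment for one prediction/gt set."""
    tp_flags, _, matches = _greedy_match(preds, gts, iou_thr)
    tp = int(tp_flags.sum())
    return EvalCounts(tp=tp, fp=len(preds) - tp, fn=len(gts) - tp), matches


def precision(c: EvalCounts) -> float:
    return c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 1.0


def recall(c: EvalCounts) -> float:
    return c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 1.0


def average_precision(preds, gts, iou_thr: float = 0.5,
                      interpolation: str = "101point") -> float:
    """AP for one class across images at one IoU threshold."""
    if not gts:
        return float("nan")
    if not preds:
        return 0.0
    tp_flags, _, _ = _greedy_match(preds, gts, iou_thr)
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(~tp_flags)
    rec = tp_cum / len(gts)
    prec = tp_cum / (tp_cum + fp_cum)
    if interpolation == "101point":
        grid = np.linspace(0.0, 1.0, 101)
        # precision envelope: best precision achieved at recall >= r
        prec_env = np.maximum.accumulate(prec[::-1])[::-1]
        idx = np.searchsorted(rec, grid, side="left")
        vals = np.where(idx < len(prec_env), prec_env[np.minimum(idx, len(prec_env) - 1)], 0.0)
        ap = float(vals.mean())
        return ap
    if interpolation == "allpoint":
        mrec = np.concatenate([[0.0], rec, [1.0]])
        mpre = np.concatenate([[1.0], prec, [0.0]])
        mpre = np.maximum.accumulate(mpre[::-1])[::-1]
        changed = np.nonzero(mrec[1:] != mrec[:-1])[0]
        return float(np.sum((mrec[changed + 1] - mrec[changed]) * mpre[changed + 1]))
    raise ValueError(f"unknown interpolation {interpolation!r}")


def _per_class(preds, gts, class_id):
    return ([p for p in preds if p.class_id == class_id],
            [g for g in gts if g.class_id == class_id])


def map50_95(preds, gts, num_classes: int, interpolation: str = "101point") -> float:
    vals = []
    for c in range(num_classes):
        pc, gc = _per_class(preds, gts, c)
        if not gc:
            continue
        aps = [average_precision(pc, gc, t, interpolation) for t in IOU_GRID]
        vals.append(float(np.mean(aps)))
    return float(np.mean(vals)) if vals else float("nan")


def confusion_matrix(preds, gts, num_classes: int,
                     conf_thr: float = 0.25, iou_thr: float = 0.5) -> np.ndarray:
    """(K+1)x(K+1) counts; rows = predicted class (+background), cols = true.

    Matching is class-agnostic (greedy by confidence on IoU alone) so
    cross-class confusions land off-diagonal; an unmatched prediction
    increments (pred, background) and an unmatched ground truth increments
    (background, true).
    """
    kept = [p for p in preds if p.confidence >= conf_thr]
    mat = np.zeros((num_classes + 1, num_classes + 1), dtype=int)
    tp_flags, order, matches = _greedy_match(kept, gts, iou_thr, same_class=False)
    matched_preds = {pi for pi, _ in matches}
    matched_gts = {gi for _, gi in matches}
    for pi, gi in matches:
        mat[kept[pi].class_id, gts[gi].class_id] += 1
    for pi, p in enumerate(kept):
        if pi not in matched_preds:
            mat[p.class_id, num_classes] += 1
    for gi, g in enumerate(gts):
        if gi not in matched_gts:
            mat[num_classes, g.class_id] += 1
    return mat


@dataclass
class EvalSummary:
    class_names: list[str]
    instances: list[int]
    per_class_p: list[float]
    per_class_r: list[float]
    per_class_ap50: list[float]
    per_class_ap50_95: list[float]
    confusion: np.ndarray
    map50: float
    map50_95: float

    def rows(self):
        yield ("all", sum(self.instances),
               float(np.mean([p for p, n in zip(self.per_class_p, self.instances) if n])),
               float(np.mean([r for r, n in zip(self.per_class_r, self.instances) if n])),
               self.map50, self.map50_95)
        for i, name in enumerate(self.class_names):
            yield (name, self.instances[i], self.per_class_p[i], self.per_class_r[i],
                   self.per_class_ap50[i], self.per_class_ap50_95[i])


def evaluate_detections(preds, gts, class_names: list[str],
                        conf_thr: float = 0.25, iou_thr: float = 0.5,
                        interpolation: str = "101point") -> EvalSummary:
    k = len(class_names)
    inst, ps, rs, ap50s, ap95s = [], [], [], [], []
    for c in range(k):
        pc, gc = _per_class(preds, gts, c)
        inst.append(len(gc))
        counts, _ = match_detections([p for p in pc if p.confidence >= conf_thr], gc, iou_thr)
        ps.append(precision(counts))
        rs.append(recall(counts))
        if gc:
            ap50s.append(average_precision(pc, gc, 0.5, interpolation))
            ap95s.append(float(np.mean([
                average_precision(pc, gc, t, interpolation) for t in IOU_GRID
            ])))
        else:
            ap50s.append(float("nan"))
            ap95s.append(float("nan"))
    valid50 = [a for a, n in zip(ap50s, inst) if n]
    valid95 = [a for a, n in zip(ap95s, inst) if n]
    return EvalSummary(
        class_names=list(class_names),
        instances=inst,
        per_class_p=ps,
        per_class_r=rs,
        per_class_ap50=ap50s,
        per_class_ap50_95=ap95s,
        confusion=confusion_matrix(preds, gts, k, conf_thr, iou_thr),
        map50=float(np.mean(valid50)) if valid50 else float("nan"),
        map50_95=float(np.mean(valid95)) if valid95 else float("nan"),
    )


def write_report_csv(summary: EvalSummary, path) -> None:
    """Per-class report with the standard table schema."""
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["Class", "Instances", "P", "R", "mAP50", "mAP50-95"])
        for row in summary.rows():
            wr.writerow([row[0], row[1]] + [f"{v:.4f}" if v == v else "" for v in row[2:]])


def plot_pr_curves(preds, gts, class_names, path, iou_thr: float = 0.5):  # pragma: no cover
    """Optional PR-curve rendering (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for c, name in enumerate(class_names):
        pc, gc = _per_class(preds, gts, c)
        if not gc:
            continue
        tp_flags, _, _ = _greedy_match(pc, gc, iou_thr)
        tp_cum = np.cumsum(tp_flags)
        fp_cum = np.cumsum(~tp_flags)
        ax.plot(tp_cum / len(gc), tp_cum / np.maximum(tp_cum + fp_cum, 1), label=name)
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.05)
    ax.legend(fontsize=6)
    fig.savefig(path, dpi=120)
    plt.close(fig)
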
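"""Independent reference implementations used only as test oracles.

Each oracle is deliberately written on a different path from the package
implementation: brute-force enumeration, per-cutoff recounting, or direct
closed forms, so agreement is evidence rather than tautology.
"""

from __future__ import annotations

import numpy as np


def median_by_sort(values: np.ndarray) -> float:
    """Median via full sort; even count -> mean of the two middle values."""
    s = np.sort(values.ravel())
    n = s.size
    if n % 2:
        return float(s[n // 2])
    return float((s[n // 2 - 1] + s[n // 2]) / 2)


def conv_flops_ref(h: int, w: int, cin_per_group: int, cout: int, kh: int, kw: int) -> int:
    return 2 * h * w * (cin_per_group * kh * kw + 1) * cout


def iou_ref(a, b) -> float:
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    ua = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return inter / ua if ua > 0 else 0.0


def _match_count(preds, gts, iou_thr):
    """Greedy confidence-descending matching; returns TP count."""
    taken = set()
    tp = 0
    for p in sorted(preds, key=lambda q: -q.confidence):
        best, best_v = None, iou_thr
        for gi, g in enumerate(gts):
            if gi in taken or g.image_id != p.image_id or g.class_id != p.class_id:
                continue
            v = iou_ref(p.box, g.box)
            if v >= best_v:
                best, best_v = gi, v
        if best is not None:
            taken.add(best)
            tp += 1
    return tp


def ap_all_cutoff(preds, gts, iou_thr: float = 0.5) -> float:
    """AP by enumerating every confidence cutoff and recounting from scratch.

    For each distinct confidence value the precision/recall pair is
    recomputed with a fresh greedy matching over the retained predictions;
    the envelope is then sampled on the 101-point recall grid.
    """
    if not gts:
        return float("nan")
    if not preds:
        return 0.0
    cutoffs = sorted({p.confidence for p in preds}, reverse=True)
    points = []
    for c in cutoffs:
        kept = [p for p in preds if p.confidence >= c]
        tp = _match_count(kept, gts, iou_thr)
        points.append((tp / len(gts), tp / len(kept)))
    recs = np.array([r for r, _ in points])
    precs = np.array([p for _, p in points])
    grid = np.linspace(0, 1, 101)
    vals = np.zeros_like(grid)
    for i, r in enumerate(grid):
        mask = recs >= r
        vals[i] = precs[mask].max() if mask.any() else 0.0
    return float(vals.mean())


def ap_cocostyle(preds, gts, iou_thr: float = 0.5) -> float:
    """COCO-style AP: global confidence sort, per-image best-IoU matching,
    cumulative TP/FP curve, envelope, 101-point interpolation."""
    if not gts:
        return float("nan")
    if not preds:
        return 0.0
    order = sorted(preds, key=lambda p: -p.confidence)
    gt_used = np.zeros(len(gts), dtype=bool)
    tp = np.zeros(len(order))
    for i, p in enumerate(order):
        best, best_v = -1, iou_thr
        for gi, g in enumerate(gts):
            if gt_used[gi] or g.image_id != p.image_id or g.class_id != p.class_id:
                continue
            v = iou_ref(p.box, g.box)
            if v >= best_v:
                best, best_v = gi, v
        if best >= 0:
            gt_used[best] = True
            tp[i] = 1
    ctp = np.cumsum(tp)
    cfp = np.cumsum(1 - tp)
    rec = ctp / len(gts)
    prec = ctp / (ctp + cfp)
    # envelope then 101-point sampling
    env = np.maximum.accumulate(prec[::-1])[::-1]
    grid = np.linspace(0, 1, 101)
    out = np.zeros_like(grid)
    for i, r in enumerate(grid):
        mask = rec >= r
        out[i] = env[mask].max() if mask.any() else 0.0
    return float(out.mean())
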
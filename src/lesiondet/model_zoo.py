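"""Detector assembly: YOLOv8n-style baseline plus the three ablation toggles.

``build_model`` constructs the anchor-free, decoupled-head detector in its
"n"-scale configuration (width 0.25 / depth 0.33).  Three flags select the
ablation variants:

* ``use_mecs``  -- insert a MECS attention block after each backbone stage
  output (and after the SPPF), sharpening small-lesion features.
* ``use_bfm``   -- replace every concat fusion node in the PAN neck with a
  softmax-gated BFM fusion (laterals/downsamples are width-matched first,
  since BFM fuses same-shape maps).
* ``use_gsc2f`` -- swap the neck C2f blocks for the lightweight GSC2f.

The 2^3 flag combinations correspond to the rows of the ablation study.
Construction is deterministic: weights are drawn from a fixed internal
seed, so a variant always maps to the same parameter count.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .bfm import BFM, BFMConfig
from .conv_blocks import ConvBnAct, GSC2f
from .mecs import MECS, MECSConfig
from .nn import Tensor

__all__ = [
    "ModelVariant",
    "Detector",
    "Detection",
    "build_model",
    "decode_detections",
    "nms",
    "save_checkpoint",
    "load_checkpoint",
]

STRIDES = (8, 16, 32)

# pinned architecture constants (free hyperparameters fixed against the
# published parameter/GFLOP budgets; see docs/methods.md)
MECS_REDUCTION = 4
MECS_AFTER_SPPF = True


@dataclass(frozen=True)
class ModelVariant:
    use_mecs: bool = False
    use_bfm: bool = False
    use_gsc2f: bool = False
    width_mult: float = 0.25
    depth_mult: float = 0.33
    num_classes: int = 15
    reg_max: int = 16

    def __post_init__(self):
        if self.width_mult <= 0 or self.depth_mult <= 0:
            raise ValueError("multipliers must be positive")
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")

    @property
    def name(self) -> str:
        flags = [
            "mecs" if self.use_mecs else None,
            "bfm" if self.use_bfm else None,
            "gsc2f" if self.use_gsc2f else None,
        ]
        on = "+".join(f for f in flags if f)
        return on or "baseline"


def _make_divisible(x: float, divisor: int = 8) -> int:
    return max(divisor, int(x + divisor / 2) // divisor * divisor)


class Bottleneck(nn.Module):
    """Standard residual bottleneck: two 3x3 convs with optional shortcut."""

    def __init__(self, c1: int, c2: int, shortcut: bool = True, rng=None):
        super().__init__()
        self.cv1 = ConvBnAct(c1, c2, 3, 1, rng=rng)
        self.cv2 = ConvBnAct(c2, c2, 3, 1, rng=rng)
        self.add = shortcut and c1 == c2

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C2f(nn.Module):
    """CSP-style block: split, n bottlenecks, concat all intermediates."""

    def __init__(self, c1: int, c2: int, n: int = 1, shortcut: bool = False, rng=None):
        super().__init__()
        self.c = c2 // 2
        self.cv1 = ConvBnAct(c1, 2 * self.c, 1, 1, rng=rng)
        self.cv2 = ConvBnAct((2 + n) * self.c, c2, 1, rng=rng)
        self.blocks = nn.ModuleList(
            Bottleneck(self.c, self.c, shortcut, rng=rng) for _ in range(n)
        )

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        outs = [y[:, : self.c], y[:, self.c :]]
        for blk in self.blocks:
            outs.append(blk(outs[-1]))
        return self.cv2(nn.concat(outs, axis=1))


class SPPF(nn.Module):
    """Spatial pyramid pooling (fast): three chained 5x5 max-pools."""

    def __init__(self, c1: int, c2: int, k: int = 5, rng=None):
        super().__init__()
        mid = c1 // 2
        self.cv1 = ConvBnAct(c1, mid, 1, 1, rng=rng)
        self.cv2 = ConvBnAct(mid * 4, c2, 1, 1, rng=rng)
        self.pool = nn.MaxPool2d(k, 1)

    def forward(self, x: Tensor) -> Tensor:
        a = self.cv1(x)
        b = self.pool(a)
        c = self.pool(b)
        d = self.pool(c)
        return self.cv2(nn.concat([a, b, c, d], axis=1))


class DetectHead(nn.Module):
    """Decoupled anchor-free head: per-scale box-distribution and class logits."""

    def __init__(self, nc: int, reg_max: int, ch: tuple[int, int, int], rng=None):
        super().__init__()
        self.nc = nc
        self.reg_max = reg_max
        c2 = max(16, ch[0] // 4, 4 * reg_max)
        c3 = max(ch[0], min(nc, 100))
        self.box_branches = nn.ModuleList(
            nn.Sequential(
                ConvBnAct(c, c2, 3, rng=rng),
                ConvBnAct(c2, c2, 3, rng=rng),
                nn.Conv2d(c2, 4 * reg_max, 1, bias=True, rng=rng),
            )
            for c in ch
        )
        self.cls_branches = nn.ModuleList(
            nn.Sequential(
                ConvBnAct(c, c3, 3, rng=rng),
                ConvBnAct(c3, c3, 3, rng=rng),
                nn.Conv2d(c3, nc, 1, bias=True, rng=rng),
            )
            for c in ch
        )
        # bias priors: start detections rare so early training is stable
        for br in self.cls_branches:
            br.m2.bias.data[:] = -4.6  # sigmoid ~ 0.01

    def forward(self, feats: list[Tensor]) -> list[Tensor]:
        outs = []
        for f, bb, cb in zip(feats, self.box_branches, self.cls_branches):
            outs.append(nn.concat([bb(f), cb(f)], axis=1))
        return outs


class Detector(nn.Module):
    def __init__(self, variant: ModelVariant):
        super().__init__()
        self.variant = variant
        rng = np.random.default_rng(12345)  # deterministic construction
        w, dmult = variant.width_mult, variant.depth_mult

        def cw(c):  # scaled channel width
            return _make_divisible(c * w)

        def dn(n):  # scaled block depth
            return max(round(n * dmult), 1)

        c1, c2, c3_, c4, c5 = cw(64), cw(128), cw(256), cw(512), cw(1024)
        self.ch = (c3_, c4, c5)

        # ---- backbone -------------------------------------------------
        self.stem = ConvBnAct(3, c1, 3, 2, rng=rng)
        self.down2 = ConvBnAct(c1, c2, 3, 2, rng=rng)
        self.stage2 = C2f(c2, c2, dn(3), shortcut=True, rng=rng)
        self.down3 = ConvBnAct(c2, c3_, 3, 2, rng=rng)
        self.stage3 = C2f(c3_, c3_, dn(6), shortcut=True, rng=rng)
        self.down4 = ConvBnAct(c3_, c4, 3, 2, rng=rng)
        self.stage4 = C2f(c4, c4, dn(6), shortcut=True, rng=rng)
        self.down5 = ConvBnAct(c4, c5, 3, 2, rng=rng)
        self.stage5 = C2f(c5, c5, dn(3), shortcut=True, rng=rng)
        self.sppf = SPPF(c5, c5, rng=rng)

        if variant.use_mecs:
            def mecs_for(c):
                return MECS(MECSConfig(channels=c, reduction=MECS_REDUCTION), rng=rng)

            self.att1 = mecs_for(c1)
            self.att2 = mecs_for(c2)
            self.att3 = mecs_for(c3_)
            self.att4 = mecs_for(c4)
            self.att5 = mecs_for(c5)
            if MECS_AFTER_SPPF:
                self.att_sppf = mecs_for(c5)

        # ---- neck -----------------------------------------------------
        self.up = nn.Upsample()
        NeckBlock = GSC2f if variant.use_gsc2f else C2f

        if variant.use_bfm:
            # width-match the two streams, then softmax-gate them
            self.lat1 = ConvBnAct(c5, c4, 1, rng=rng)   # top-down into P4
            self.fuse1 = BFM(BFMConfig(c4), rng=rng)
            self.n1 = NeckBlock(c4, c4, dn(3), rng=rng)
            self.lat2 = ConvBnAct(c4, c3_, 1, rng=rng)  # top-down into P3
            self.fuse2 = BFM(BFMConfig(c3_), rng=rng)
            self.n2 = NeckBlock(c3_, c3_, dn(3), rng=rng)
            self.dsa = ConvBnAct(c3_, c4, 3, 2, rng=rng)
            self.fuse3 = BFM(BFMConfig(c4), rng=rng)
            self.n3 = NeckBlock(c4, c4, dn(3), rng=rng)
            self.dsb = ConvBnAct(c4, c5, 3, 2, rng=rng)
            self.fuse4 = BFM(BFMConfig(c5), rng=rng)
            self.n4 = NeckBlock(c5, c5, dn(3), rng=rng)
        else:
            self.n1 = NeckBlock(c5 + c4, c4, dn(3), rng=rng)
            self.n2 = NeckBlock(c4 + c3_, c3_, dn(3), rng=rng)
            self.dsa = ConvBnAct(c3_, c3_, 3, 2, rng=rng)
            self.n3 = NeckBlock(c3_ + c4, c4, dn(3), rng=rng)
            self.dsb = ConvBnAct(c4, c4, 3, 2, rng=rng)
            self.n4 = NeckBlock(c4 + c5, c5, dn(3), rng=rng)

        self.head = DetectHead(variant.num_classes, variant.reg_max, self.ch, rng=rng)

    # ------------------------------------------------------------------
    def forward(self, x: Tensor) -> list[Tensor]:
        b, c, h, w = x.shape
        if h % 32 or w % 32:
            raise ValueError(f"input dims must be divisible by 32, got {h}x{w}")
        v = self.variant

        p1 = self.stem(x)
        if v.use_mecs:
            p1 = self.att1(p1)
        p2 = self.stage2(self.down2(p1))
        if v.use_mecs:
            p2 = self.att2(p2)
        p3 = self.stage3(self.down3(p2))
        if v.use_mecs:
            p3 = self.att3(p3)
        p4 = self.stage4(self.down4(p3))
        if v.use_mecs:
            p4 = self.att4(p4)
        p5 = self.stage5(self.down5(p4))
        if v.use_mecs:
            p5 = self.att5(p5)
        p5 = self.sppf(p5)
        if v.use_mecs and MECS_AFTER_SPPF:
            p5 = self.att_sppf(p5)

        if v.use_bfm:
            t1 = self.n1(self.fuse1(self.lat1(self.up(p5)), p4))
            t2 = self.n2(self.fuse2(self.lat2(self.up(t1)), p3))
            t3 = self.n3(self.fuse3(self.dsa(t2), t1))
            t4 = self.n4(self.fuse4(self.dsb(t3), p5))
        else:
            t1 = self.n1(nn.concat([self.up(p5), p4], axis=1))
            t2 = self.n2(nn.concat([self.up(t1), p3], axis=1))
            t3 = self.n3(nn.concat([self.dsa(t2), t1], axis=1))
            t4 = self.n4(nn.concat([self.dsb(t3), p5], axis=1))

        return self.head([t2, t3, t4])


def build_model(variant: ModelVariant) -> Detector:
    return Detector(variant)


# ----------------------------------------------------------------------
# decoding
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class Detection:
    """One decoded detection: class id, confidence and a normalized box."""

    class_id: int
    confidence: float
    cx: float
    cy: float
    w: float
    h: float


def _box_iou_xyxy(box: np.ndarray, boxes: np.ndarray) -> np.ndarray:
    x1 = np.maximum(box[0], boxes[:, 0])
    y1 = np.maximum(box[1], boxes[:, 1])
    x2 = np.minimum(box[2], boxes[:, 2])
    y2 = np.minimum(box[3], boxes[:, 3])
    inter = np.clip(x2 - x1, 0, None) * np.clip(y2 - y1, 0, None)
    a = np.clip(box[2] - box[0], 0, None) * np.clip(box[3] - box[1], 0, None)
    b = np.clip(boxes[:, 2] - boxes[:, 0], 0, None) * np.clip(boxes[:, 3] - boxes[:, 1], 0, None)
    union = a + b - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices, best first."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    while order.size:
        i = order[0]
        keep.append(i)
        if order.size == 1:
            break
        rest = order[1:]
        ious = _box_iou_xyxy(boxes[i], boxes[rest])
        order = rest[ious <= iou_thr]
    return np.asarray(keep, dtype=int)


def decode_detections(
    outputs: list[Tensor] | list[np.ndarray],
    num_classes: int,
    reg_max: int = 16,
    conf_thr: float = 0.25,
    iou_thr: float = 0.45,
    strides: tuple[int, ...] = STRIDES,
) -> list[list[Detection]]:
    """Decode raw per-scale maps into per-image detection lists.

    Box sides come from the expectation of the softmaxed ``reg_max``-bin
    distance distribution, scaled by the stride; class/confidence from the
    sigmoided class logits; greedy per-class NMS at ``iou_thr``; boxes are
    clipped to the image and returned normalized (cx, cy, w, h).
    """
    if not 0 <= conf_thr <= 1 or not 0 <= iou_thr <= 1:
        raise ValueError("thresholds must lie in [0, 1]")
    maps = [o.data if isinstance(o, Tensor) else np.asarray(o) for o in outputs]
    bsz = maps[0].shape[0]
    img_h = maps[0].shape[2] * strides[0]
    img_w = maps[0].shape[3] * strides[0]
    bins = np.arange(reg_max, dtype=np.float32)

    results: list[list[Detection]] = []
    for bi in range(bsz):
        all_boxes, all_scores, all_cls = [], [], []
        for m, stride in zip(maps, strides):
            _, ctot, gh, gw = m.shape
            box_logits = m[bi, : 4 * reg_max].reshape(4, reg_max, gh, gw)
            e = np.exp(box_logits - box_logits.max(axis=1, keepdims=True))
            dist = (e / e.sum(axis=1, keepdims=True) * bins[None, :, None, None]).sum(axis=1)
            cls = 1.0 / (1.0 + np.exp(-m[bi, 4 * reg_max :]))
            conf = cls.max(axis=0)
            cid = cls.argmax(axis=0)
            ys, xs = np.nonzero(conf >= conf_thr)
            if ys.size == 0:
                continue
            cxs = (xs + 0.5) * stride
            cys = (ys + 0.5) * stride
            l, t, r, b = (dist[k, ys, xs] * stride for k in range(4))
            boxes = np.stack([cxs - l, cys - t, cxs + r, cys + b], axis=1)
            boxes[:, 0::2] = boxes[:, 0::2].clip(0, img_w)
            boxes[:, 1::2] = boxes[:, 1::2].clip(0, img_h)
            all_boxes.append(boxes)
            all_scores.append(conf[ys, xs])
            all_cls.append(cid[ys, xs])
        dets: list[Detection] = []
        if all_boxes:
            boxes = np.concatenate(all_boxes)
            scores = np.concatenate(all_scores)
            cids = np.concatenate(all_cls)
            for c in np.unique(cids):
                sel = np.nonzero(cids == c)[0]
                keep = nms(boxes[sel], scores[sel], iou_thr)
                for i in sel[keep]:
                    x1, y1, x2, y2 = boxes[i]
                    dets.append(Detection(
                        class_id=int(c),
                        confidence=float(scores[i]),
                        cx=float((x1 + x2) / 2 / img_w),
                        cy=float((y1 + y2) / 2 / img_h),
                        w=float((x2 - x1) / img_w),
                        h=float((y2 - y1) / img_h),
                    ))
            dets.sort(key=lambda d: -d.confidence)
        results.append(dets)
    return results


# ----------------------------------------------------------------------
# checkpoints
# ----------------------------------------------------------------------

def save_checkpoint(model: Detector, path) -> None:
    state = model.state_dict()
    meta = json.dumps(asdict(model.variant))
    buf = io.BytesIO()
    np.savez(buf, __variant__=np.frombuffer(meta.encode(), dtype=np.uint8), **state)
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())


def load_checkpoint(path) -> Detector:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__variant__"]).decode())
        state = {k: data[k] for k in data.files if k != "__variant__"}
    model = build_model(ModelVariant(**meta))
    model.load_state_dict(state)
    return model
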
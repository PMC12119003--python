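"""Synthetic plant-lesion scenes, YOLO-format dataset I/O, splits, augmentation.

No public lesion-detection dataset ships with this package; instead a
seeded generator emulates the statistics of the kind of field imagery the
detector targets: leaf-textured backgrounds with soil/weed clutter and
variable brightness, an average of two lesions per image
(Poisson-distributed), ~15 disease classes with imbalanced sampling
weights, and tight bounding boxes whose areas span 200 to over 8,000
square pixels.  Lesions are rendered as superellipse blobs with a
class-specific colour/texture signature.

Annotations use the YOLO text convention: one ``class cx cy w h`` line per
object, coordinates normalized to the image; datasets are laid out as
``images/{split}/*.png`` + ``labels/{split}/*.txt`` + ``data.yaml``.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

__all__ = [
    "Annotation",
    "SceneSpec",
    "DatasetManifest",
    "LabelFormatError",
    "DEFAULT_CLASS_NAMES",
    "generate_scene",
    "split_dataset",
    "read_yolo_labels",
    "write_yolo_labels",
    "augment",
    "build_dataset",
]

DEFAULT_CLASS_NAMES = [
    "bean_healthy", "bean_angular_leaf_spot", "bean_rust",
    "strawberry_healthy", "strawberry_angular_leaf_spot", "strawberry_anthracnose",
    "strawberry_blossom_blight", "strawberry_gray_mold", "strawberry_leaf_spot",
    "strawberry_powdery_mildew_leaf", "strawberry_powdery_mildew_fruit",
    "tomato_healthy", "tomato_blight", "tomato_leaf_mold", "tomato_spider_mites",
]


@dataclass(frozen=True)
class Annotation:
    """One object: class index plus a normalized center-format box."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def validate(self, num_classes: int | None = None) -> None:
        if self.class_id < 0 or (num_classes is not None and self.class_id >= num_classes):
            raise ValueError(f"class_id {self.class_id} out of range")
        if not (0.0 <= self.cx <= 1.0 and 0.0 <= self.cy <= 1.0):
            raise ValueError(f"center ({self.cx}, {self.cy}) outside unit square")
        if not (0.0 < self.w <= 1.0 and 0.0 < self.h <= 1.0):
            raise ValueError(f"size ({self.w}, {self.h}) outside (0, 1]")

    def to_xyxy(self, img_w: int, img_h: int) -> tuple[float, float, float, float]:
        return (
            (self.cx - self.w / 2) * img_w,
            (self.cy - self.h / 2) * img_h,
            (self.cx + self.w / 2) * img_w,
            (self.cy + self.h / 2) * img_h,
        )


def _default_class_weights(num_classes: int) -> np.ndarray:
    # imbalanced sampling: per-class prevalence ramps ~300..800 image-equivalents
    w = np.linspace(300.0, 800.0, num_classes)
    return w / w.sum()


@dataclass(frozen=True)
class SceneSpec:
    image_hw: tuple[int, int] = (640, 640)
    mean_objects: float = 2.0
    area_range: tuple[float, float] = (200.0, 8000.0)
    oversize_tail: float = 0.05   # probability of an over-8000 px^2 lesion
    num_classes: int = 15
    clutter_level: float = 0.4
    brightness_jitter: float = 0.35
    max_objects: int = 8
    class_weights: tuple[float, ...] | None = None

    def __post_init__(self):
        h, w = self.image_hw
        if self.mean_objects <= 0:
            raise ValueError("mean_objects must be positive")
        lo, hi = self.area_range
        if not (0 < lo <= hi):
            raise ValueError("invalid area_range")
        if hi > h * w:
            raise ValueError(f"area_range {self.area_range} infeasible for {h}x{w} image")

    def weights(self) -> np.ndarray:
        if self.class_weights is not None:
            w = np.asarray(self.class_weights, dtype=float)
            return w / w.sum()
        return _default_class_weights(self.num_classes)


# ----------------------------------------------------------------------
# scene rendering
# ----------------------------------------------------------------------

def _smooth_noise(rng: np.random.Generator, hw: tuple[int, int], cells: int) -> np.ndarray:
    """Low-frequency noise field in [0, 1] via coarse-grid bilinear upsampling."""
    h, w = hw
    coarse = rng.random((cells, cells)).astype(np.float32)
    img = Image.fromarray((coarse * 255).astype(np.uint8))
    return np.asarray(img.resize((w, h), Image.BILINEAR), dtype=np.float32) / 255.0


def _class_color(class_id: int, num_classes: int) -> np.ndarray:
    hue = (0.02 + 0.93 * class_id / max(num_classes, 1)) % 1.0
    r, g, b = colorsys.hsv_to_rgb(hue, 0.75, 0.7)
    return np.array([r, g, b], dtype=np.float32)


def generate_scene(spec: SceneSpec, seed: int) -> tuple[np.ndarray, list[Annotation]]:
    """Render one seeded scene; byte-identical output for identical seed."""
    rng = np.random.default_rng(seed)
    h, w = spec.image_hw

    # leaf background: layered green noise + vein-like streaks
    base = 0.6 * _smooth_noise(rng, (h, w), 6) + 0.4 * _smooth_noise(rng, (h, w), 24)
    img = np.empty((h, w, 3), dtype=np.float32)
    img[..., 0] = 0.12 + 0.18 * base
    img[..., 1] = 0.35 + 0.35 * base
    img[..., 2] = 0.10 + 0.12 * base

    # soil / weed clutter patches
    n_clutter = rng.poisson(6.0 * spec.clutter_level)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n_clutter):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        ry, rx = rng.uniform(0.05, 0.25, 2) * np.array([h, w])
        ang = rng.uniform(0, np.pi)
        ca, sa = np.cos(ang), np.sin(ang)
        u = ((xx - cx) * ca + (yy - cy) * sa) / max(rx, 1)
        v = (-(xx - cx) * sa + (yy - cy) * ca) / max(ry, 1)
        mask = u * u + v * v < 1
        if rng.random() < 0.6:  # soil
            color = np.array([0.35, 0.25, 0.15]) + rng.normal(0, 0.03, 3)
        else:  # weed / dry grass
            color = np.array([0.45, 0.55, 0.2]) + rng.normal(0, 0.03, 3)
        alpha = rng.uniform(0.4, 0.8)
        img[mask] = (1 - alpha) * img[mask] + alpha * color.astype(np.float32)

    # lesions
    weights = spec.weights()
    k = min(int(rng.poisson(spec.mean_objects)), spec.max_objects)
    annotations: list[Annotation] = []
    lo, hi = spec.area_range
    for _ in range(k):
        cls = int(rng.choice(spec.num_classes, p=weights))
        if rng.random() < spec.oversize_tail:
            area = rng.uniform(hi, min(2.0 * hi, 0.5 * h * w))
        else:
            area = rng.uniform(lo, hi)
        aspect = float(np.clip(rng.lognormal(0.0, 0.25), 0.5, 2.0))
        bw = float(np.sqrt(area * aspect))
        bh = area / bw
        bw, bh = min(bw, w - 2), min(bh, h - 2)
        x0 = rng.uniform(1, w - bw - 1)
        y0 = rng.uniform(1, h - bh - 1)

        # superellipse blob inscribed in the box (touches all four sides,
        # so the tight bounding box equals the sampled box)
        exp_n = rng.uniform(1.5, 3.5)
        xs0, xs1 = int(np.floor(x0)), int(np.ceil(x0 + bw))
        ys0, ys1 = int(np.floor(y0)), int(np.ceil(y0 + bh))
        sub_y, sub_x = np.mgrid[ys0:ys1, xs0:xs1]
        u = np.abs((sub_x + 0.5 - (x0 + bw / 2)) / (bw / 2))
        v = np.abs((sub_y + 0.5 - (y0 + bh / 2)) / (bh / 2))
        mask = u**exp_n + v**exp_n <= 1.0

        color = _class_color(cls, spec.num_classes)
        tex = 0.75 + 0.5 * _smooth_noise(rng, mask.shape, max(2, min(8, mask.shape[0] // 3)))
        if cls % 3 == 1:  # ringed signature
            r2 = np.sqrt(u * u + v * v)
            tex *= 0.8 + 0.4 * np.cos(6.0 * np.pi * r2) ** 2
        patch = img[ys0:ys1, xs0:xs1]
        blend = 0.85
        patch[mask] = (1 - blend) * patch[mask] + blend * (color[None, :] * tex[mask, None])
        img[ys0:ys1, xs0:xs1] = patch

        ann = Annotation(
            class_id=cls,
            cx=(x0 + bw / 2) / w,
            cy=(y0 + bh / 2) / h,
            w=bw / w,
            h=bh / h,
        )
        ann.validate(spec.num_classes)
        annotations.append(ann)

    # global brightness
    factor = rng.uniform(1 - spec.brightness_jitter, 1 + spec.brightness_jitter)
    img = np.clip(img * factor, 0.0, 1.0)
    return (img * 255).astype(np.uint8), annotations


# ----------------------------------------------------------------------
# splits
# ----------------------------------------------------------------------

def split_dataset(
    n: int,
    ratios: tuple[float, float, float] = (0.7, 0.2, 0.1),
    seed: int = 0,
) -> tuple[tuple[int, int, int], np.ndarray]:
    """Partition ``n`` items into train/val/test by floor/floor/remainder.

    Returns the three sizes and an array of split tags ('train'/'val'/'test')
    under a seeded permutation.  ``n=5841`` at 7:2:1 yields (4088, 1168, 585).
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    if n < 0:
        raise ValueError("n must be nonnegative")
    n_train = int(np.floor(ratios[0] * n))
    n_val = int(np.floor(ratios[1] * n))
    n_test = n - n_train - n_val
    perm = np.random.default_rng(seed).permutation(n)
    tags = np.empty(n, dtype=object)
    tags[perm[:n_train]] = "train"
    tags[perm[n_train : n_train + n_val]] = "val"
    tags[perm[n_train + n_val :]] = "test"
    return (n_train, n_val, n_test), tags


# ----------------------------------------------------------------------
# YOLO label I/O
# ----------------------------------------------------------------------

class LabelFormatError(ValueError):
    """Raised on malformed label files; carries (line_number, message) pairs."""

    def __init__(self, path, offenders: list[tuple[int, str]]):
        self.offenders = offenders
        details = "; ".join(f"line {ln}: {msg}" for ln, msg in offenders)
        super().__init__(f"{path}: {details}")


def read_yolo_labels(path, num_classes: int | None = None) -> list[Annotation]:
    path = Path(path)
    annotations: list[Annotation] = []
    offenders: list[tuple[int, str]] = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            offenders.append((ln, f"expected 5 fields, got {len(parts)}"))
            continue
        try:
            cls = int(parts[0])
            cx, cy, bw, bh = (float(p) for p in parts[1:])
            ann = Annotation(cls, cx, cy, bw, bh)
            ann.validate(num_classes)
        except ValueError as exc:
            offenders.append((ln, str(exc)))
            continue
        annotations.append(ann)
    if offenders:
        raise LabelFormatError(path, offenders)
    return annotations


def write_yolo_labels(path, annotations: list[Annotation]) -> None:
    lines = [
        f"{a.class_id} {a.cx:.6f} {a.cy:.6f} {a.w:.6f} {a.h:.6f}" for a in annotations
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ----------------------------------------------------------------------
# augmentation
# ----------------------------------------------------------------------

def augment(
    image: np.ndarray,
    annotations: list[Annotation],
    op: str,
    seed: int = 0,
    *,
    angle: float | None = None,
    factor: float | None = None,
    crop_box: tuple[int, int, int, int] | None = None,
    drop_threshold: float = 0.3,
) -> tuple[np.ndarray, list[Annotation]]:
    """Apply one augmentation; geometric ops transform boxes consistently.

    ``op`` is one of hflip / rotate / crop / brightness / contrast.  Crops
    drop boxes whose surviving area fraction falls below ``drop_threshold``.
    """
    rng = np.random.default_rng(seed)
    h, w = image.shape[:2]

    if op == "hflip":
        out = image[:, ::-1].copy()
        anns = [replace(a, cx=1.0 - a.cx) for a in annotations]
        return out, anns

    if op == "rotate":
        ang = rng.uniform(-30, 30) if angle is None else float(angle)
        if ang % 360 == 0:
            return image.copy(), list(annotations)
        pil = Image.fromarray(image).rotate(-ang, resample=Image.BILINEAR)
        out = np.asarray(pil)
        rad = np.deg2rad(ang)
        ca, sa = np.cos(rad), np.sin(rad)
        anns = []
        for a in annotations:
            x1, y1, x2, y2 = a.to_xyxy(w, h)
            corners = np.array([[x1, y1], [x2, y1], [x2, y2], [x1, y2]], dtype=float)
            corners -= [w / 2, h / 2]
            rot = corners @ np.array([[ca, -sa], [sa, ca]]).T
            rot += [w / 2, h / 2]
            nx1, ny1 = rot.min(axis=0)
            nx2, ny2 = rot.max(axis=0)
            nx1, nx2 = np.clip([nx1, nx2], 0, w)
            ny1, ny2 = np.clip([ny1, ny2], 0, h)
            if nx2 - nx1 < 1 or ny2 - ny1 < 1:
                continue
            anns.append(Annotation(
                a.class_id,
                (nx1 + nx2) / 2 / w, (ny1 + ny2) / 2 / h,
                (nx2 - nx1) / w, (ny2 - ny1) / h,
            ))
        return out, anns

    if op == "crop":
        if crop_box is None:
            scale = rng.uniform(0.6, 0.9)
            cw, ch = int(w * scale), int(h * scale)
            x0 = int(rng.integers(0, w - cw + 1))
            y0 = int(rng.integers(0, h - ch + 1))
        else:
            x0, y0, cw, ch = crop_box
        if cw > w or ch > h or cw < 1 or ch < 1:
            raise ValueError(f"crop {cw}x{ch} larger than image {w}x{h} or empty")
        out = image[y0 : y0 + ch, x0 : x0 + cw].copy()
        anns = []
        for a in annotations:
            x1, y1, x2, y2 = a.to_xyxy(w, h)
            ix1, iy1 = max(x1, x0), max(y1, y0)
            ix2, iy2 = min(x2, x0 + cw), min(y2, y0 + ch)
            inter = max(ix2 - ix1, 0) * max(iy2 - iy1, 0)
            area = (x2 - x1) * (y2 - y1)
            if area <= 0 or inter / area < drop_threshold:
                continue
            anns.append(Annotation(
                a.class_id,
                ((ix1 + ix2) / 2 - x0) / cw, ((iy1 + iy2) / 2 - y0) / ch,
                (ix2 - ix1) / cw, (iy2 - iy1) / ch,
            ))
        return out, anns

    if op in ("brightness", "contrast"):
        f = rng.uniform(0.6, 1.4) if factor is None else float(factor)
        arr = image.astype(np.float32)
        if op == "brightness":
            arr = arr * f
        else:
            mean = arr.mean(axis=(0, 1), keepdims=True)
            arr = (arr - mean) * f + mean
        return np.clip(arr, 0, 255).astype(image.dtype), list(annotations)

    raise ValueError(f"unknown augmentation op {op!r}")


# ----------------------------------------------------------------------
# dataset assembly
# ----------------------------------------------------------------------

@dataclass
class DatasetManifest:
    root: Path
    names: list[str]
    records: list[tuple[Path, list[Annotation], str]] = field(default_factory=list)

    @property
    def num_classes(self) -> int:
        return len(self.names)

    def split(self, tag: str) -> list[tuple[Path, list[Annotation]]]:
        return [(p, a) for p, a, t in self.records if t == tag]

    @classmethod
    def from_dir(cls, root) -> "DatasetManifest":
        root = Path(root)
        cfg = yaml.safe_load((root / "data.yaml").read_text())
        names = list(cfg["names"])
        manifest = cls(root=root, names=names)
        for tag in ("train", "val", "test"):
            img_dir = root / "images" / tag
            if not img_dir.is_dir():
                continue
            for img_path in sorted(img_dir.glob("*.png")):
                lbl = root / "labels" / tag / (img_path.stem + ".txt")
                anns = read_yolo_labels(lbl, len(names)) if lbl.exists() else []
                manifest.records.append((img_path, anns, tag))
        return manifest


def build_dataset(
    root,
    n_images: int,
    spec: SceneSpec | None = None,
    seed: int = 0,
    ratios: tuple[float, float, float] = (0.7, 0.2, 0.1),
    class_names: list[str] | None = None,
) -> DatasetManifest:
    """Generate a complete YOLO-layout dataset directory of synthetic scenes."""
    spec = spec or SceneSpec()
    root = Path(root)
    names = class_names or DEFAULT_CLASS_NAMES[: spec.num_classes]
    if len(names) != spec.num_classes:
        names = [f"class_{i}" for i in range(spec.num_classes)]
    rng = np.random.default_rng(seed)
    scene_seeds = rng.integers(0, 2**31 - 1, size=n_images)
    _, tags = split_dataset(n_images, ratios, seed=seed)

    manifest = DatasetManifest(root=root, names=list(names))
    for tag in ("train", "val", "test"):
        (root / "images" / tag).mkdir(parents=True, exist_ok=True)
        (root / "labels" / tag).mkdir(parents=True, exist_ok=True)
    for i in range(n_images):
        tag = str(tags[i])
        img, anns = generate_scene(spec, int(scene_seeds[i]))
        img_path = root / "images" / tag / f"scene_{i:05d}.png"
        Image.fromarray(img).save(img_path)
        write_yolo_labels(root / "labels" / tag / f"scene_{i:05d}.txt", anns)
        manifest.records.append((img_path, anns, tag))
    (root / "data.yaml").write_text(yaml.safe_dump({
        "path": str(root),
        "train": "images/train",
        "val": "images/val",
        "test": "images/test",
        "nc": spec.num_classes,
        "names": list(names),
    }))
    return manifest
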
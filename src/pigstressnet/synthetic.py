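"""Synthetic pen scenes with YOLO-format annotations.

The generator emulates the *statistical* structure of top/oblique pen
imagery — five pose classes with distinct silhouettes, partial overlap,
fence-bar occlusion, lighting variation, and an erythema (excess-red)
signal — not its photographic appearance.  Pigs are rasterised as
rotated ellipses (lying/stress: elongated; standing: ellipse plus legs
and head; sitting/eating: compact blobs, eaters placed at the trough
strip).  Heat-stressed pigs are rendered in lying geometry with a
redness value drawn from Normal(0.08, 0.02) truncated to [0, 1];
non-stressed pigs draw from a low Normal(0.02, 0.01).  The excess-red
component is composed after lighting and occlusion so that the
measurable redness index of each box matches its drawn value, keeping
the stress population separable exactly as designed.

Labels follow the YOLO text convention: one line per object,
``class cx cy w h`` normalised to the image size, six decimals.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import yaml
from PIL import Image

CLASS_NAMES = ("stand", "eat", "sit", "lying", "stress")
CLASS_TO_IDX = {n: i for i, n in enumerate(CLASS_NAMES)}


@dataclass
class Pig:
    pose: str                  # one of CLASS_NAMES
    cx: float
    cy: float
    orientation: float         # radians
    scale: float               # half-length of the major axis, px
    redness: float


@dataclass
class SceneSpec:
    image_size: int = 320
    n_pigs: int = 4
    pigs: list | None = None             # explicit pigs override sampling
    fence_spacing: int = 48
    fence_width: int = 3
    brightness: float = 1.0
    contrast: float = 1.0
    stress_redness: tuple = (0.08, 0.02)
    normal_redness: tuple = (0.02, 0.01)
    pose_pool: tuple = CLASS_NAMES        # poses sampled uniformly from here
    seed: int = 0
    max_place_attempts: int = 60


@dataclass
class AugmentSpec:
    brightness_delta: float = 0.30
    contrast_delta: float = 0.20
    occlusion_area_max: float = 0.15
    hflip_prob: float = 0.5
    copies_per_image: int = 10


@dataclass
class Annotation:
    cls: int
    x1: float
    y1: float
    x2: float
    y2: float

    def yolo_line(self, size: int) -> str:
        cx = (self.x1 + self.x2) / 2 / size
        cy = (self.y1 + self.y2) / 2 / size
        w = (self.x2 - self.x1) / size
        h = (self.y2 - self.y1) / size
        return f"{self.cls} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}"

    @property
    def box(self):
        return (self.x1, self.y1, self.x2, self.y2)


class PlacementError(RuntimeError):
    """Raised when pigs cannot be placed without complete overlap."""


def _truncated_normal(rng, mean, sd, n=1):
    out = []
    while len(out) < n:
        d = rng.normal(mean, sd, size=2 * (n - len(out)) + 4)
        out.extend(d[(d >= 0.0) & (d <= 1.0)].tolist())
    return out[:n] if n > 1 else out[0]


def _pose_geometry(pose: str, scale: float):
    """(major, minor) half-axes of the body ellipse for a pose."""
    if pose in ("lying", "stress"):
        return scale, scale * 0.40
    if pose == "stand":
        return scale * 0.80, scale * 0.34
    if pose == "sit":
        return scale * 0.60, scale * 0.45
    if pose == "eat":
        return scale * 0.62, scale * 0.38
    raise ValueError(f"unknown pose {pose!r}")


def _ellipse_mask(size, cx, cy, a, b, theta):
    ys, xs = np.mgrid[0:size, 0:size]
    dx, dy = xs - cx, ys - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _pig_mask(size: int, pig: Pig) -> np.ndarray:
    a, b = _pose_geometry(pig.pose, pig.scale)
    mask = _ellipse_mask(size, pig.cx, pig.cy, a, b, pig.orientation)
    ct, st = np.cos(pig.orientation), np.sin(pig.orientation)
    # head blob at the front of the major axis
    hx, hy = pig.cx + ct * a * 0.95, pig.cy + st * a * 0.95
    mask |= _ellipse_mask(size, hx, hy, b * 0.55, b * 0.55, 0.0)
    if pig.pose == "stand":
        # four leg stubs perpendicular to the body
        for f in (-0.6, -0.2, 0.2, 0.6):
            lx, ly = pig.cx + ct * a * f, pig.cy + st * a * f
            mask |= _ellipse_mask(size, lx - st * b * 1.2, ly + ct * b * 1.2,
                                  b * 0.22, b * 0.55, pig.orientation)
    return mask


def _sample_pigs(spec: SceneSpec, rng) -> list:
    size = spec.image_size
    pigs, masks = [], []
    pool = spec.pose_pool
    poses = [pool[i] for i in rng.integers(0, len(pool), size=spec.n_pigs)]
    for pose in poses:
        placed = False
        for _ in range(spec.max_place_attempts):
            scale = size * rng.uniform(0.10, 0.16)
            if pose == "eat":
                cx = rng.uniform(scale, size - scale)
                cy = rng.uniform(scale * 0.6, size * 0.16)
                theta = -np.pi / 2 + rng.normal(0, 0.15)
            else:
                cx = rng.uniform(scale, size - scale)
                cy = rng.uniform(scale, size - scale)
                theta = rng.uniform(0, np.pi)
            cand = Pig(pose, cx, cy, theta, scale, 0.0)
            m = _pig_mask(size, cand)
            # allow partial overlap, refuse near-total occlusion
            if all((m & pm).sum() < 0.55 * min(m.sum(), pm.sum()) for pm in masks):
                mean, sd = (spec.stress_redness if pose == "stress"
                            else spec.normal_redness)
                cand.redness = _truncated_normal(rng, mean, sd)
                pigs.append(cand)
                masks.append(m)
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place {spec.n_pigs} pigs without full overlap")
    return pigs


def generate_scene(spec: SceneSpec):
    """Render one pen image; returns (uint8 HxWx3 image, [Annotation])."""
    size = spec.image_size
    rng = np.random.default_rng(spec.seed)
    pigs = spec.pigs if spec.pigs is not None else _sample_pigs(spec, rng)

    # concrete floor with mild texture and a dark trough strip at the top
    base = rng.normal(118.0, 6.0, size=(size, size))
    img = np.repeat(base[:, :, None], 3, axis=2)
    img[: max(2, size // 22), :, :] *= 0.45

    owner = np.full((size, size), -1, dtype=np.int32)   # -1 bg, -2 fence
    full_masks = []
    for i, pig in enumerate(pigs):
        m = _pig_mask(size, pig)
        full_masks.append(m)
        shade = rng.uniform(165.0, 195.0)
        img[m] = shade + rng.normal(0.0, 3.0, size=(int(m.sum()), 1))
        owner[m] = i

    # fence bars occlude everything
    phase = int(rng.integers(0, spec.fence_spacing))
    for x0 in range(phase, size, spec.fence_spacing):
        img[:, x0:x0 + spec.fence_width, :] = 90.0
        owner[:, x0:x0 + spec.fence_width] = -2

    # lighting on the luminance, before the erythema channel is applied
    img = (img - img.mean()) * spec.contrast + img.mean()
    img *= spec.brightness
    img = np.clip(img, 0.0, 235.0)

    anns = []
    for i, (pig, m) in enumerate(zip(pigs, full_masks)):
        ys, xs = np.nonzero(m)
        if xs.size == 0:
            continue
        x1, x2 = float(xs.min()), float(xs.max() + 1)
        y1, y2 = float(ys.min()), float(ys.max() + 1)
        x1, y1 = max(0.0, x1), max(0.0, y1)
        x2, y2 = min(float(size), x2), min(float(size), y2)
        anns.append(Annotation(CLASS_TO_IDX[pig.pose], x1, y1, x2, y2))
        # paint excess red on the pixels this pig still owns so the
        # measured index of the box equals the drawn redness value
        own = (owner == i) & m
        n_own = int(own.sum())
        if n_own == 0:
            continue
        n_box = (x2 - x1) * (y2 - y1)
        e_pix = pig.redness * 255.0 * n_box / n_own
        img[own, 0] = np.minimum(img[own, 0] + e_pix, 255.0)

    return np.clip(np.round(img), 0, 255).astype(np.uint8), anns


def augment(image: np.ndarray, annotations: list, spec: AugmentSpec, seed: int = 0):
    """Return ``copies_per_image`` augmented variants of one scene.

    Brightness/contrast jitter in the stated ranges, one gray occlusion
    patch of at most ``occlusion_area_max`` of the image area, and
    horizontal flips with the stated probability.  Labels are kept for
    occluded objects (boxes are only remapped by flips).
    """
    rng = np.random.default_rng(seed)
    h, w = image.shape[:2]
    out = []
    for _ in range(spec.copies_per_image):
        img = image.astype(np.float64)
        anns = list(annotations)
        b = 1.0 + rng.uniform(-spec.brightness_delta, spec.brightness_delta)
        c = 1.0 + rng.uniform(-spec.contrast_delta, spec.contrast_delta)
        img = (img - img.mean()) * c + img.mean()
        img *= b
        # occlusion patch, area <= occlusion_area_max of the image
        frac = rng.uniform(0.02, spec.occlusion_area_max)
        pw = int(np.sqrt(frac * h * w * rng.uniform(0.5, 2.0)))
        pw = max(2, min(pw, w - 1))
        ph = max(2, min(int(frac * h * w / pw), h - 1))
        px = int(rng.integers(0, w - pw))
        py = int(rng.integers(0, h - ph))
        img[py:py + ph, px:px + pw] = 96.0
        if rng.uniform() < spec.hflip_prob:
            img = img[:, ::-1]
            anns = [replace(a, x1=w - a.x2, x2=w - a.x1) for a in anns]
        out.append((np.clip(np.round(img), 0, 255).astype(np.uint8), anns))
    return out


def write_dataset(scenes, out_dir: str, split: float = 0.8,
                  class_names=CLASS_NAMES) -> str:
    """Write scenes to a YOLO-layout dataset; returns the YAML path.

    ``scenes`` is a sequence of (image, annotations).  The train/val
    split is by scene index so augmented copies of one scene never cross
    the split boundary.
    """
    n_train = int(round(len(scenes) * split))
    for sub in ("images/train", "images/val", "labels/train", "labels/val"):
        os.makedirs(os.path.join(out_dir, sub), exist_ok=True)
    for i, (img, anns) in enumerate(scenes):
        part = "train" if i < n_train else "val"
        stem = f"scene_{i:05d}"
        Image.fromarray(img).save(os.path.join(out_dir, "images", part, stem + ".png"))
        size = img.shape[0]
        lines = [a.yolo_line(size) for a in anns]
        with open(os.path.join(out_dir, "labels", part, stem + ".txt"), "w") as fh:
            fh.write("\n".join(lines) + ("\n" if lines else ""))
    cfg = {
        "path": os.path.abspath(out_dir),
        "train": "images/train",
        "val": "images/val",
        "names": {i: n for i, n in enumerate(class_names)},
    }
    yaml_path = os.path.join(out_dir, "dataset.yaml")
    with open(yaml_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return yaml_path


def read_dataset(yaml_path: str, part: str = "train"):
    """Load a YOLO-layout dataset; yields (image array, [Annotation])."""
    with open(yaml_path) as fh:
        cfg = yaml.safe_load(fh)
    root = cfg["path"]
    img_dir = os.path.join(root, cfg[part])
    lbl_dir = img_dir.replace(os.sep + "images" + os.sep, os.sep + "labels" + os.sep)
    items = []
    for name in sorted(os.listdir(img_dir)):
        if not name.endswith(".png"):
            continue
        img = np.asarray(Image.open(os.path.join(img_dir, name)))
        size_h, size_w = img.shape[:2]
        anns = []
        lbl = os.path.join(lbl_dir, name[:-4] + ".txt")
        if os.path.exists(lbl):
            for line in open(lbl):
                if not line.strip():
                    continue
                c, cx, cy, w, h = line.split()
                cx, cy, w, h = (float(cx) * size_w, float(cy) * size_h,
                                float(w) * size_w, float(h) * size_h)
                anns.append(Annotation(int(c), cx - w / 2, cy - h / 2,
                                       cx + w / 2, cy + h / 2))
        items.append((img, anns))
    return items
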
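"""Desk-scale training loop, target assignment, and inference.

The loss follows the anchor-free YOLO recipe: a task-aligned assigner
picks, for every ground-truth box, the top-k grid cells (by an
alignment metric mixing classification score and IoU) among the cells
whose centre falls inside the box; assigned cells regress their box
through the distribution-focal decoding and are supervised with

``loss = box_w * (1 - overlap) + cls_w * BCE + dfl_w * DFL
        + p * (sum|gamma| + sum|lambda|)``

where the overlap is the configured IoU family (MPDIoU by default,
CIoU selectable) and the last term is the NAM sparsity penalty.
Optimisation is SGD with momentum and a cosine learning-rate schedule
with linear warmup.  All randomness flows from one integer seed, so a
repeated run reproduces its losses bit for bit on the same machine.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .evaluate import evaluate, nms
from .fusion import RednessStats, fusion_report
from .losses import ImageExtent, iou_t
from .model import CLASS_NAMES, PigStressNet
from .nn import tensor as T


@dataclass
class TrainConfig:
    """Training hyperparameters; defaults follow the full-scale recipe."""
    epochs: int = 100
    batch_size: int = 16
    workers: int = 32           # advisory; this implementation is single-process
    scale: float = 0.5          # random-scale augmentation range (+/-)
    mosaic: bool = True
    mixup: float = 0.0
    copy_paste: float = 0.1
    seed: int = 0
    device: str = "cpu"
    img_size: int = 640
    lr: float = 0.01
    final_lr_frac: float = 0.1
    momentum: float = 0.9
    weight_decay: float = 5e-4
    warmup_iters: int = 50
    box_weight: float = 7.5
    cls_weight: float = 0.5
    dfl_weight: float = 1.5
    nam_p: float = 1e-4
    assign_topk: int = 10


#: the desk-scale preset: 200 scenes at 320x320, 10 epochs on CPU.
#: batch 2 gives the short schedule twice the optimisation steps of the
#: full-scale batch size at the same total compute.
DESK_PRESET = dict(epochs=10, batch_size=2, img_size=320, mosaic=False,
                   copy_paste=0.0, scale=0.0, lr=0.02, warmup_iters=80)


def desk_config(**overrides) -> TrainConfig:
    kw = dict(DESK_PRESET)
    kw.update(overrides)
    return TrainConfig(**kw)


# ---------------------------------------------------------------------------
# target assignment (numpy, outside the autodiff graph)
# ---------------------------------------------------------------------------

def _anchors(img_size: int, strides=(8, 16, 32)):
    pts, strs = [], []
    for s in strides:
        n = img_size // s
        xs, ys = np.meshgrid(np.arange(n), np.arange(n))
        cx = (xs.ravel() + 0.5) * s
        cy = (ys.ravel() + 0.5) * s
        pts.append(np.stack([cx, cy], axis=1))
        strs.append(np.full(n * n, s))
    return np.concatenate(pts).astype(np.float32), np.concatenate(strs).astype(np.float32)


def assign_targets(pred_boxes, pred_scores, gt_boxes, gt_cls, anchors,
                   topk=10, alpha=0.5, beta=6.0):
    """Task-aligned assignment for one image.

    Returns (anchor_idx, gt_idx, target_scores) arrays; ``target_scores``
    are the per-anchor normalised alignment weights in (0, 1].
    """
    if len(gt_boxes) == 0:
        return (np.zeros(0, np.int64), np.zeros(0, np.int64), np.zeros(0, np.float32))
    chosen = {}
    for gi, (gb, gc) in enumerate(zip(gt_boxes, gt_cls)):
        inside = ((anchors[:, 0] > gb[0]) & (anchors[:, 0] < gb[2]) &
                  (anchors[:, 1] > gb[1]) & (anchors[:, 1] < gb[3]))
        cand = np.nonzero(inside)[0]
        if cand.size == 0:
            continue
        pb = pred_boxes[cand]
        ix = np.clip(np.minimum(pb[:, 2], gb[2]) - np.maximum(pb[:, 0], gb[0]), 0, None)
        iy = np.clip(np.minimum(pb[:, 3], gb[3]) - np.maximum(pb[:, 1], gb[1]), 0, None)
        inter = ix * iy
        area_p = np.clip(pb[:, 2] - pb[:, 0], 0, None) * np.clip(pb[:, 3] - pb[:, 1], 0, None)
        area_g = (gb[2] - gb[0]) * (gb[3] - gb[1])
        ious = inter / np.maximum(area_p + area_g - inter, 1e-9)
        score = pred_scores[cand, int(gc)]
        align = np.power(score, alpha) * np.power(np.maximum(ious, 1e-9), beta)
        top = cand[np.argsort(-align)[:topk]]
        top_align = align[np.argsort(-align)[:topk]]
        norm = top_align * (ious.max() / (top_align.max() + 1e-9))
        for a, t in zip(top, np.maximum(norm, 1e-4)):
            if a not in chosen or chosen[a][1] < t:
                chosen[a] = (gi, t)
    if not chosen:
        return (np.zeros(0, np.int64), np.zeros(0, np.int64), np.zeros(0, np.float32))
    aidx = np.array(sorted(chosen), dtype=np.int64)
    gidx = np.array([chosen[a][0] for a in aidx], dtype=np.int64)
    tsc = np.array([chosen[a][1] for a in aidx], dtype=np.float32)
    return aidx, gidx, tsc


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _abs_t(x):
    return T.maximum(x, -x)


def _flatten_outputs(outputs, reg_max=16):
    """Per-level (box, cls) maps -> flat Tensors (N, A, 4*reg_max) / (N, A, C)."""
    box_flat, cls_flat = [], []
    for b, c in outputs:
        n, bc, h, w = b.shape
        box_flat.append(b.reshape(n, bc, h * w).transpose(0, 2, 1))
        n, cc, h, w = c.shape
        cls_flat.append(c.reshape(n, cc, h * w).transpose(0, 2, 1))
    return T.concat(box_flat, axis=1), T.concat(cls_flat, axis=1)


def detection_loss(model: PigStressNet, outputs, batch_gt, img_size: int,
                   cfg: TrainConfig):
    """Total loss Tensor plus a dict of detached components."""
    reg_max = model.head.spec.reg_max
    nc = model.head.spec.n_classes
    anchors, strides = _anchors(img_size)
    box_t, cls_t = _flatten_outputs(outputs, reg_max)
    n_batch, n_anchor = cls_t.shape[0], cls_t.shape[1]

    # detached decode for the assigner
    box_np = box_t.data.reshape(n_batch, n_anchor, 4, reg_max)
    z = box_np - box_np.max(axis=3, keepdims=True)
    e = np.exp(z)
    dist = (e / e.sum(axis=3, keepdims=True) @ np.arange(reg_max, dtype=np.float32))
    lt = anchors[None] - dist[..., :2] * strides[None, :, None]
    rb = anchors[None] + dist[..., 2:] * strides[None, :, None]
    pred_boxes = np.concatenate([lt, rb], axis=2)
    pred_scores = 1.0 / (1.0 + np.exp(-cls_t.data))

    idx_b, idx_a, gts_box, gts_cls, tscores = [], [], [], [], []
    for bi, gt in enumerate(batch_gt):
        gb = np.array([g["box"] for g in gt], dtype=np.float32).reshape(-1, 4)
        gc = np.array([g["cls"] for g in gt], dtype=np.int64)
        aidx, gidx, tsc = assign_targets(pred_boxes[bi], pred_scores[bi], gb, gc,
                                         anchors, cfg.assign_topk)
        idx_b.extend([bi] * len(aidx))
        idx_a.extend(aidx.tolist())
        gts_box.extend(gb[gidx].tolist())
        gts_cls.extend(gc[gidx].tolist())
        tscores.extend(tsc.tolist())

    # classification BCE over every anchor; positives carry their score
    target = np.zeros((n_batch, n_anchor, nc), dtype=np.float32)
    if idx_b:
        target[idx_b, idx_a, gts_cls] = tscores
    score_sum = max(float(np.sum(tscores)), 1.0)
    probs = T.sigmoid(cls_t)
    eps = 1e-7
    bce = -(target * T.log(probs + eps) + (1.0 - target) * T.log(1.0 - probs + eps))
    cls_loss = bce.sum() / score_sum

    if idx_b:
        w = np.asarray(tscores, dtype=np.float32)
        gt_arr = np.asarray(gts_box, dtype=np.float32)
        sel = (np.asarray(idx_b), np.asarray(idx_a))
        box_sel = box_t[sel].reshape(len(idx_b), 4, reg_max)
        # differentiable integral decode
        p = T.softmax(box_sel, axis=2)
        rng_bins = np.arange(reg_max, dtype=np.float32).reshape(1, 1, reg_max)
        dist_t = (p * rng_bins).sum(axis=2)                      # (M, 4)
        a_sel = anchors[sel[1]]
        s_sel = strides[sel[1]].reshape(-1, 1)
        lt_t = a_sel - dist_t[:, :2] * s_sel
        rb_t = a_sel + dist_t[:, 2:] * s_sel
        boxes_t = T.concat([lt_t, rb_t], axis=1)
        ext = ImageExtent(img_size, img_size)
        ov = iou_t(boxes_t, gt_arr, model.spec.loss, ext)
        box_loss = ((1.0 - ov) * w).sum() / score_sum
        # distribution focal loss on the l,t,r,b bin distributions
        tgt_dist = np.stack([
            (a_sel[:, 0] - gt_arr[:, 0]), (a_sel[:, 1] - gt_arr[:, 1]),
            (gt_arr[:, 2] - a_sel[:, 0]), (gt_arr[:, 3] - a_sel[:, 1])], axis=1)
        tgt_dist = np.clip(tgt_dist / s_sel, 0.0, reg_max - 1 - 1e-3)
        tl = np.floor(tgt_dist).astype(np.int64)
        wr = tgt_dist - tl
        logp = T.log(p + eps)
        oh_l = np.zeros((len(idx_b), 4, reg_max), dtype=np.float32)
        oh_r = np.zeros_like(oh_l)
        ii = np.arange(len(idx_b))[:, None]
        jj = np.arange(4)[None, :]
        oh_l[ii, jj, tl] = 1.0 - wr
        oh_r[ii, jj, np.minimum(tl + 1, reg_max - 1)] = wr
        dfl = -((oh_l + oh_r) * logp).sum(axis=2).mean(axis=1)
        dfl_loss = (dfl * w).sum() / score_sum
    else:
        box_loss = T.Tensor(0.0)
        dfl_loss = T.Tensor(0.0)

    reg = T.Tensor(0.0)
    if cfg.nam_p > 0:
        for gamma in model.nam_gammas:
            reg = reg + _abs_t(gamma).sum() * cfg.nam_p

    total = (cfg.box_weight * box_loss + cfg.cls_weight * cls_loss
             + cfg.dfl_weight * dfl_loss + reg)
    parts = {"box": float(np.asarray(box_loss.data)),
             "cls": float(np.asarray(cls_loss.data)),
             "dfl": float(np.asarray(dfl_loss.data)),
             "nam_reg": float(np.asarray(reg.data)),
             "total": float(np.asarray(total.data))}
    return total, parts


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------

class SGD:
    def __init__(self, params, lr, momentum=0.9, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.momentum, self.wd = lr, momentum, weight_decay
        self.vel = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.vel):
            if p.grad is None:
                continue
            g = p.grad
            if self.wd and p.data.ndim >= 2:
                g = g + self.wd * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def _lr_at(cfg: TrainConfig, it: int, total_iters: int) -> float:
    if it < cfg.warmup_iters:
        return cfg.lr * (it + 1) / cfg.warmup_iters
    t = (it - cfg.warmup_iters) / max(1, total_iters - cfg.warmup_iters)
    floor = cfg.lr * cfg.final_lr_frac
    return floor + 0.5 * (cfg.lr - floor) * (1.0 + np.cos(np.pi * t))


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------

def _to_input(img: np.ndarray) -> np.ndarray:
    x = np.asarray(img, dtype=np.float32) / 255.0
    return np.ascontiguousarray(x.transpose(2, 0, 1))


def _mosaic4(items, rng, size):
    """Four-image mosaic at the training size (each tile half-size)."""
    from PIL import Image as PILImage
    canvas = np.zeros((size, size, 3), dtype=np.uint8)
    anns = []
    half = size // 2
    picks = rng.choice(len(items), 4, replace=len(items) < 4)
    for q, pi in enumerate(picks):
        img, ann = items[pi]
        tile = np.asarray(PILImage.fromarray(img).resize((half, half)))
        sy, sx = (q // 2) * half, (q % 2) * half
        canvas[sy:sy + half, sx:sx + half] = tile
        fy, fx = half / img.shape[0], half / img.shape[1]
        for a in ann:
            anns.append({"box": np.array([a.x1 * fx + sx, a.y1 * fy + sy,
                                          a.x2 * fx + sx, a.y2 * fy + sy]),
                         "cls": a.cls})
    return canvas, anns


def _copy_paste(img, anns, items, rng):
    src_img, src_anns = items[int(rng.integers(len(items)))]
    if not src_anns:
        return img, anns
    a = src_anns[int(rng.integers(len(src_anns)))]
    x1, y1, x2, y2 = map(int, (a.x1, a.y1, a.x2, a.y2))
    patch = src_img[y1:y2, x1:x2]
    if patch.size == 0:
        return img, anns
    h, w = img.shape[:2]
    ph, pw = patch.shape[:2]
    if ph >= h or pw >= w:
        return img, anns
    ox = int(rng.integers(0, w - pw))
    oy = int(rng.integers(0, h - ph))
    img = img.copy()
    img[oy:oy + ph, ox:ox + pw] = patch
    anns = anns + [{"box": np.array([ox, oy, ox + pw, oy + ph], dtype=np.float64),
                    "cls": a.cls}]
    return img, anns


def _random_scale(img, anns, cfg: TrainConfig, rng):
    """Random rescale by (1 +/- scale), refitted onto a same-size canvas."""
    from PIL import Image as PILImage
    h, w = img.shape[:2]
    f = 1.0 + rng.uniform(-cfg.scale, cfg.scale)
    nh, nw = max(8, int(h * f)), max(8, int(w * f))
    resized = np.asarray(PILImage.fromarray(img).resize((nw, nh)))
    canvas = np.full_like(img, 114)
    ch, cw = min(h, nh), min(w, nw)
    canvas[:ch, :cw] = resized[:ch, :cw]
    fx, fy = nw / w, nh / h
    out = []
    for a in anns:
        b = a["box"] * np.array([fx, fy, fx, fy])
        b = np.clip(b, 0, [w, h, w, h])
        if b[2] - b[0] >= 2 and b[3] - b[1] >= 2:
            out.append({"box": b, "cls": a["cls"]})
    return canvas, out


def _prepare_batch(items, idxs, cfg: TrainConfig, rng):
    imgs, gts = [], []
    for i in idxs:
        if cfg.mosaic and rng.uniform() < 0.5:
            img, anns = _mosaic4(items, rng, cfg.img_size)
        else:
            img, ann_objs = items[i]
            anns = [{"box": np.array(a.box, dtype=np.float64), "cls": a.cls}
                    for a in ann_objs]
            if cfg.copy_paste > 0 and rng.uniform() < cfg.copy_paste:
                img, anns = _copy_paste(img, anns, items, rng)
        if cfg.scale > 0:
            img, anns = _random_scale(img, anns, cfg, rng)
        imgs.append(_to_input(img))
        gts.append(anns)
    return np.stack(imgs), gts


# ---------------------------------------------------------------------------
# the loop
# ---------------------------------------------------------------------------

def train(model: PigStressNet, items, cfg: TrainConfig, val_items=None,
          log_fn=None):
    """Train in place; returns per-epoch logs (list of dicts).

    ``items`` is a list of (image, [Annotation]) pairs, e.g. from
    :func:`pigstressnet.synthetic.read_dataset`.
    """
    if not items:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(cfg.seed)
    model.train()
    opt = SGD(model.parameters(), cfg.lr, cfg.momentum, cfg.weight_decay)
    steps_per_epoch = max(1, len(items) // cfg.batch_size)
    total_iters = steps_per_epoch * cfg.epochs
    logs, it = [], 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(items))
        epoch_parts, t0 = [], time.time()
        for step in range(steps_per_epoch):
            idxs = order[step * cfg.batch_size:(step + 1) * cfg.batch_size]
            x, gts = _prepare_batch(items, idxs, cfg, rng)
            opt.lr = _lr_at(cfg, it, total_iters)
            opt.zero_grad()
            outputs = model(T.Tensor(x))
            loss, parts = detection_loss(model, outputs, gts, cfg.img_size, cfg)
            if not np.isfinite(parts["total"]):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} step {step}: {parts}")
            loss.backward()
            opt.step()
            epoch_parts.append(parts)
            it += 1
        log = {k: float(np.mean([p[k] for p in epoch_parts]))
               for k in epoch_parts[0]}
        log.update(epoch=epoch, lr=float(opt.lr), seconds=time.time() - t0)
        logs.append(log)
        if log_fn:
            log_fn(log)
    model.eval()
    return logs


def detect(model: PigStressNet, image: np.ndarray, conf_thr: float = 0.25,
           nms_iou: float = 0.45, stats: RednessStats = RednessStats(),
           fusion_combine: str = "and"):
    """Run inference on one RGB image; returns (detections, fusion report).

    Each detection dict carries box (xyxy pixels), cls (name), conf and
    redness; the fusion report re-scores stress per the lying+erythema
    rule.
    """
    model.eval()
    reg_max = model.head.spec.reg_max
    nc = model.head.spec.n_classes
    img_size = image.shape[0]
    x = _to_input(image)[None]
    with T.no_grad():
        outputs = model(T.Tensor(x))
    from .heads import decode_boxes
    all_boxes, all_scores = [], []
    for (b, c), s in zip(outputs, model.head.spec.strides):
        boxes = decode_boxes(b.data, s, reg_max)[0]
        scores = 1.0 / (1.0 + np.exp(-np.clip(c.data[0].reshape(nc, -1).T, -80, 80)))
        all_boxes.append(boxes)
        all_scores.append(scores)
    boxes = np.concatenate(all_boxes)
    scores = np.concatenate(all_scores)
    dets = []
    max_det = 300
    for ci in range(nc):
        mask = scores[:, ci] >= conf_thr
        if not mask.any():
            continue
        b = boxes[mask]
        sc = scores[mask, ci]
        if sc.size > max_det:
            top = np.argsort(-sc)[:max_det]
            b, sc = b[top], sc[top]
        keep = nms(b, sc, nms_iou)
        for k in keep:
            x1, y1, x2, y2 = np.clip(b[k], 0, img_size)
            if x2 - x1 < 2 or y2 - y1 < 2:
                continue
            dets.append({"box": (float(x1), float(y1), float(x2), float(y2)),
                         "cls": CLASS_NAMES[ci], "cls_idx": ci,
                         "conf": float(sc[k])})
    report = fusion_report(dets, image, stats, fusion_combine) if dets else []
    return dets, report


def evaluate_model(model: PigStressNet, items, conf_thr=0.001, nms_iou=0.45,
                   iou_thr=0.5):
    """mAP@0.5 and confusion matrix of a model over (image, anns) items."""
    preds, gts = [], []
    for img, anns in items:
        dets, _ = detect(model, img, conf_thr, nms_iou)
        preds.append([{"box": d["box"], "cls": d["cls_idx"], "conf": d["conf"]}
                      for d in dets])
        gts.append([{"box": a.box, "cls": a.cls} for a in anns])
    return evaluate(preds, gts, model.head.spec.n_classes, iou_thr)


def save_checkpoint(model: PigStressNet, path: str):
    arrays = dict(model.state_arrays())
    np.savez(path, **arrays)


def load_checkpoint(model: PigStressNet, path: str):
    data = np.load(path)
    model.load_state({k: data[k] for k in data.files})
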
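"""Training-time target assignment, loss, smoke-training loop and evaluator.

The anchor-matching rule follows the YOLOv5 lineage the detector family
descends from (the family's own publications leave it unspecified): a
ground truth is assigned to every anchor whose width and height ratios to
the box lie within [1/4, 4], in the cell containing the box center plus
the two nearest neighbour cells.  The loss is a weighted sum of a CIoU box
term on positives, a binary cross-entropy objectness term against
IoU-weighted labels, and a binary cross-entropy class term (weights
0.5 / 1.0 / 0.5 by default) — a composition chosen here, not taken from
any publication of the wheat-spike study itself.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .head import HeadConfig
from .metrics import EvalResult, evaluate
from .nn import Adam, Tensor
from .synthetic import load_dataset_manifest, read_yolo_labels
from .variants import Detector, ModelVariant, save_checkpoint

logger = logging.getLogger("spikedet")

__all__ = [
    "TrainConfig", "ScaleTargets", "assign_targets", "training_loss",
    "LossBreakdown", "smoke_train", "evaluate_detector", "load_image_dataset",
    "kmeans_anchors",
]


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 8
    lr: float = 8e-3
    lr_final_frac: float = 0.1     # cosine decay floor as a fraction of lr
    warmup_steps: int = 20
    weight_decay: float = 0.0
    box_weight: float = 0.5
    obj_weight: float = 1.0
    cls_weight: float = 0.5
    anchor_ratio_gate: float = 4.0
    seed: int = 0


@dataclass
class ScaleTargets:
    """Positive assignments for one detection scale."""

    img: np.ndarray      # (P,) batch index
    anchor: np.ndarray   # (P,) anchor index within the scale
    gy: np.ndarray       # (P,) cell row
    gx: np.ndarray       # (P,) cell col
    boxes: np.ndarray    # (P, 4) gt boxes, pixel corners
    classes: np.ndarray  # (P,) class ids


def assign_targets(gt_per_image: list, head_cfg: HeadConfig, input_size: int,
                   strides=(16, 32), ratio_gate: float = 4.0) -> list:
    """YOLOv5-style assignment of ground truths to (scale, anchor, cell).

    ``gt_per_image`` is a list (over the batch) of ground-truth box lists
    in pixel coordinates.  Returns one :class:`ScaleTargets` per stride.
    """
    out = []
    for si, stride in enumerate(strides):
        grid = input_size // stride
        anchors = head_cfg.anchors_for_scale(si)
        img_idx, anc_idx, gys, gxs, bxs, clss = [], [], [], [], [], []
        for bi, gts in enumerate(gt_per_image):
            for g in gts:
                w, h = g.width, g.height
                cx, cy = (g.x_min + g.x_max) / 2, (g.y_min + g.y_max) / 2
                fx, fy = cx / stride, cy / stride
                cell_x, cell_y = int(fx), int(fy)
                # containing cell + the two nearest neighbours
                cells = {(cell_x, cell_y)}
                if fx - cell_x < 0.5 and cell_x > 0:
                    cells.add((cell_x - 1, cell_y))
                elif fx - cell_x >= 0.5 and cell_x < grid - 1:
                    cells.add((cell_x + 1, cell_y))
                if fy - cell_y < 0.5 and cell_y > 0:
                    cells.add((cell_x, cell_y - 1))
                elif fy - cell_y >= 0.5 and cell_y < grid - 1:
                    cells.add((cell_x, cell_y + 1))
                for ai, (aw, ah) in enumerate(anchors):
                    rw, rh = w / aw, h / ah
                    gate = max(rw, 1.0 / rw, rh, 1.0 / rh)
                    if gate >= ratio_gate:
                        continue
                    for gx, gy in cells:
                        if 0 <= gx < grid and 0 <= gy < grid:
                            img_idx.append(bi)
                            anc_idx.append(ai)
                            gys.append(gy)
                            gxs.append(gx)
                            bxs.append([g.x_min, g.y_min, g.x_max, g.y_max])
                            clss.append(g.class_id)
        out.append(ScaleTargets(
            img=np.asarray(img_idx, dtype=np.int64),
            anchor=np.asarray(anc_idx, dtype=np.int64),
            gy=np.asarray(gys, dtype=np.int64),
            gx=np.asarray(gxs, dtype=np.int64),
            boxes=np.asarray(bxs, dtype=np.float32).reshape(-1, 4),
            classes=np.asarray(clss, dtype=np.int64)))
    return out


def _bce_with_logits(x: Tensor, target) -> Tensor:
    """Numerically stable elementwise binary cross-entropy on logits."""
    t = target if isinstance(target, Tensor) else Tensor(np.asarray(target, dtype=np.float32))
    absx = x.maximum(-x)
    return x.maximum(0.0) - x * t + (1.0 + (-absx).exp()).log()


def _ciou(px0, py0, px1, py1, gt: np.ndarray) -> Tensor:
    """Differentiable complete-IoU between predicted tensors and fixed boxes."""
    gx0, gy0, gx1, gy1 = (Tensor(gt[:, i]) for i in range(4))
    eps = 1e-7
    iw = px1.minimum(gx1) - px0.maximum(gx0)
    ih = py1.minimum(gy1) - py0.maximum(gy0)
    inter = iw.maximum(0.0) * ih.maximum(0.0)
    area_p = (px1 - px0) * (py1 - py0)
    area_g = (gx1 - gx0) * (gy1 - gy0)
    union = area_p + area_g - inter + eps
    iou_t = inter / union
    # enclosing-box diagonal and center distance
    cw = px1.maximum(gx1) - px0.minimum(gx0)
    ch = py1.maximum(gy1) - py0.minimum(gy0)
    c2 = cw * cw + ch * ch + eps
    rho2 = ((px0 + px1 - gx0 - gx1) ** 2 + (py0 + py1 - gy0 - gy1) ** 2) * 0.25
    # aspect-ratio consistency
    v = (4.0 / math.pi ** 2) * (
        ((gx1 - gx0) / (gy1 - gy0 + eps)).arctan()
        - ((px1 - px0) / (py1 - py0 + eps)).arctan()) ** 2
    alpha = Tensor(v.data / (1.0 - iou_t.data + v.data + eps))  # detached
    return iou_t - rho2 / c2 - alpha * v


@dataclass
class LossBreakdown:
    total: Tensor
    box: float
    obj: float
    cls: float
    n_pos: int


def training_loss(raw, targets: list, head_cfg: HeadConfig, input_size: int,
                  cfg: TrainConfig | None = None) -> LossBreakdown:
    """Composite detection loss for one batch.

    Box: mean(1 - CIoU) over positives, scaled by ``box_weight``.
    Objectness: BCE over every cell/anchor against labels that are the
    (detached) predicted IoU at positives and 0 elsewhere.
    Class: BCE at positives (single-class: target 1), ``cls_weight``.
    """
    cfg = cfg or TrainConfig()
    a = head_cfg.anchors_per_scale
    box_terms, cls_terms, obj_terms = [], [], []
    n_pos_total = 0
    for si, stride in enumerate(raw.strides):
        tgt = targets[si]
        box_map, obj_map, cls_map = raw.box[si], raw.obj[si], raw.cls[si]
        n, _, gh, gw = box_map.shape
        anchors = head_cfg.anchors_for_scale(si)
        obj_label = np.zeros((n, a, gh, gw), dtype=np.float32)
        if len(tgt.img):
            n_pos_total += len(tgt.img)
            bm = box_map.reshape(n, a, 4, gh, gw)
            tx = bm[tgt.img, tgt.anchor, 0, tgt.gy, tgt.gx]
            ty = bm[tgt.img, tgt.anchor, 1, tgt.gy, tgt.gx]
            tw = bm[tgt.img, tgt.anchor, 2, tgt.gy, tgt.gx]
            th = bm[tgt.img, tgt.anchor, 3, tgt.gy, tgt.gx]
            aw = anchors[tgt.anchor, 0]
            ah = anchors[tgt.anchor, 1]
            cx = (2.0 * tx.sigmoid() - 0.5 + Tensor(tgt.gx.astype(np.float32))) * stride
            cy = (2.0 * ty.sigmoid() - 0.5 + Tensor(tgt.gy.astype(np.float32))) * stride
            bw = Tensor(aw) * (2.0 * tw.sigmoid()) ** 2
            bh = Tensor(ah) * (2.0 * th.sigmoid()) ** 2
            ciou = _ciou(cx - bw * 0.5, cy - bh * 0.5,
                         cx + bw * 0.5, cy + bh * 0.5, tgt.boxes)
            box_terms.append((1.0 - ciou).sum())
            # objectness labels: clipped predicted IoU, no gradient
            obj_label[tgt.img, tgt.anchor, tgt.gy, tgt.gx] = np.clip(
                ciou.data, 0.0, 1.0)
            cm = cls_map.reshape(n, head_cfg.num_classes, gh, gw)
            logits = cm[tgt.img, tgt.classes, tgt.gy, tgt.gx]
            cls_terms.append(_bce_with_logits(logits, np.ones(len(tgt.img),
                                                              dtype=np.float32)).sum())
        obj_terms.append(_bce_with_logits(
            obj_map.reshape(n, a, gh, gw), obj_label).mean())

    n_pos = max(n_pos_total, 1)
    box_l = (sum(box_terms) * (1.0 / n_pos)) if box_terms else Tensor(0.0)
    cls_l = (sum(cls_terms) * (1.0 / n_pos)) if cls_terms else Tensor(0.0)
    obj_l = sum(obj_terms) * (1.0 / len(obj_terms))
    total = cfg.box_weight * box_l + cfg.obj_weight * obj_l + cfg.cls_weight * cls_l
    return LossBreakdown(total=total, box=float(box_l.data),
                         obj=float(obj_l.data), cls=float(cls_l.data),
                         n_pos=n_pos_total)


# -- data loading ---------------------------------------------------------

def load_image_dataset(dataset_dir, indices=None) -> tuple:
    """Read a generated dataset from disk into (images, gt_lists, ids)."""
    root = Path(dataset_dir)
    manifest = load_dataset_manifest(root)
    size = manifest["image_size"]
    entries = manifest["images"]
    if indices is not None:
        entries = [entries[i] for i in indices]
    images, gts, ids = [], [], []
    for e in entries:
        img = iio.imread(root / "images" / f"{e['image_id']}.png")
        images.append(np.asarray(img))
        gts.append(read_yolo_labels(root / "labels" / f"{e['image_id']}.txt", size))
        ids.append(e["image_id"])
    return images, gts, ids


def kmeans_anchors(gt_lists: list, n_anchors: int = 6, seed: int = 0,
                   iters: int = 50) -> np.ndarray:
    """Plain k-means over box (w, h) pairs; rows sorted by area ascending."""
    wh = np.array([[g.width, g.height] for gts in gt_lists for g in gts],
                  dtype=np.float64)
    if len(wh) < n_anchors:
        raise ValueError("need at least as many boxes as anchors")
    rng = np.random.default_rng(seed)
    centers = wh[rng.choice(len(wh), n_anchors, replace=False)]
    for _ in range(iters):
        d = ((wh[:, None, :] - centers[None]) ** 2).sum(-1)
        lab = d.argmin(1)
        for k in range(n_anchors):
            if np.any(lab == k):
                centers[k] = wh[lab == k].mean(0)
    return centers[np.argsort(centers.prod(1))]


# -- training loop --------------------------------------------------------

@dataclass
class TrainResult:
    epoch_losses: list
    checkpoint_path: str | None
    detector: Detector


def _lr_at(step: int, total: int, cfg: TrainConfig) -> float:
    if step < cfg.warmup_steps:
        return cfg.lr * (step + 1) / cfg.warmup_steps
    frac = (step - cfg.warmup_steps) / max(total - cfg.warmup_steps, 1)
    floor = cfg.lr * cfg.lr_final_frac
    return floor + 0.5 * (cfg.lr - floor) * (1 + math.cos(math.pi * frac))


def smoke_train(variant: ModelVariant | Detector, images: list, gt_lists: list,
                cfg: TrainConfig | None = None,
                checkpoint_path=None) -> TrainResult:
    """Deterministic small-scale training on an in-memory dataset.

    ``images`` are HWC uint8 arrays at the detector's input size.  Returns
    per-epoch mean losses and (optionally) writes a checkpoint loadable by
    :func:`spikedet.variants.load_checkpoint`.
    """
    cfg = cfg or TrainConfig()
    det = variant.build() if isinstance(variant, ModelVariant) else variant
    size = det.input_size
    for im in images:
        if im.shape[0] != size or im.shape[1] != size:
            raise ValueError(f"image size {im.shape[:2]} != detector input {size}")
    data = np.stack([im.astype(np.float32) / 255.0 for im in images])
    data = data.transpose(0, 3, 1, 2)

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(det.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    n = len(images)
    steps_per_epoch = max(1, math.ceil(n / cfg.batch_size))
    total_steps = steps_per_epoch * cfg.epochs
    det.train(True)
    epoch_losses = []
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        running = []
        for bi in range(steps_per_epoch):
            idx = order[bi * cfg.batch_size:(bi + 1) * cfg.batch_size]
            if len(idx) == 0:
                continue
            batch = Tensor(data[idx])
            gts = [gt_lists[i] for i in idx]
            targets = assign_targets(gts, det.head_cfg, size,
                                     ratio_gate=cfg.anchor_ratio_gate)
            raw = det(batch)
            loss = training_loss(raw, targets, det.head_cfg, size, cfg)
            if not np.isfinite(loss.total.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} step {bi}: "
                    f"box={loss.box:.4f} obj={loss.obj:.4f} cls={loss.cls:.4f}")
            opt.zero_grad()
            loss.total.backward()
            opt.lr = _lr_at(step, total_steps, cfg)
            opt.step()
            running.append(float(loss.total.data))
            step += 1
        epoch_losses.append(float(np.mean(running)))
        logger.info("epoch %d/%d loss %.4f (lr %.2e)", epoch + 1, cfg.epochs,
                    epoch_losses[-1], opt.lr)
    ckpt = None
    if checkpoint_path is not None:
        save_checkpoint(checkpoint_path, det,
                        extra={"epoch_losses": epoch_losses})
        ckpt = str(checkpoint_path)
    return TrainResult(epoch_losses=epoch_losses, checkpoint_path=ckpt,
                       detector=det)


def run_smoke_benchmark(seed: int = 1, n_images: int = 200, epochs: int = 30,
                        variant_name: str = "YOLO-FastestV2",
                        input_size: int = 160) -> dict:
    """End-to-end pipeline check: generate -> train -> evaluate.

    Renders ``n_images`` easy synthetic scenes (large, sparse, unoccluded
    spikes), smoke-trains the named variant on the 80% train split and
    evaluates on the held-out test split.  Returns a dict with the loss
    trace and the test-split :class:`EvalResult`.  This is a functional
    floor for the pipeline, not a statement about field imagery.
    """
    from dataclasses import replace

    from .backbone import BackboneConfig
    from .synthetic import EASY_PRESET, SplitSpec, generate_scene, split_dataset
    from .variants import build_variant

    preset = replace(EASY_PRESET, image_size=input_size)
    ss = np.random.SeedSequence(entropy=seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_images)]
    scenes = [generate_scene(preset, seed=s) for s in seeds]
    images = [s.pixels for s in scenes]
    gts = [s.boxes for s in scenes]

    anchors = kmeans_anchors(gts, 6, seed=seed % (2 ** 31))
    head_cfg = HeadConfig(anchor_sizes=tuple(map(tuple, anchors)))
    variant = build_variant(
        variant_name,
        backbone_cfg=BackboneConfig(input_size=input_size, seed=seed % (2 ** 31)),
        head_cfg=head_cfg)
    train_ids, _, test_ids = split_dataset(n_images, SplitSpec(seed=seed))
    tc = TrainConfig(epochs=epochs, seed=seed % (2 ** 31))
    result = smoke_train(variant, [images[i] for i in train_ids],
                         [gts[i] for i in train_ids], tc)
    ev = evaluate_detector(result.detector, [images[i] for i in test_ids],
                           [gts[i] for i in test_ids])
    return {"losses": result.epoch_losses, "eval": ev,
            "detector": result.detector,
            "n_train": len(train_ids), "n_test": len(test_ids)}


def evaluate_detector(det: Detector, images: list, gt_lists: list,
                      ids: list | None = None, conf_threshold: float = 0.25,
                      nms_iou: float = 0.45,
                      decode_threshold: float = 0.05) -> EvalResult:
    """Run the detector over a split and score it.

    Decoding uses a low score floor (``decode_threshold``) so the PR curve
    is well populated; the reported P/R operating point uses
    ``conf_threshold``.
    """
    ids = ids or [f"img_{i}" for i in range(len(images))]
    dets_per_image, gts_per_image = {}, {}
    for img, gts, iid in zip(images, gt_lists, ids):
        dets_per_image[iid] = det.predict(img, conf_threshold=decode_threshold,
                                          nms_iou=nms_iou)
        gts_per_image[iid] = gts
    return evaluate(dets_per_image, gts_per_image,
                    conf_threshold=conf_threshold,
                    num_classes=det.head_cfg.num_classes)
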
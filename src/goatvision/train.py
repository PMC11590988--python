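"""Desk-scale training: target assignment and a short smoke fit.

The assigner is a task-aligned top-k rule: for each ground-truth box the
candidate anchors are those whose center lies inside the box; candidates are
ranked by the alignment metric ``score^0.5 * IoU^6`` (classification score of
the true class times the IoU of the decoded prediction) and the top k=10 are
taken as positives.  An anchor claimed by several boxes goes to the box with
the highest alignment.  Any consistent positive-sampling rule works at this
scale; this one matches the convention of the anchor-free detector family.

``fit_smoke`` runs a few hundred Adam steps on a small synthetic batch with
Mixup, and exists to demonstrate that the assembled network, the losses and
the autodiff engine optimize end to end — not to reach farm-data accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from . import nn
from .losses import (Assignment, LossBreakdown, LossWeights, anchor_grid,
                     decode_boxes, flatten_output, total_loss)
from .model_zoo import Detector, letterbox
from .nn import Tensor
from .types import AnnotatedImage, Box, boxes_as_array


@dataclass
class OptimizerConfig:
    lr: float = 1e-3
    weight_decay: float = 1e-5
    betas: tuple[float, float] = (0.9, 0.999)


@dataclass
class SmokeFitConfig:
    steps: int = 200
    image_size: int = 64          # training canvas (must be divisible by 32)
    mixup_prob: float = 0.5       # fraction of images mixed per step
    mixup_alpha: float = 0.2      # Beta(alpha, alpha) mixing weight
    topk: int = 10
    loss_weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0

    def __post_init__(self):
        if self.steps > 500:
            raise ValueError("smoke fit is capped at 500 steps")
        if self.image_size % 32:
            raise ValueError("image_size must be divisible by 32")


def assign_targets(output, gt_boxes: Sequence[np.ndarray],
                   gt_cls: Sequence[np.ndarray], reg_max: int,
                   topk: int = 10) -> Assignment:
    """Task-aligned top-k assignment of ground truth to anchors.

    ``gt_boxes[i]`` is an (G_i, 4) xyxy array in canvas pixels and
    ``gt_cls[i]`` the matching class indices, for image i of the batch.
    """
    from .model_zoo import iou_matrix

    shapes = [(m.shape[2], m.shape[3]) for m in output.box_maps]
    points, strides = anchor_grid(output.strides, shapes)
    M = len(points)
    N = len(gt_boxes)

    with nn.no_grad():
        box_pred, cls_pred = flatten_output(output)
        pred_xyxy = decode_boxes(box_pred, points, strides, reg_max).data
        scores = 1.0 / (1.0 + np.exp(-cls_pred.data))

    fg = np.zeros((N, M), dtype=bool)
    tboxes = np.zeros((N, M, 4))
    tcls = np.zeros((N, M), dtype=int)
    for i in range(N):
        g = np.asarray(gt_boxes[i], dtype=float).reshape(-1, 4)
        if len(g) == 0:
            continue
        c = np.asarray(gt_cls[i], dtype=int)
        inside = ((points[:, 0:1] > g[:, 0]) & (points[:, 0:1] < g[:, 2])
                  & (points[:, 1:2] > g[:, 1]) & (points[:, 1:2] < g[:, 3]))  # (M, G)
        ious = iou_matrix(pred_xyxy[i], g)                       # (M, G)
        s = scores[i][np.arange(M)[:, None], c[None, :]]         # (M, G)
        align = (s ** 0.5) * (ious ** 6.0) + 1e-9 * inside       # tiny center prior
        align = np.where(inside, align, -1.0)
        best_align = np.full(M, -1.0)
        best_gt = np.full(M, -1, dtype=int)
        for j in range(len(g)):
            cand = np.nonzero(inside[:, j])[0]
            if len(cand) == 0:
                continue
            take = cand[np.argsort(-align[cand, j], kind="stable")[:topk]]
            better = align[take, j] > best_align[take]
            best_align[take[better]] = align[take[better], j]
            best_gt[take[better]] = j
        pos = best_gt >= 0
        fg[i, pos] = True
        tboxes[i, pos] = g[best_gt[pos]]
        tcls[i, pos] = c[best_gt[pos]]
    return Assignment(anchor_points=points, anchor_strides=strides,
                      fg_mask=fg, target_boxes=tboxes, target_cls=tcls)


def _prepare_batch(dataset: Sequence[AnnotatedImage], size: int
                   ) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]:
    """Letterbox every image to the training canvas; boxes follow."""
    imgs, boxes, cls = [], [], []
    for im in dataset:
        canvas, tf = letterbox(im.pixels, size)
        imgs.append(canvas.astype(np.float32).transpose(2, 0, 1) / 255.0)
        if im.boxes:
            xy = tf.source_to_canvas(boxes_as_array(im.boxes))
            boxes.append(xy)
            cls.append(np.array([b.cls_index for b in im.boxes], dtype=int))
        else:
            boxes.append(np.zeros((0, 4)))
            cls.append(np.zeros(0, dtype=int))
    return np.stack(imgs), boxes, cls


def fit_smoke(detector: Detector, dataset: Sequence[AnnotatedImage],
              steps: int = 200,
              optimizer_config: Optional[OptimizerConfig] = None,
              config: Optional[SmokeFitConfig] = None,
              callback: Optional[Callable[[int, LossBreakdown], None]] = None
              ) -> list[float]:
    """Run ``steps`` optimizer steps on a fixed batch; return the loss trace.

    Mixup blends pairs of training images (pixels only — the box lists are
    united), with the mixing weight drawn from Beta(alpha, alpha) so most
    draws stay near 0 or 1.  The run is fully determined by the seeds in the
    configs and the detector's initial weights.
    """
    if len(dataset) == 0:
        raise ValueError("dataset must contain at least one annotated image")
    if len(dataset) < 8:
        raise ValueError("smoke fit expects >= 8 images")
    opt_cfg = optimizer_config or OptimizerConfig()
    cfg = config or SmokeFitConfig(steps=steps)
    if cfg.steps != steps:
        cfg = SmokeFitConfig(**{**cfg.__dict__, "steps": steps})

    pixels, gt_boxes, gt_cls = _prepare_batch(dataset, cfg.image_size)
    rng = np.random.default_rng(cfg.seed)
    optimizer = nn.Adam(detector.parameters(), lr=opt_cfg.lr,
                        betas=opt_cfg.betas, weight_decay=opt_cfg.weight_decay)
    detector.train()
    reg_max = detector.config.reg_max
    trace: list[float] = []
    n = len(dataset)
    for step in range(cfg.steps):
        px = pixels.copy()
        boxes = [b.copy() for b in gt_boxes]
        cls = [c.copy() for c in gt_cls]
        for i in range(n):
            if rng.random() < cfg.mixup_prob:
                j = int(rng.integers(n))
                lam = float(rng.beta(cfg.mixup_alpha, cfg.mixup_alpha))
                px[i] = lam * pixels[i] + (1 - lam) * pixels[j]
                if j != i:
                    boxes[i] = np.concatenate([gt_boxes[i], gt_boxes[j]])
                    cls[i] = np.concatenate([gt_cls[i], gt_cls[j]])
        out = detector(Tensor(px))
        assignment = assign_targets(out, boxes, cls, reg_max, cfg.topk)
        breakdown = total_loss(out, assignment, cfg.loss_weights,
                               box_loss_kind=detector.config.box_loss)
        optimizer.zero_grad()
        breakdown.total_tensor.backward()
        optimizer.step()
        trace.append(breakdown.total)
        if callback:
            callback(step, breakdown)
    return trace
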
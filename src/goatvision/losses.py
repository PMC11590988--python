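"""The training objective: IoU-family box regression losses (IoU, CIoU, EIoU,
SIoU, Alpha-CIoU), the distribution (binned-distance) regression loss, the
binary cross-entropy classification loss, and their weighted combination.

All regression losses share the scale- and translation-invariant penalty
vocabulary: ``rho^2 / c^2`` (squared center gap over squared enclosing-box
diagonal), the aspect term ``v = (4/pi^2) (atan(w_t/h_t) - atan(w_p/h_p))^2``
with trade-off ``alpha_c = v / ((1 - IoU) + v)``, EIoU's width/height gap
terms over the enclosing box's width/height, and SIoU's angle-modulated
distance cost plus shape cost.  Alpha-CIoU raises each CIoU term to the power
``a`` (default 3), which sharpens the gradient for high-IoU boxes.

Every function accepts and returns autodiff tensors so the smoke trainer can
backpropagate through them; scalar convenience wrappers take :class:`Box`
pairs and return floats.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from . import nn
from .nn import Tensor
from .types import Box

_EPS = 1e-9

BOX_LOSS_KINDS = ("iou", "ciou", "eiou", "siou", "alpha_ciou")


def _as_boxes_tensor(x) -> Tensor:
    if isinstance(x, Box):
        return Tensor(x.xyxy().reshape(1, 4))
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=float).reshape(-1, 4))


def _parts(b: Tensor):
    x1 = nn.narrow(b, -1, 0, 1)
    y1 = nn.narrow(b, -1, 1, 1)
    x2 = nn.narrow(b, -1, 2, 1)
    y2 = nn.narrow(b, -1, 3, 1)
    return x1, y1, x2, y2


def _check_degenerate(b: Tensor) -> None:
    d = b.data.reshape(-1, 4)
    if np.any((d[:, 2] - d[:, 0]) <= 0) or np.any((d[:, 3] - d[:, 1]) <= 0):
        warnings.warn("degenerate (zero-area) box in IoU computation; "
                      "its IoU is defined as 0", stacklevel=3)


def iou(pred, target) -> Tensor:
    """Elementwise IoU of two (..., 4) xyxy tensors (0 for disjoint pairs)."""
    p, t = _as_boxes_tensor(pred), _as_boxes_tensor(target)
    _check_degenerate(p)
    _check_degenerate(t)
    px1, py1, px2, py2 = _parts(p)
    tx1, ty1, tx2, ty2 = _parts(t)
    ix = nn.clamp(nn.minimum(px2, tx2) - nn.maximum(px1, tx1), 0)
    iy = nn.clamp(nn.minimum(py2, ty2) - nn.maximum(py1, ty1), 0)
    inter = ix * iy
    area_p = nn.clamp((px2 - px1), 0) * nn.clamp((py2 - py1), 0)
    area_t = nn.clamp((tx2 - tx1), 0) * nn.clamp((ty2 - ty1), 0)
    union = area_p + area_t - inter
    return inter / (union + _EPS)


def _geometry(pred: Tensor, target: Tensor):
    """Shared penalty-term geometry for the CIoU family."""
    px1, py1, px2, py2 = _parts(pred)
    tx1, ty1, tx2, ty2 = _parts(target)
    pw, ph = px2 - px1, py2 - py1
    tw, th = tx2 - tx1, ty2 - ty1
    pcx, pcy = (px1 + px2) * 0.5, (py1 + py2) * 0.5
    tcx, tcy = (tx1 + tx2) * 0.5, (ty1 + ty2) * 0.5
    cw = nn.maximum(px2, tx2) - nn.minimum(px1, tx1)  # enclosing box
    ch = nn.maximum(py2, ty2) - nn.minimum(py1, ty1)
    rho2 = (pcx - tcx) ** 2 + (pcy - tcy) ** 2
    c2 = cw ** 2 + ch ** 2
    return dict(pw=pw, ph=ph, tw=tw, th=th, pcx=pcx, pcy=pcy, tcx=tcx,
                tcy=tcy, cw=cw, ch=ch, rho2=rho2, c2=c2)


def _aspect_terms(g, i: Tensor):
    v = (4.0 / math.pi ** 2) * (nn.atan(g["tw"] / (g["th"] + _EPS))
                                - nn.atan(g["pw"] / (g["ph"] + _EPS))) ** 2
    # the trade-off coefficient is treated as a constant (standard practice)
    alpha_c = v.data / ((1.0 - i.data) + v.data + _EPS)
    return v, Tensor(alpha_c)


def ciou_loss(pred, target) -> Tensor:
    """Complete-IoU loss: ``1 - IoU + rho^2/c^2 + alpha_c * v``."""
    p, t = _as_boxes_tensor(pred), _as_boxes_tensor(target)
    i = iou(p, t)
    g = _geometry(p, t)
    v, alpha_c = _aspect_terms(g, i)
    return (1.0 - i) + g["rho2"] / (g["c2"] + _EPS) + alpha_c * v


def alpha_ciou_loss(pred, target, a: float = 3.0) -> Tensor:
    """Alpha-CIoU: each CIoU term raised to the power ``a`` (a=1 recovers CIoU)."""
    if a <= 0:
        raise ValueError("alpha exponent must be > 0")
    p, t = _as_boxes_tensor(pred), _as_boxes_tensor(target)
    i = iou(p, t)
    g = _geometry(p, t)
    v, alpha_c = _aspect_terms(g, i)
    av = alpha_c * v
    if a < 1:  # keep the fractional power differentiable at 0
        av = nn.clamp(av, _EPS)
    return (1.0 - i ** a) + (g["rho2"] / (g["c2"] + _EPS)) ** a + av ** a


def eiou_loss(pred, target) -> Tensor:
    """Efficient-IoU loss: center, width and height gap penalties."""
    p, t = _as_boxes_tensor(pred), _as_boxes_tensor(target)
    i = iou(p, t)
    g = _geometry(p, t)
    return (1.0 - i) + g["rho2"] / (g["c2"] + _EPS) \
        + (g["pw"] - g["tw"]) ** 2 / (g["cw"] ** 2 + _EPS) \
        + (g["ph"] - g["th"]) ** 2 / (g["ch"] ** 2 + _EPS)


def siou_loss(pred, target) -> Tensor:
    """SCYLLA-IoU loss with angle-modulated distance cost and shape cost."""
    p, t = _as_boxes_tensor(pred), _as_boxes_tensor(target)
    i = iou(p, t)
    g = _geometry(p, t)
    s_cw = g["tcx"] - g["pcx"]
    s_ch = g["tcy"] - g["pcy"]
    sigma = nn.sqrt(s_cw ** 2 + s_ch ** 2 + _EPS)
    sin_a = nn.abs_(s_ch) / sigma
    sin_b = nn.abs_(s_cw) / sigma
    thr = math.sqrt(2) / 2
    # past 45 degrees, measure the angle to the other axis
    use_b = sin_a.data > thr
    sin_x = Tensor(np.where(use_b, sin_b.data, sin_a.data))
    # sin(2 arcsin x) = 2 x sqrt(1 - x^2)
    angle = 2.0 * sin_x * nn.sqrt(nn.clamp(1.0 - sin_x ** 2, 0.0))
    gamma = 2.0 - angle
    rho_x = (s_cw / (g["cw"] + _EPS)) ** 2
    rho_y = (s_ch / (g["ch"] + _EPS)) ** 2
    distance = (1.0 - nn.exp(-gamma * rho_x)) + (1.0 - nn.exp(-gamma * rho_y))
    ww = nn.abs_(g["pw"] - g["tw"]) / (nn.maximum(g["pw"], g["tw"]) + _EPS)
    wh = nn.abs_(g["ph"] - g["th"]) / (nn.maximum(g["ph"], g["th"]) + _EPS)
    theta = 4.0
    shape = (1.0 - nn.exp(-ww)) ** theta + (1.0 - nn.exp(-wh)) ** theta
    return (1.0 - i) + (distance + shape) * 0.5


def iou_loss(pred, target) -> Tensor:
    p, t = _as_boxes_tensor(pred), _as_boxes_tensor(target)
    return 1.0 - iou(p, t)


_BOX_LOSSES = {
    "iou": iou_loss,
    "ciou": ciou_loss,
    "eiou": eiou_loss,
    "siou": siou_loss,
}


def box_loss(pred, target, kind: str = "ciou", a: float = 3.0) -> Tensor:
    if kind == "alpha_ciou":
        return alpha_ciou_loss(pred, target, a)
    if kind not in _BOX_LOSSES:
        raise ValueError(f"unknown box loss {kind!r}; choose from {BOX_LOSS_KINDS}")
    return _BOX_LOSSES[kind](pred, target)


# scalar convenience API on Box pairs -----------------------------------------

def pair_value(fn, pred: Box, target: Box, **kw) -> float:
    return float(fn(pred, target, **kw).data.reshape(-1)[0])


# ---------------------------------------------------------------------------
# distribution (binned-distance) regression loss
# ---------------------------------------------------------------------------

def dfl_loss(bin_logits, continuous_target, reduce: bool = True) -> Tensor:
    """Cross-entropy against the two integer bins bracketing each target.

    ``bin_logits`` has ``reg_max`` logits on the last axis; each continuous
    target ``t`` in ``[0, reg_max - 1]`` contributes
    ``-( (r - t) log p_l + (t - l) log p_r )`` with ``l = floor(t)``,
    ``r = l + 1``.  Targets outside the range are clamped with a warning.
    """
    logits = bin_logits if isinstance(bin_logits, Tensor) else Tensor(np.asarray(bin_logits, dtype=float))
    reg_max = logits.shape[-1]
    t = np.asarray(continuous_target, dtype=float)
    if np.any(t < 0) or np.any(t > reg_max - 1):
        warnings.warn(f"distribution-loss target outside [0, {reg_max - 1}]; clamping")
        t = np.clip(t, 0, reg_max - 1)
    t = np.minimum(t, reg_max - 1 - 1e-6)
    left = np.floor(t).astype(np.intp)
    right = left + 1
    wl = right - t
    wr = t - left
    logp = nn.log_softmax(logits, axis=-1)
    lp_l = nn.take_along(logp, left[..., None], axis=-1)
    lp_r = nn.take_along(logp, right[..., None], axis=-1)
    losses = -(Tensor(wl[..., None]) * lp_l + Tensor(wr[..., None]) * lp_r)
    return nn.tmean(losses) if reduce else losses


def cls_loss(class_logits, targets) -> Tensor:
    """Mean binary cross-entropy with logits over classes and positions."""
    z = class_logits if isinstance(class_logits, Tensor) else Tensor(np.asarray(class_logits, dtype=float))
    t = np.asarray(targets, dtype=float)
    if t.shape != z.shape:
        raise ValueError(f"targets shape {t.shape} != logits shape {z.shape}")
    # stable BCE-with-logits: max(z,0) - z*t + log(1 + exp(-|z|))
    loss = nn.relu(z) - z * Tensor(t) + nn.log(1.0 + nn.exp(-nn.abs_(z)))
    return nn.tmean(loss)


# ---------------------------------------------------------------------------
# total objective
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LossWeights:
    box: float = 7.5
    dfl: float = 1.5
    cls: float = 0.5


@dataclass
class Assignment:
    """Anchor-level targets for one batch, produced by the trainer's assigner.

    ``anchor_points`` are canvas-pixel anchor centers stacked across the
    three scales, ``anchor_strides`` the per-anchor stride.  ``fg_mask``
    flags positive anchors per image; target boxes/classes are valid at
    positive anchors only.
    """

    anchor_points: np.ndarray    # (M, 2)
    anchor_strides: np.ndarray   # (M,)
    fg_mask: np.ndarray          # (N, M) bool
    target_boxes: np.ndarray     # (N, M, 4) canvas xyxy
    target_cls: np.ndarray       # (N, M) int


@dataclass
class LossBreakdown:
    box_loss: float
    dfl_loss: float
    cls_loss: float
    total: float
    weights: LossWeights
    total_tensor: Optional[Tensor] = None


def flatten_output(output) -> tuple[Tensor, Tensor]:
    """Per-scale maps -> (N, M, 4*reg_max) and (N, M, nc) anchor-major tensors."""
    box_flat, cls_flat = [], []
    for bmap, cmap in zip(output.box_maps, output.cls_maps):
        N, C, h, w = bmap.shape
        box_flat.append(nn.transpose(nn.reshape(bmap, (N, C, h * w)), (0, 2, 1)))
        Nc = cmap.shape[1]
        cls_flat.append(nn.transpose(nn.reshape(cmap, (N, Nc, h * w)), (0, 2, 1)))
    return nn.concat(box_flat, axis=1), nn.concat(cls_flat, axis=1)


def anchor_grid(strides, shapes) -> tuple[np.ndarray, np.ndarray]:
    """Anchor centers (canvas px) and strides for per-scale map shapes."""
    pts, sts = [], []
    for s, (h, w) in zip(strides, shapes):
        cx = (np.arange(w) + 0.5) * s
        cy = (np.arange(h) + 0.5) * s
        CX, CY = np.meshgrid(cx, cy)
        pts.append(np.stack([CX.ravel(), CY.ravel()], axis=1))
        sts.append(np.full(h * w, s, dtype=float))
    return np.concatenate(pts), np.concatenate(sts)


def decode_boxes(box_pred: Tensor, anchor_points: np.ndarray,
                 anchor_strides: np.ndarray, reg_max: int) -> Tensor:
    """Differentiable expected-bin decode: (N, M, 4*reg_max) -> (N, M, 4) xyxy."""
    N, M, _ = box_pred.shape
    logits = nn.reshape(box_pred, (N, M, 4, reg_max))
    p = nn.softmax(logits, axis=-1)
    bins = Tensor(np.arange(reg_max, dtype=float).reshape(1, 1, 1, reg_max))
    dist = nn.tsum(p * bins, axis=-1)  # (N, M, 4) in stride units
    s = Tensor(anchor_strides.reshape(1, M, 1))
    dist = dist * s
    ax = Tensor(anchor_points[None, :, 0:1])
    ay = Tensor(anchor_points[None, :, 1:2])
    l = nn.narrow(dist, 2, 0, 1)
    t = nn.narrow(dist, 2, 1, 1)
    r = nn.narrow(dist, 2, 2, 1)
    b = nn.narrow(dist, 2, 3, 1)
    return nn.concat([ax - l, ay - t, ax + r, ay + b], axis=2)


def total_loss(detector_output, assignment: Assignment,
               weights: LossWeights = LossWeights(),
               box_loss_kind: str = "ciou", a: float = 3.0) -> LossBreakdown:
    """Weighted sum of box + distribution + classification losses.

    With no positive anchors the box and distribution terms are zero and the
    classification term is still computed (all-background targets).
    """
    if box_loss_kind not in BOX_LOSS_KINDS:
        raise ValueError(f"unknown box loss {box_loss_kind!r}")
    reg_max = detector_output.box_maps[0].shape[1] // 4
    box_pred, cls_pred = flatten_output(detector_output)
    N, M, nc = cls_pred.shape

    # classification: one-hot targets at positive anchors
    cls_targets = np.zeros((N, M, nc))
    fg = assignment.fg_mask
    if fg.any():
        n_idx, m_idx = np.nonzero(fg)
        cls_targets[n_idx, m_idx, assignment.target_cls[n_idx, m_idx]] = 1.0
    l_cls = cls_loss(cls_pred, cls_targets)

    if fg.any():
        pred_boxes = decode_boxes(box_pred, assignment.anchor_points,
                                  assignment.anchor_strides, reg_max)
        flat_idx = n_idx * M + m_idx
        pb = nn.gather_rows(nn.reshape(pred_boxes, (N * M, 4)), flat_idx)
        tb = assignment.target_boxes[n_idx, m_idx]
        l_box = nn.tmean(box_loss(pb, Tensor(tb), kind=box_loss_kind, a=a))

        strides = assignment.anchor_strides[m_idx]
        pts = assignment.anchor_points[m_idx]
        ltrb = np.stack([
            (pts[:, 0] - tb[:, 0]) / strides,
            (pts[:, 1] - tb[:, 1]) / strides,
            (tb[:, 2] - pts[:, 0]) / strides,
            (tb[:, 3] - pts[:, 1]) / strides,
        ], axis=1)
        ltrb = np.clip(ltrb, 0, reg_max - 1 - 1e-3)
        blog = nn.reshape(nn.gather_rows(
            nn.reshape(box_pred, (N * M, 4 * reg_max)), flat_idx), (-1, 4, reg_max))
        l_dfl = dfl_loss(blog, ltrb)
    else:
        l_box = Tensor(0.0)
        l_dfl = Tensor(0.0)

    total = weights.box * l_box + weights.dfl * l_dfl + weights.cls * l_cls
    return LossBreakdown(
        box_loss=float(l_box.data), dfl_loss=float(l_dfl.data),
        cls_loss=float(l_cls.data), total=float(total.data),
        weights=weights, total_tensor=total)
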
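"""Detector construction: the baseline n-scale one-stage network and its
lightweight variants, plus letterboxing, decoding, NMS and attention heatmaps.

The baseline follows the standard n-scale layout of the anchor-free YOLO
family: a stem plus four stages of C2f blocks (repeats 1/2/2/1 after depth
scaling, widths 16/32/64/128/256 after width scaling), SPPF at the end of the
backbone, a top-down + bottom-up feature-pyramid neck with four C2f blocks,
and a decoupled head predicting a discrete distance distribution
(``reg_max`` bins per box side) and per-class logits at strides 8/16/32.

Variants substitute the C2f bottlenecks:

* ``gnca`` — every bottleneck becomes a GC-BottleNeck
  (Ghost module -> channel attention -> Ghost module, plus residual);
* ``snca`` — every bottleneck becomes an SC-BottleNeck
  (GSConv -> channel attention -> GSConv, plus residual);
* ``gsca`` — GC-BottleNecks in the backbone, SC-BottleNecks in the neck.

``fpn_attention`` inserts an attention block at each of the four neck fusion
points (applied to the concatenated features entering each neck C2f).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from PIL import Image

from . import nn
from .nn import Tensor
from .types import CLASSES, Box

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

VARIANTS = ("baseline", "gnca", "snca", "gsca")
ATTENTION_KINDS = ("none", "ca", "se", "cbam", "nonlocal")


@dataclass
class ArchitectureConfig:
    variant: str = "baseline"
    depth_multiple: float = 0.33
    width_multiple: float = 0.25
    max_channels: int = 1024
    nc: int = 4
    reg_max: int = 16
    fpn_attention: str = "none"
    ghost_ratio: int = 2
    attention_reduction: int = 16
    bottleneck_ca_reduction: int = 2
    box_loss: str = "ciou"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.fpn_attention not in ATTENTION_KINDS:
            raise ValueError(
                f"unknown attention {self.fpn_attention!r}; choose from {ATTENTION_KINDS}")
        if self.nc < 1 or self.reg_max < 2:
            raise ValueError("nc must be >= 1 and reg_max >= 2")
        if self.depth_multiple <= 0 or self.width_multiple <= 0:
            raise ValueError("depth/width multiples must be > 0")
        if self.ghost_ratio < 2:
            raise ValueError("ghost_ratio must be >= 2")


def variant_config(name: str, nc: int = 4) -> ArchitectureConfig:
    """Presets for the three named lightweight models (CBAM in the FPN,
    Alpha-CIoU regression loss) and the plain baseline."""
    if name == "baseline":
        return ArchitectureConfig(variant="baseline", nc=nc)
    return ArchitectureConfig(variant=name, nc=nc, fpn_attention="cbam",
                              box_loss="alpha_ciou")


@dataclass(frozen=True)
class EvalProtocol:
    conf_threshold: float = 0.001
    nms_iou: float = 0.5

    def __post_init__(self):
        if not (0 < self.conf_threshold < 1 and 0 < self.nms_iou < 1):
            raise ValueError("thresholds must lie in (0, 1)")


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

class ChannelAttention(nn.Module):
    """Squeeze-excitation-style channel gating: GAP -> bottleneck -> sigmoid."""

    def __init__(self, channels: int, reduction: int = 16):
        super().__init__()
        if channels < reduction:
            raise ValueError(f"channels ({channels}) must be >= reduction ({reduction})")
        hidden = max(1, channels // reduction)
        self.fc1 = nn.Conv2d(channels, hidden, 1, bias=True)
        self.fc2 = nn.Conv2d(hidden, channels, 1, bias=True)

    def forward(self, x):
        s = nn.tmean(x, axis=(2, 3), keepdims=True)
        gate = nn.sigmoid(self.fc2(nn.relu(self.fc1(s))))
        return x * gate


class CBAM(nn.Module):
    """Channel gate (avg+max pooled shared MLP) then 7x7 spatial gate."""

    def __init__(self, channels: int, reduction: int = 16):
        super().__init__()
        if channels < reduction:
            raise ValueError(f"channels ({channels}) must be >= reduction ({reduction})")
        hidden = max(1, channels // reduction)
        self.fc1 = nn.Conv2d(channels, hidden, 1, bias=True)
        self.fc2 = nn.Conv2d(hidden, channels, 1, bias=True)
        self.spatial = nn.Conv2d(2, 1, 7, bias=True)

    def forward(self, x):
        avg = nn.tmean(x, axis=(2, 3), keepdims=True)
        mx = nn.tmax(nn.tmax(x, axis=3, keepdims=True), axis=2, keepdims=True)
        mlp = lambda t: self.fc2(nn.relu(self.fc1(t)))
        x = x * nn.sigmoid(mlp(avg) + mlp(mx))
        sp_avg = nn.tmean(x, axis=1, keepdims=True)
        sp_max = nn.tmax(x, axis=1, keepdims=True)
        gate = nn.sigmoid(self.spatial(nn.concat([sp_avg, sp_max], axis=1)))
        return x * gate


class NonLocalBlock(nn.Module):
    """Embedded-Gaussian non-local attention with a residual connection."""

    def __init__(self, channels: int, reduction: int = 2):
        super().__init__()
        inner = max(1, channels // reduction)
        self.inner = inner
        self.theta = nn.Conv2d(channels, inner, 1, bias=True)
        self.phi = nn.Conv2d(channels, inner, 1, bias=True)
        self.g = nn.Conv2d(channels, inner, 1, bias=True)
        self.out = nn.Conv2d(inner, channels, 1, bias=True)

    def forward(self, x):
        N, C, H, W = x.shape
        L = H * W
        th = nn.reshape(self.theta(x), (N, self.inner, L))
        ph = nn.reshape(self.phi(x), (N, self.inner, L))
        gv = nn.reshape(self.g(x), (N, self.inner, L))
        att = nn.softmax(nn.matmul(nn.transpose(th, (0, 2, 1)), ph), axis=-1)
        y = nn.matmul(gv, nn.transpose(att, (0, 2, 1)))  # N, inner, L
        y = nn.reshape(y, (N, self.inner, H, W))
        return x + self.out(y)


def attention_block(kind: str, channels: int, reduction: int = 16) -> nn.Module:
    """Factory for the FPN attention choices (``ca`` is channel attention in
    the squeeze-excitation sense, which is how this family of models uses
    the acronym)."""
    if kind in ("ca", "se"):
        return ChannelAttention(channels, reduction)
    if kind == "cbam":
        return CBAM(channels, reduction)
    if kind == "nonlocal":
        return NonLocalBlock(channels)
    raise ValueError(f"unknown attention kind {kind!r}")


class GhostModule(nn.Module):
    """Convolution factorized into a pointwise "intrinsic" convolution plus
    cheap depthwise 3x3 operations, concatenated to ``cout`` channels."""

    def __init__(self, cin: int, cout: int, ratio: int = 2):
        super().__init__()
        if ratio < 2:
            raise ValueError("ghost ratio must be >= 2")
        self.intrinsic = math.ceil(cout / ratio)
        self.cheap_ch = cout - self.intrinsic
        if self.cheap_ch % self.intrinsic:
            raise ValueError(
                f"cheap channels ({self.cheap_ch}) must be a multiple of the "
                f"intrinsic channels ({self.intrinsic})")
        self.primary = nn.ConvBN(cin, self.intrinsic, 1)
        self.cheap = nn.ConvBN(self.intrinsic, self.cheap_ch, 3,
                               groups=self.intrinsic)

    def forward(self, x):
        y = self.primary(x)
        return nn.concat([y, self.cheap(y)], axis=1)


class GSConv(nn.Module):
    """Half-dense / half-depthwise convolution with an interleaving shuffle.

    A dense convolution produces ``cout/2`` channels, a 5x5 depthwise
    convolution on those produces the other half, and a perfect-interleave
    channel shuffle mixes the two halves.
    """

    def __init__(self, cin: int, cout: int, k: int = 1, dw_k: int = 5):
        super().__init__()
        if cout % 2:
            raise ValueError(f"GSConv output channels must be even, got {cout}")
        self.half = cout // 2
        self.dense = nn.ConvBN(cin, self.half, k)
        self.dw = nn.ConvBN(self.half, self.half, dw_k, groups=self.half)

    def forward(self, x):
        a = self.dense(x)
        b = self.dw(a)
        y = nn.concat([a, b], axis=1)  # (N, 2*half, H, W)
        N, C, H, W = y.shape
        y = nn.reshape(y, (N, 2, self.half, H, W))
        y = nn.transpose(y, (0, 2, 1, 3, 4))
        return nn.reshape(y, (N, C, H, W))


class Bottleneck(nn.Module):
    def __init__(self, c: int, shortcut: bool = True):
        super().__init__()
        self.cv1 = nn.ConvBN(c, c, 3)
        self.cv2 = nn.ConvBN(c, c, 3)
        self.shortcut = shortcut

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.shortcut else y


class GCBottleneck(nn.Module):
    """Ghost module -> channel attention -> Ghost module (+ residual)."""

    def __init__(self, c: int, shortcut: bool = True, ratio: int = 2,
                 ca_reduction: int = 2):
        super().__init__()
        self.g1 = GhostModule(c, c, ratio)
        self.ca = ChannelAttention(c, ca_reduction)
        self.g2 = GhostModule(c, c, ratio)
        self.shortcut = shortcut

    def forward(self, x):
        y = self.g2(self.ca(self.g1(x)))
        return x + y if self.shortcut else y


class SCBottleneck(nn.Module):
    """GSConv -> channel attention -> GSConv (+ residual)."""

    def __init__(self, c: int, shortcut: bool = True, ca_reduction: int = 2):
        super().__init__()
        self.g1 = GSConv(c, c, k=3)
        self.ca = ChannelAttention(c, ca_reduction)
        self.g2 = GSConv(c, c, k=1)
        self.shortcut = shortcut

    def forward(self, x):
        y = self.g2(self.ca(self.g1(x)))
        return x + y if self.shortcut else y


def ghost_module(in_ch: int, out_ch: int, ratio: int = 2) -> GhostModule:
    return GhostModule(in_ch, out_ch, ratio)


def gs_conv(in_ch: int, out_ch: int, k: int = 1) -> GSConv:
    return GSConv(in_ch, out_ch, k)


class C2f(nn.Module):
    """Split-transform-concatenate stage with n internal bottlenecks whose
    intermediate outputs are all concatenated before a fusing convolution."""

    def __init__(self, c1: int, c2: int, n: int, shortcut: bool,
                 bottleneck: Callable[[int, bool], nn.Module]):
        super().__init__()
        self.c = c2 // 2
        self.cv1 = nn.ConvBN(c1, 2 * self.c, 1)
        self.cv2 = nn.ConvBN((2 + n) * self.c, c2, 1)
        self.blocks = nn.ModuleList([bottleneck(self.c, shortcut) for _ in range(n)])

    def forward(self, x):
        y = self.cv1(x)
        parts = [nn.narrow(y, 1, 0, self.c), nn.narrow(y, 1, self.c, self.c)]
        for blk in self.blocks:
            parts.append(blk(parts[-1]))
        return self.cv2(nn.concat(parts, axis=1))


def gc_c2f(c1: int, c2: int, n: int, shortcut: bool, ratio: int = 2,
           ca_reduction: int = 2) -> C2f:
    return C2f(c1, c2, n, shortcut,
               lambda c, s: GCBottleneck(c, s, ratio, ca_reduction))


def sc_c2f(c1: int, c2: int, n: int, shortcut: bool,
           ca_reduction: int = 2) -> C2f:
    return C2f(c1, c2, n, shortcut, lambda c, s: SCBottleneck(c, s, ca_reduction))


class SPPF(nn.Module):
    def __init__(self, c1: int, c2: int, k: int = 5):
        super().__init__()
        self.cv1 = nn.ConvBN(c1, c1 // 2, 1)
        self.cv2 = nn.ConvBN(c1 * 2, c2, 1)
        self.k = k

    def forward(self, x):
        y = self.cv1(x)
        p1 = nn.max_pool2d(y, self.k, 1, self.k // 2)
        p2 = nn.max_pool2d(p1, self.k, 1, self.k // 2)
        p3 = nn.max_pool2d(p2, self.k, 1, self.k // 2)
        return self.cv2(nn.concat([y, p1, p2, p3], axis=1))


class DetectHead(nn.Module):
    """Decoupled anchor-free head: distance-distribution box branch plus
    class branch, one pair per scale."""

    def __init__(self, nc: int, reg_max: int, channels: Sequence[int]):
        super().__init__()
        c2 = max(16, channels[0] // 4, reg_max * 4)
        c3 = max(channels[0], min(nc, 100))
        self.nc = nc
        self.reg_max = reg_max
        self.box_branches = nn.ModuleList([
            nn.Sequential(nn.ConvBN(ch, c2, 3), nn.ConvBN(c2, c2, 3),
                          nn.Conv2d(c2, 4 * reg_max, 1, bias=True))
            for ch in channels])
        self.cls_branches = nn.ModuleList([
            nn.Sequential(nn.ConvBN(ch, c3, 3), nn.ConvBN(c3, c3, 3),
                          nn.Conv2d(c3, nc, 1, bias=True))
            for ch in channels])

    def forward(self, feats):
        return [(self.box_branches[i](f), self.cls_branches[i](f))
                for i, f in enumerate(feats)]


# ---------------------------------------------------------------------------
# full detector
# ---------------------------------------------------------------------------

@dataclass
class DetectorOutput:
    """Raw per-scale maps plus the post-attention neck activations."""

    box_maps: list[Tensor]        # (N, 4*reg_max, h, w) per stride
    cls_maps: list[Tensor]        # (N, nc, h, w) per stride
    strides: tuple[int, ...]
    attention_maps: list[np.ndarray] = field(default_factory=list)


class Detector(nn.Module):
    STRIDES = (8, 16, 32)

    def __init__(self, config: ArchitectureConfig):
        super().__init__()
        self.config = config
        cw = self._widths(config)
        nb = self._repeats(config)
        bb = self._bottleneck_factory(config, backbone=True)
        nk = self._bottleneck_factory(config, backbone=False)

        c0, c1, c2, c3, c4 = cw  # 16, 32, 64, 128, 256 at width 0.25
        self.stem = nn.ConvBN(3, c0, 3, 2)
        self.down1 = nn.ConvBN(c0, c1, 3, 2)
        self.stage1 = C2f(c1, c1, nb[0], True, bb)
        self.down2 = nn.ConvBN(c1, c2, 3, 2)
        self.stage2 = C2f(c2, c2, nb[1], True, bb)
        self.down3 = nn.ConvBN(c2, c3, 3, 2)
        self.stage3 = C2f(c3, c3, nb[2], True, bb)
        self.down4 = nn.ConvBN(c3, c4, 3, 2)
        self.stage4 = C2f(c4, c4, nb[3], True, bb)
        self.sppf = SPPF(c4, c4)

        att = config.fpn_attention
        mk_att = (lambda ch: attention_block(att, ch, config.attention_reduction)) \
            if att != "none" else (lambda ch: None)
        # top-down
        self.att_td1 = mk_att(c4 + c3)
        self.neck_td1 = C2f(c4 + c3, c3, nb[4], False, nk)
        self.att_td2 = mk_att(c3 + c2)
        self.neck_td2 = C2f(c3 + c2, c2, nb[4], False, nk)
        # bottom-up
        self.down_n1 = nn.ConvBN(c2, c2, 3, 2)
        self.att_bu1 = mk_att(c2 + c3)
        self.neck_bu1 = C2f(c2 + c3, c3, nb[4], False, nk)
        self.down_n2 = nn.ConvBN(c3, c3, 3, 2)
        self.att_bu2 = mk_att(c3 + c4)
        self.neck_bu2 = C2f(c3 + c4, c4, nb[4], False, nk)

        self.head = DetectHead(config.nc, config.reg_max, (c2, c3, c4))
        self.initialize(seed=0)

    @staticmethod
    def _widths(cfg: ArchitectureConfig) -> tuple[int, ...]:
        base = (64, 128, 256, 512, 1024)
        return tuple(
            int(round(min(b, cfg.max_channels) * cfg.width_multiple))
            for b in base)

    @staticmethod
    def _repeats(cfg: ArchitectureConfig) -> tuple[int, ...]:
        base = (3, 6, 6, 3, 3)  # four backbone stages + neck blocks
        return tuple(max(1, round(b * cfg.depth_multiple)) for b in base)

    @staticmethod
    def _bottleneck_factory(cfg: ArchitectureConfig, backbone: bool):
        kind = {
            "baseline": ("std", "std"),
            "gnca": ("gc", "gc"),
            "snca": ("sc", "sc"),
            "gsca": ("gc", "sc"),
        }[cfg.variant][0 if backbone else 1]
        if kind == "std":
            return lambda c, s: Bottleneck(c, s)
        if kind == "gc":
            return lambda c, s: GCBottleneck(c, s, cfg.ghost_ratio,
                                             cfg.bottleneck_ca_reduction)
        return lambda c, s: SCBottleneck(c, s, cfg.bottleneck_ca_reduction)

    def forward(self, x: Tensor) -> DetectorOutput:
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError(
                f"input spatial dims must be divisible by 32, got {x.shape[2:]}")
        x = self.stem(x)
        x = self.stage1(self.down1(x))
        p3 = self.stage2(self.down2(x))
        p4 = self.stage3(self.down3(p3))
        p5 = self.sppf(self.stage4(self.down4(p4)))

        attention_maps: list[np.ndarray] = []

        def fuse(cat, att, c2f_blk):
            if att is not None:
                cat = att(cat)
                attention_maps.append(cat.data)
            return c2f_blk(cat)

        t1 = fuse(nn.concat([nn.upsample_nearest2x(p5), p4], axis=1),
                  self.att_td1, self.neck_td1)
        n3 = fuse(nn.concat([nn.upsample_nearest2x(t1), p3], axis=1),
                  self.att_td2, self.neck_td2)
        n4 = fuse(nn.concat([self.down_n1(n3), t1], axis=1),
                  self.att_bu1, self.neck_bu1)
        n5 = fuse(nn.concat([self.down_n2(n4), p5], axis=1),
                  self.att_bu2, self.neck_bu2)

        maps = self.head([n3, n4, n5])
        return DetectorOutput(box_maps=[m[0] for m in maps],
                              cls_maps=[m[1] for m in maps],
                              strides=self.STRIDES,
                              attention_maps=attention_maps)


def build_detector(config: Optional[ArchitectureConfig] = None,
                   seed: int = 0) -> Detector:
    """Assemble a detector variant with deterministic initial weights."""
    det = Detector(config or ArchitectureConfig())
    det.initialize(seed)
    return det


def count_parameters(detector: nn.Module) -> int:
    """Exact count of trainable scalar weights."""
    return detector.count_parameters()


def save_weights(detector: Detector, path) -> None:
    np.savez(path, **detector.state_dict())


def load_weights(detector: Detector, path) -> None:
    with np.load(path) as data:
        detector.load_state_dict({k: data[k] for k in data.files})


# ---------------------------------------------------------------------------
# letterboxing
# ---------------------------------------------------------------------------

GRAY_FILL = 114


@dataclass(frozen=True)
class LetterboxTransform:
    scale: float
    pad_x: float
    pad_y: float
    src_size: tuple[int, int]   # (W, H)
    target: int

    def source_to_canvas(self, xyxy: np.ndarray) -> np.ndarray:
        out = np.asarray(xyxy, dtype=float).copy()
        out[..., [0, 2]] = out[..., [0, 2]] * self.scale + self.pad_x
        out[..., [1, 3]] = out[..., [1, 3]] * self.scale + self.pad_y
        return out

    def canvas_to_source(self, xyxy: np.ndarray) -> np.ndarray:
        out = np.asarray(xyxy, dtype=float).copy()
        out[..., [0, 2]] = (out[..., [0, 2]] - self.pad_x) / self.scale
        out[..., [1, 3]] = (out[..., [1, 3]] - self.pad_y) / self.scale
        return out


def letterbox(image: np.ndarray, target: int = 640
              ) -> tuple[np.ndarray, LetterboxTransform]:
    """Aspect-preserving resize onto a gray target x target canvas."""
    img = np.asarray(image)
    H, W = img.shape[:2]
    scale = min(target / W, target / H)
    new_w, new_h = int(round(W * scale)), int(round(H * scale))
    if (new_w, new_h) != (W, H):
        resized = np.asarray(Image.fromarray(img).resize((new_w, new_h),
                                                         Image.BILINEAR))
    else:
        resized = img
    canvas = np.full((target, target, 3), GRAY_FILL, dtype=np.uint8)
    px = (target - new_w) // 2
    py = (target - new_h) // 2
    canvas[py:py + new_h, px:px + new_w] = resized
    return canvas, LetterboxTransform(scale=scale, pad_x=px, pad_y=py,
                                      src_size=(W, H), target=target)


# ---------------------------------------------------------------------------
# decoding and non-maximum suppression
# ---------------------------------------------------------------------------

def _decode_output(output: DetectorOutput, reg_max: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Raw maps -> (M, 4) canvas xyxy boxes and (M, nc) class probabilities.

    Box decode is the expected-bin-value convention: softmax over the
    ``reg_max`` bins of each side gives a distribution over distances (in
    stride units) from the anchor center.
    """
    all_boxes, all_scores = [], []
    bins = np.arange(reg_max, dtype=np.float64)
    for (bmap, cmap), s in zip(zip(output.box_maps, output.cls_maps),
                               output.strides):
        b = bmap.data if isinstance(bmap, Tensor) else bmap
        c = cmap.data if isinstance(cmap, Tensor) else cmap
        N, _, h, w = b.shape
        assert N == 1, "decode expects a single image"
        d = b.reshape(4, reg_max, h, w)
        z = d - d.max(axis=1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=1, keepdims=True)
        dist = (p * bins[None, :, None, None]).sum(axis=1) * s  # l,t,r,b px
        cx = (np.arange(w) + 0.5) * s
        cy = (np.arange(h) + 0.5) * s
        CX, CY = np.meshgrid(cx, cy)
        boxes = np.stack([CX - dist[0], CY - dist[1],
                          CX + dist[2], CY + dist[3]], axis=-1)
        scores = 1.0 / (1.0 + np.exp(-c[0]))  # nc, h, w
        all_boxes.append(boxes.reshape(-1, 4))
        all_scores.append(scores.reshape(scores.shape[0], -1).T)
    return np.concatenate(all_boxes), np.concatenate(all_scores)


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (N,4) and (M,4) xyxy arrays."""
    a = np.asarray(a, dtype=float).reshape(-1, 4)
    b = np.asarray(b, dtype=float).reshape(-1, 4)
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(br - tl, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = np.prod(a[:, 2:] - a[:, :2], axis=1)
    area_b = np.prod(b[:, 2:] - b[:, :2], axis=1)
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float
        ) -> np.ndarray:
    """Greedy NMS by descending score (ties broken by lower index).

    Returns the indices of the surviving boxes.
    """
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 4)
    scores = np.asarray(scores, dtype=float)
    # stable sort on negative scores keeps lower index first among ties
    order = np.argsort(-scores, kind="stable")
    keep = []
    suppressed = np.zeros(len(boxes), dtype=bool)
    for i in order:
        if suppressed[i]:
            continue
        keep.append(i)
        ious = iou_matrix(boxes[i:i + 1], boxes)[0]
        suppressed |= ious > iou_threshold
        suppressed[i] = True
    return np.array(keep, dtype=int)


def predict(detector: Detector, image: np.ndarray,
            protocol: EvalProtocol = EvalProtocol(),
            target: int = 640) -> list[Box]:
    """Letterbox -> forward -> decode -> confidence filter -> class-wise NMS
    -> boxes mapped back to source coordinates."""
    detector.eval()
    canvas, tf = letterbox(image, target)
    x = Tensor(canvas.astype(np.float32).transpose(2, 0, 1)[None] / 255.0)
    with nn.no_grad():
        out = detector(x)
    boxes, scores = _decode_output(out, detector.config.reg_max)
    conf = scores.max(axis=1)
    cls = scores.argmax(axis=1)
    keep = conf > protocol.conf_threshold
    boxes, conf, cls = boxes[keep], conf[keep], cls[keep]
    results: list[Box] = []
    W, H = tf.src_size
    for k in np.unique(cls):
        sel = cls == k
        b, s = boxes[sel], conf[sel]
        for i in nms(b, s, protocol.nms_iou):
            src = tf.canvas_to_source(b[i])
            x1, y1 = max(0.0, src[0]), max(0.0, src[1])
            x2, y2 = min(float(W), src[2]), min(float(H), src[3])
            if x2 - x1 >= 1e-3 and y2 - y1 >= 1e-3:
                results.append(Box(x1, y1, x2, y2, CLASSES[int(k)],
                                   conf=float(np.clip(s[i], 0, 1))))
    return results


def attention_heatmap(detector: Detector, image: np.ndarray,
                      neck_level: int, target: int = 640) -> np.ndarray:
    """Channel-mean of the post-attention neck activation, upsampled to the
    source image size and min-max normalized to [0, 1]."""
    if detector.config.fpn_attention == "none":
        raise ValueError("detector was built without FPN attention")
    detector.eval()
    canvas, tf = letterbox(image, target)
    x = Tensor(canvas.astype(np.float32).transpose(2, 0, 1)[None] / 255.0)
    with nn.no_grad():
        out = detector(x)
    if not (0 <= neck_level < len(out.attention_maps)):
        raise ValueError(
            f"neck_level must be in [0, {len(out.attention_maps)}), got {neck_level}")
    amap = out.attention_maps[neck_level][0].mean(axis=0)  # h, w
    from skimage.transform import resize as sk_resize
    up = sk_resize(amap, (target, target), order=1, anti_aliasing=False)
    # crop away the letterbox padding, then fit the source size
    W, H = tf.src_size
    cw, ch = int(round(W * tf.scale)), int(round(H * tf.scale))
    px, py = int(tf.pad_x), int(tf.pad_y)
    up = up[py:py + ch, px:px + cw]
    up = sk_resize(up, (H, W), order=1, anti_aliasing=False)
    lo, hi = float(up.min()), float(up.max())
    if hi - lo < 1e-12:
        return np.zeros((H, W))
    return (up - lo) / (hi - lo)
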
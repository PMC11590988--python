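"""Data-augmentation operators with exact label bookkeeping.

Vertical stitching is the centerpiece: two same-width frames are stacked so
every label survives intact (no cropping, no rescaling), and the composite's
aspect ratio moves closer to the square network input, shrinking the gray
letterbox padding.  Mosaic is the comparator whose random crop/scale can cut
subjects and drop labels; Mixup blends pixel content while uniting the label
sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .model_zoo import letterbox  # noqa: F401  (gray_fill_fraction shares its geometry)
from .types import AnnotatedImage, Box


@dataclass(frozen=True)
class MosaicParams:
    out_size: tuple[int, int] = (1280, 720)   # (W, H)
    scale_range: tuple[float, float] = (0.5, 1.5)
    min_box_area_frac: float = 0.25
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.scale_range
        if not (0 < lo <= hi <= 2):
            raise ValueError("scale_range must satisfy 0 < lo <= hi <= 2")
        if not (0 <= self.min_box_area_frac < 1) and self.min_box_area_frac != 1.0:
            raise ValueError("min_box_area_frac must lie in [0, 1]")
        if self.out_size[0] <= 0 or self.out_size[1] <= 0:
            raise ValueError("out_size dims must be positive")


@dataclass(frozen=True)
class MixupParams:
    lam: float = 0.5

    def __post_init__(self):
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("mixing weight must be in [0, 1]")


def vertical_stitch(top: AnnotatedImage, bottom: AnnotatedImage) -> AnnotatedImage:
    """Stack two same-width frames; bottom boxes shift down by ``top.H``.

    No box is cropped, dropped or resized: the output carries exactly
    ``len(top.boxes) + len(bottom.boxes)`` labels.
    """
    if top.width != bottom.width:
        raise ValueError(
            f"vertical stitch requires equal widths, got {top.width} and "
            f"{bottom.width} (no implicit resizing)")
    pixels = np.concatenate([top.pixels, bottom.pixels], axis=0)
    boxes = list(top.boxes) + [b.shifted(0, top.height) for b in bottom.boxes]
    return AnnotatedImage(pixels=pixels, boxes=boxes,
                          source_id=f"{top.source_id}+{bottom.source_id}")


def horizontal_stitch(left: AnnotatedImage, right: AnnotatedImage) -> AnnotatedImage:
    """Symmetric counterpart of :func:`vertical_stitch` along the x axis."""
    if left.height != right.height:
        raise ValueError(
            f"horizontal stitch requires equal heights, got {left.height} "
            f"and {right.height} (no implicit resizing)")
    pixels = np.concatenate([left.pixels, right.pixels], axis=1)
    boxes = list(left.boxes) + [b.shifted(left.width, 0) for b in right.boxes]
    return AnnotatedImage(pixels=pixels, boxes=boxes,
                          source_id=f"{left.source_id}+{right.source_id}")


@dataclass(frozen=True)
class MosaicGeometry:
    """The sampled transform of one mosaic tile (for audit/oracle checks)."""

    quad: tuple[int, int, int, int]   # quadrant rect on the canvas
    scale: float
    offset: tuple[int, int]           # top-left of the scaled image on canvas
    scaled_size: tuple[int, int]      # (sw, sh)


def mosaic(four_images: list[AnnotatedImage], params: MosaicParams,
           return_geometry: bool = False):
    """2x2 composite with a seeded random center split.

    Each input is randomly scaled within ``scale_range`` and anchored at the
    center point of its quadrant (top-left image by its bottom-right corner,
    and so on), then cropped to the quadrant.  A transformed box is kept only
    if its clipped area is at least ``min_box_area_frac`` of its (scaled)
    full area — the mechanism by which mosaic can lose labels when it cuts
    through subjects.
    """
    if len(four_images) != 4:
        raise ValueError(f"mosaic requires exactly 4 images, got {len(four_images)}")
    W, H = params.out_size
    rng = np.random.default_rng(params.seed)
    cx = int(round(rng.uniform(0.25, 0.75) * W))
    cy = int(round(rng.uniform(0.25, 0.75) * H))
    # quadrant rectangles and the anchor corner of each tile
    quads = [
        ((0, 0, cx, cy), (cx, cy)),      # top-left image, anchored bottom-right
        ((cx, 0, W, cy), (cx, cy)),      # top-right, anchored bottom-left
        ((0, cy, cx, H), (cx, cy)),      # bottom-left, anchored top-right
        ((cx, cy, W, H), (cx, cy)),      # bottom-right, anchored top-left
    ]
    canvas = np.full((H, W, 3), 114, dtype=np.uint8)
    out_boxes: list[Box] = []
    geometry: list[MosaicGeometry] = []
    for k, (img, ((qx1, qy1, qx2, qy2), (ax, ay))) in enumerate(zip(four_images, quads)):
        s = float(rng.uniform(*params.scale_range))
        sw = max(1, int(round(img.width * s)))
        sh = max(1, int(round(img.height * s)))
        sx, sy = sw / img.width, sh / img.height
        resized = np.asarray(Image.fromarray(img.pixels).resize((sw, sh),
                                                                Image.BILINEAR))
        # top-left placement of the scaled image on the canvas
        x0 = ax - sw if k in (0, 2) else ax
        y0 = ay - sh if k in (0, 1) else ay
        geometry.append(MosaicGeometry(quad=(qx1, qy1, qx2, qy2), scale=s,
                                       offset=(x0, y0), scaled_size=(sw, sh)))
        vx1, vy1 = max(x0, qx1), max(y0, qy1)
        vx2, vy2 = min(x0 + sw, qx2), min(y0 + sh, qy2)
        if vx2 > vx1 and vy2 > vy1:
            canvas[vy1:vy2, vx1:vx2] = resized[vy1 - y0:vy2 - y0, vx1 - x0:vx2 - x0]
        for b in img.boxes:
            # raw transformed corners may fall outside the canvas; clip first
            tx1, ty1 = b.x1 * sx + x0, b.y1 * sy + y0
            tx2, ty2 = b.x2 * sx + x0, b.y2 * sy + y0
            full_area = (tx2 - tx1) * (ty2 - ty1)
            cx1, cy1 = max(tx1, qx1), max(ty1, qy1)
            cx2, cy2 = min(tx2, qx2), min(ty2, qy2)
            clipped = max(0.0, cx2 - cx1) * max(0.0, cy2 - cy1)
            if clipped >= params.min_box_area_frac * full_area and clipped > 0:
                out_boxes.append(Box(cx1, cy1, cx2, cy2, b.cls, b.conf))
    out = AnnotatedImage(pixels=canvas, boxes=out_boxes,
                         source_id=f"mosaic-seed{params.seed}")
    return (out, geometry) if return_geometry else out


def mixup(a: AnnotatedImage, b: AnnotatedImage, params: MixupParams
          ) -> AnnotatedImage:
    """Pixel blend ``lam * a + (1 - lam) * b``; labels are the exact union."""
    if a.size != b.size:
        raise ValueError(f"mixup requires equal sizes, got {a.size} and {b.size}")
    px = np.clip(np.rint(params.lam * a.pixels.astype(np.float64)
                         + (1.0 - params.lam) * b.pixels.astype(np.float64)),
                 0, 255).astype(np.uint8)
    return AnnotatedImage(pixels=px, boxes=list(a.boxes) + list(b.boxes),
                          source_id=f"mixup({a.source_id},{b.source_id})")


def gray_fill_fraction(image_size: tuple[int, int], target: int = 640) -> float:
    """Fraction of the letterboxed square canvas occupied by gray padding.

    Shares the letterbox geometry of the detector preprocessing: the image
    is fitted aspect-preservingly into ``target x target``, so e.g. a
    1280x720 frame leaves 1 - 360/640 = 0.4375 of the canvas as padding
    while the 1280x1440 vertical composite leaves less.
    """
    w, h = image_size
    if w <= 0 or h <= 0:
        raise ValueError("image dims must be positive")
    scale = min(target / w, target / h)
    new_w, new_h = round(w * scale), round(h * scale)
    return 1.0 - (new_w * new_h) / float(target * target)
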
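"""Seeded synthetic top-down pen scenes with goat-like blobs in four behavior poses.

The generator emulates the geometry of overhead pen footage: a textured
ground, a feed-trough strip along the top edge, a water point in the
bottom-right corner, and per-goat oriented ellipse clusters whose pose
encodes the behavior class:

* ``lying``  — low-aspect blob (goat folded on the ground);
* ``stand``  — elongated blob plus a small head and a cast shadow;
* ``eat``    — standing pose with the head overlapping the trough strip;
* ``drink``  — standing pose with the head overlapping the water point.

Scale is fixed at 60 px per metre, so the stocking-density regimes
(2 m² per goat for high density, 3 m² for low) translate directly into a
minimum center spacing.  Rendering is flat-shaded and fully determined by
the seed; the acceptance surface of the package is geometry and counting,
not photorealism.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage.draw import disk, ellipse

from .types import CLASSES, AnnotatedImage, BehaviorRecord, Box

PX_PER_M = 60.0
#: free area per goat (m^2) for the two stocking-density regimes
DENSITY_M2 = {"high": 2.0, "low": 3.0}

#: empirical class mix of the annotated farm data set
#: (4415 lying, 2869 standing, 112 drinking, 1022 eating of 8418 labels)
DEFAULT_CLASS_MIX = (4415 / 8418, 2869 / 8418, 112 / 8418, 1022 / 8418)

#: default wall-clock start of a generated monitoring session
DEFAULT_START = _dt.datetime(2023, 10, 8, 9, 15, 3)


class PlacementError(RuntimeError):
    """Raised when goats cannot be placed at the requested density."""


@dataclass
class PenSceneConfig:
    image_size: tuple[int, int] = (1280, 720)  # (W, H)
    n_goats: int = 12
    density: str = "low"
    lighting: str = "day"
    class_mix: tuple[float, float, float, float] = DEFAULT_CLASS_MIX
    occlusion_level: float = 0.3
    seed: int = 0
    amodal_boxes: bool = True  # box full extents even when partially hidden

    def __post_init__(self):
        if self.n_goats < 0:
            raise ValueError("n_goats must be >= 0")
        if self.density not in DENSITY_M2:
            raise ValueError(f"density must be one of {sorted(DENSITY_M2)}")
        if self.lighting not in ("day", "night"):
            raise ValueError("lighting must be 'day' or 'night'")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError(f"class_mix must sum to 1, got {self.class_mix}")
        if not (0.0 <= self.occlusion_level <= 1.0):
            raise ValueError("occlusion_level must be in [0, 1]")
        w, h = self.image_size
        if w < 96 or h < 96:
            raise ValueError("image_size must be at least 96x96 to fit goats")


# body semi-axes (along, across) in pixels at 60 px/m, per pose
_BODY = {
    "lying": (30.0, 22.0),
    "stand": (36.0, 14.0),
    "eat": (34.0, 14.0),
    "drink": (34.0, 14.0),
}
_HEAD_R = 8.0


@dataclass
class _Goat:
    cls: str
    cx: float
    cy: float
    theta: float  # body orientation, radians
    shade: float  # base gray level of the coat


def _zone_center(rng: np.random.Generator, cls: str, W: int, H: int,
                 trough_h: int, water_c: tuple[float, float], water_r: float
                 ) -> tuple[float, float, float]:
    """Draw a candidate (cx, cy, theta) respecting the pose's pen zone."""
    a, b = _BODY[cls]
    margin = a + _HEAD_R + 2
    if cls == "eat":
        # body below the trough, head reaching into it: vertical orientation
        cx = rng.uniform(margin, W - margin)
        cy = trough_h + b + rng.uniform(0, 6)
        theta = -math.pi / 2 + rng.normal(0, 0.08)
    elif cls == "drink":
        # around the water point, nose toward it
        ang = rng.uniform(math.pi * 1.05, math.pi * 1.45)  # up/left of corner
        dist = water_r + a * 0.7 + rng.uniform(0, a)
        cx = float(np.clip(water_c[0] + dist * math.cos(ang), margin, W - margin))
        cy = float(np.clip(water_c[1] + dist * math.sin(ang), trough_h + margin, H - margin))
        theta = math.atan2(water_c[1] - cy, water_c[0] - cx)
    else:
        cx = rng.uniform(margin, W - margin)
        cy = rng.uniform(trough_h + margin, H - margin)
        theta = rng.uniform(0, 2 * math.pi)
    return cx, cy, theta


def _goat_parts(g: _Goat) -> list[tuple[str, tuple]]:
    """Geometric primitives making up one goat: (kind, params)."""
    a, b = _BODY[g.cls]
    parts = [("ellipse", (g.cy, g.cx, b, a, g.theta))]
    if g.cls != "lying":
        hx = g.cx + (a + _HEAD_R * 0.6) * math.cos(g.theta)
        hy = g.cy + (a + _HEAD_R * 0.6) * math.sin(g.theta)
        parts.append(("disk", (hy, hx, _HEAD_R)))
    return parts


def _paint_goat(canvas: np.ndarray, owner: np.ndarray, g: _Goat, gid: int,
                rng: np.random.Generator) -> Box:
    """Draw one goat (with occlusion by draw order) and return its amodal box."""
    H, W = canvas.shape[:2]
    xs_all, ys_all = [], []
    if g.cls == "stand":  # cast shadow, not part of the box
        a, b = _BODY[g.cls]
        rr, cc = ellipse(g.cy + 5, g.cx + 5, b * 1.05, a * 1.05,
                         rotation=-g.theta, shape=(H, W))
        canvas[rr, cc] = (canvas[rr, cc] * 0.7).astype(np.uint8)
    for kind, p in _goat_parts(g):
        if kind == "ellipse":
            cy, cx, rb, ra, th = p
            rr, cc = ellipse(cy, cx, rb, ra, rotation=-th, shape=(H, W))
        else:
            cy, cx, r = p
            rr, cc = disk((cy, cx), r, shape=(H, W))
        coat = np.clip(g.shade + rng.normal(0, 6, size=rr.shape), 0, 255)
        canvas[rr, cc] = np.stack([coat, coat * 0.98, coat * 0.94], axis=-1).astype(np.uint8)
        owner[rr, cc] = gid
        # full (amodal) extent, regardless of clipping by the frame is not
        # possible: placement keeps goats inside, so drawn extent == extent
        xs_all.append(cc)
        ys_all.append(rr)
    xs = np.concatenate(xs_all)
    ys = np.concatenate(ys_all)
    return Box(float(xs.min()), float(ys.min()),
               float(xs.max() + 1), float(ys.max() + 1), g.cls)


def _background(W: int, H: int, rng: np.random.Generator
                ) -> tuple[np.ndarray, int, tuple[float, float], float]:
    canvas = np.empty((H, W, 3), dtype=np.uint8)
    base = 150 + 18 * np.sin(np.linspace(0, 3.1, W))[None, :] \
        + rng.normal(0, 7, size=(H, W))
    canvas[:, :, 0] = np.clip(base * 0.86, 0, 255)
    canvas[:, :, 1] = np.clip(base * 0.78, 0, 255)
    canvas[:, :, 2] = np.clip(base * 0.66, 0, 255)
    trough_h = max(24, H // 12)
    trough = 95 + rng.normal(0, 5, size=(trough_h, W))
    canvas[:trough_h, :, 0] = np.clip(trough * 0.9, 0, 255)
    canvas[:trough_h, :, 1] = np.clip(trough * 0.8, 0, 255)
    canvas[:trough_h, :, 2] = np.clip(trough * 0.65, 0, 255)
    water_r = max(18.0, min(W, H) / 14)
    water_c = (W - water_r * 0.9, H - water_r * 0.9)
    rr, cc = disk((water_c[1], water_c[0]), water_r, shape=(H, W))
    canvas[rr, cc] = (70, 110, 160)
    return canvas, trough_h, water_c, water_r


def _place_goats(cfg: PenSceneConfig, rng: np.random.Generator,
                 trough_h: int, water_c, water_r) -> list[_Goat]:
    W, H = cfg.image_size
    spacing = (1.0 - cfg.occlusion_level) * math.sqrt(
        DENSITY_M2[cfg.density]) * PX_PER_M
    classes = rng.choice(len(CLASSES), size=cfg.n_goats, p=np.asarray(cfg.class_mix))
    goats: list[_Goat] = []
    for k in classes:
        cls = CLASSES[int(k)]
        placed = False
        for attempt in range(300):
            # concede half the nominal spacing if the zone is congested
            need = spacing if attempt < 150 else spacing * 0.5
            cx, cy, theta = _zone_center(rng, cls, W, H, trough_h, water_c, water_r)
            if all(math.hypot(cx - g.cx, cy - g.cy) >= need for g in goats):
                goats.append(_Goat(cls, cx, cy, theta,
                                   shade=float(rng.uniform(185, 235))))
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place {cfg.n_goats} goats at density "
                f"'{cfg.density}' (occlusion_level={cfg.occlusion_level}) "
                f"in a {W}x{H} frame after 300 retries"
            )
    return goats


def _render(cfg: PenSceneConfig, goats: list[_Goat], seed_offset: int = 0
            ) -> AnnotatedImage:
    W, H = cfg.image_size
    rng = np.random.default_rng((cfg.seed * 1_000_003 + seed_offset) % (2**31))
    canvas, _, _, _ = _background(W, H, rng)
    owner = np.full((H, W), -1, dtype=np.int32)
    boxes = [_paint_goat(canvas, owner, g, i, rng) for i, g in enumerate(goats)]
    if not cfg.amodal_boxes:
        boxes = _visible_boxes(owner, goats, boxes)
    if cfg.lighting == "night":
        canvas = degrade_night(canvas, gamma=2.2, noise_sigma=3.0,
                               seed=(cfg.seed * 7 + seed_offset + 1) % (2**31))
    return AnnotatedImage(pixels=canvas, boxes=boxes,
                          source_id=f"pen-seed{cfg.seed}-{seed_offset}")


def _visible_boxes(owner: np.ndarray, goats: list[_Goat],
                   amodal: list[Box]) -> list[Box]:
    out = []
    for i, (g, b) in enumerate(zip(goats, amodal)):
        ys, xs = np.nonzero(owner == i)
        if len(xs) == 0:  # fully occluded: keep the amodal extent
            out.append(b)
        else:
            out.append(Box(float(xs.min()), float(ys.min()),
                           float(xs.max() + 1), float(ys.max() + 1), g.cls))
    return out


def generate_pen_image(config: PenSceneConfig) -> AnnotatedImage:
    """Render one annotated pen scene; the seed fully determines the output."""
    rng = np.random.default_rng(config.seed)
    W, H = config.image_size
    _, trough_h, water_c, water_r = _background(W, H, np.random.default_rng(0))
    goats = _place_goats(config, rng, trough_h, water_c, water_r)
    return _render(config, goats)


def degrade_night(image: np.ndarray, gamma: float = 2.2,
                  noise_sigma: float = 3.0, seed: int = 0) -> np.ndarray:
    """Emulate low-light capture: gamma compression plus sensor noise.

    ``gamma > 1`` darkens and compresses the histogram (so discrete entropy
    cannot increase when ``noise_sigma == 0``); Gaussian noise emulates the
    high-ISO grain of night footage.
    """
    if gamma < 1:
        raise ValueError("gamma must be >= 1 (darkening)")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    x = np.asarray(image, dtype=np.float64) / 255.0
    out = 255.0 * np.power(x, gamma)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0, noise_sigma, size=out.shape)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


@dataclass
class SyntheticVideo:
    """A coherent frame sequence with per-frame truth and per-second records."""

    frames: list[np.ndarray]
    boxes_per_frame: list[list[Box]]
    records: list[BehaviorRecord]
    fps: int
    start: _dt.datetime = DEFAULT_START


def generate_video(config: PenSceneConfig, n_seconds: int, fps: int = 1,
                   motion: float = 0.1,
                   start: Optional[_dt.datetime] = None) -> SyntheticVideo:
    """Simulate ``n_seconds`` of pen activity.

    ``motion`` is the per-second probability that a goat switches behavior
    (resampling its class from the configured mix and re-placing it in the
    matching pen zone).  Per-frame class counts always sum to ``n_goats``.
    """
    if fps < 1:
        raise ValueError("fps must be >= 1")
    if not (0.0 <= motion <= 1.0):
        raise ValueError("motion must be a probability in [0, 1]")
    start = start or DEFAULT_START
    rng = np.random.default_rng(config.seed)
    W, H = config.image_size
    _, trough_h, water_c, water_r = _background(W, H, np.random.default_rng(0))
    goats = _place_goats(config, rng, trough_h, water_c, water_r)
    spacing = (1.0 - config.occlusion_level) * math.sqrt(
        DENSITY_M2[config.density]) * PX_PER_M

    frames: list[np.ndarray] = []
    boxes_per_frame: list[list[Box]] = []
    records: list[BehaviorRecord] = []
    for s in range(n_seconds):
        if s > 0 and motion > 0:
            for i, g in enumerate(goats):
                if rng.random() < motion:
                    new_cls = CLASSES[int(rng.choice(len(CLASSES),
                                                     p=np.asarray(config.class_mix)))]
                    others = goats[:i] + goats[i + 1:]
                    for _ in range(200):
                        cx, cy, th = _zone_center(rng, new_cls, W, H,
                                                  trough_h, water_c, water_r)
                        if all(math.hypot(cx - o.cx, cy - o.cy) >= spacing
                               for o in others):
                            goats[i] = _Goat(new_cls, cx, cy, th, g.shade)
                            break
                    # on persistent placement failure the goat keeps its pose
        scene = _render(config, goats, seed_offset=s + 1)
        for _ in range(fps):
            frames.append(scene.pixels)
            boxes_per_frame.append(list(scene.boxes))
        t = start + _dt.timedelta(seconds=s)
        counts: dict[str, int] = {c: 0 for c in CLASSES}
        for g in goats:
            counts[g.cls] += 1
        records.append(BehaviorRecord.from_class_counts(t.date(), t.time(), counts))
    return SyntheticVideo(frames=frames, boxes_per_frame=boxes_per_frame,
                          records=records, fps=fps, start=start)
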
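"""Core domain types shared across the package.

The unit of annotation, prediction and loss computation is an axis-aligned
bounding box labelled with one of the four housed-goat ethogram classes
{lying, stand, drink, eat}.  Coordinates are stored as 0-based, half-open
pixel intervals [x1, x2) x [y1, y2) in floating point, which keeps pixel-area
arithmetic unambiguous; on-disk formats apply their own conventions at the
I/O boundary.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

#: Closed behavior vocabulary, in canonical order (also the class-index order
#: used by YOLO-format labels and the detection head).
CLASSES: tuple[str, ...] = ("lying", "stand", "drink", "eat")

CLASS_TO_INDEX = {c: i for i, c in enumerate(CLASSES)}

# The literature and annotation tools mix spellings ("lying down",
# "standing", "feeding"); normalize them onto the canonical four.
_ALIASES = {
    "lying": "lying",
    "lying down": "lying",
    "lying_down": "lying",
    "lyingdown": "lying",
    "lie": "lying",
    "stand": "stand",
    "standing": "stand",
    "drink": "drink",
    "drinking": "drink",
    "eat": "eat",
    "eating": "eat",
    "feed": "eat",
    "feeding": "eat",
}


class VocabularyError(ValueError):
    """Raised when a class name is outside the four-class vocabulary."""


def normalize_class(name: str) -> str:
    """Map a free-form behavior label onto the canonical vocabulary."""
    key = name.strip().lower()
    if key in _ALIASES:
        return _ALIASES[key]
    raise VocabularyError(
        f"unknown behavior class {name!r}; allowed classes (and aliases of) {CLASSES}"
    )


@dataclass(frozen=True)
class Box:
    """Axis-aligned box with behavior class and optional confidence."""

    x1: float
    y1: float
    x2: float
    y2: float
    cls: str
    conf: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "cls", normalize_class(self.cls))
        for v in (self.x1, self.y1, self.x2, self.y2):
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"box coordinates must be finite and >= 0, got {self}")
        if not (self.x1 < self.x2 and self.y1 < self.y2):
            raise ValueError(f"box must satisfy x1 < x2 and y1 < y2, got {self}")
        if self.conf is not None and not (0.0 <= self.conf <= 1.0):
            raise ValueError(f"confidence must be in [0, 1], got {self.conf}")

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def cls_index(self) -> int:
        return CLASS_TO_INDEX[self.cls]

    def shifted(self, dx: float, dy: float) -> "Box":
        return replace(self, x1=self.x1 + dx, y1=self.y1 + dy, x2=self.x2 + dx, y2=self.y2 + dy)

    def scaled(self, sx: float, sy: float) -> "Box":
        return replace(self, x1=self.x1 * sx, y1=self.y1 * sy, x2=self.x2 * sx, y2=self.y2 * sy)

    def xyxy(self) -> np.ndarray:
        return np.array([self.x1, self.y1, self.x2, self.y2], dtype=float)


@dataclass
class AnnotatedImage:
    """An RGB raster plus its box list and provenance."""

    pixels: np.ndarray  # H x W x 3, uint8
    boxes: list[Box] = field(default_factory=list)
    source_id: str = ""
    timestamp: Optional[float] = None

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be H x W x 3, got shape {px.shape}")
        if px.shape[0] <= 0 or px.shape[1] <= 0:
            raise ValueError("image dimensions must be positive")
        if px.dtype != np.uint8:
            raise ValueError(f"pixels must be uint8, got {px.dtype}")
        self.pixels = px
        self.validate_boxes()

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def size(self) -> tuple[int, int]:
        """(width, height) in pixels."""
        return (self.width, self.height)

    def validate_boxes(self) -> None:
        for b in self.boxes:
            if b.x2 > self.width or b.y2 > self.height:
                raise ValueError(
                    f"box {b} exceeds image bounds {self.width}x{self.height}"
                )


@dataclass(frozen=True)
class BehaviorRecord:
    """One per-second row of behavior counts (the monitoring record schema)."""

    date: _dt.date
    time: _dt.time
    standing: int
    drinking: int
    lying_down: int
    feeding: int

    def __post_init__(self):
        for name in ("standing", "drinking", "lying_down", "feeding"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} count must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.standing + self.drinking + self.lying_down + self.feeding

    def counts(self) -> dict[str, int]:
        return {
            "standing": self.standing,
            "drinking": self.drinking,
            "lying_down": self.lying_down,
            "feeding": self.feeding,
        }

    @staticmethod
    def from_class_counts(
        date: _dt.date, time: _dt.time, counts: dict[str, int]
    ) -> "BehaviorRecord":
        """Build a record from canonical-class counts {lying, stand, drink, eat}."""
        return BehaviorRecord(
            date=date,
            time=time,
            standing=int(counts.get("stand", 0)),
            drinking=int(counts.get("drink", 0)),
            lying_down=int(counts.get("lying", 0)),
            feeding=int(counts.get("eat", 0)),
        )


def boxes_as_array(boxes: Sequence[Box]) -> np.ndarray:
    """Stack boxes into an (N, 4) float array of xyxy corners."""
    if len(boxes) == 0:
        return np.zeros((0, 4), dtype=float)
    return np.stack([b.xyxy() for b in boxes])
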
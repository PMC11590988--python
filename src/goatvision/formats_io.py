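"""On-disk formats: Pascal VOC XML, YOLO txt labels, record CSV, frame streams.

Coordinate conventions
----------------------
Internally boxes are 0-based half-open float intervals.  VOC XML is written
with the customary 1-based inclusive integer corners (``xmin = round(x1)+1``,
``xmax = round(x2)``) and read back with the inverse mapping, so a write/read
round-trip moves each coordinate by at most 0.5 px.  YOLO lines are
``class_index cx cy w h`` normalized to [0, 1].
"""

from __future__ import annotations

import datetime as _dt
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
from lxml import etree

from .types import CLASSES, AnnotatedImage, BehaviorRecord, Box, normalize_class

PathLike = Union[str, os.PathLike]

RECORD_COLUMNS = ["Date", "Time", "Standing", "Drinking", "LyingDown", "Feeding"]

IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff")


class VocParseError(ValueError):
    """Malformed VOC XML."""


@dataclass
class VocAnnotation:
    """Image-free VOC metadata: raster size plus boxes."""

    width: int
    height: int
    boxes: list[Box]
    filename: str = ""


# ---------------------------------------------------------------------------
# Pascal VOC XML
# ---------------------------------------------------------------------------

def read_voc_xml(path: PathLike) -> VocAnnotation:
    """Parse a Pascal VOC annotation file.

    Raises :class:`VocParseError` naming the file on malformed XML and
    :class:`~goatvision.types.VocabularyError` on class names outside the
    four-behavior vocabulary.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise VocParseError(f"cannot parse VOC XML {path}: {exc}") from exc
    root = tree.getroot()
    size = root.find("size")
    if size is None or size.find("width") is None or size.find("height") is None:
        raise VocParseError(f"VOC XML {path} is missing the <size> element")
    width = int(size.findtext("width"))
    height = int(size.findtext("height"))
    boxes: list[Box] = []
    for obj in root.findall("object"):
        name = obj.findtext("name")
        if name is None:
            raise VocParseError(f"VOC XML {path} has an <object> without <name>")
        bb = obj.find("bndbox")
        if bb is None:
            raise VocParseError(f"VOC XML {path} has an <object> without <bndbox>")
        xmin = float(bb.findtext("xmin"))
        ymin = float(bb.findtext("ymin"))
        xmax = float(bb.findtext("xmax"))
        ymax = float(bb.findtext("ymax"))
        # 1-based inclusive integers -> 0-based half-open floats
        boxes.append(Box(xmin - 1.0, ymin - 1.0, xmax, ymax, normalize_class(name)))
    return VocAnnotation(width=width, height=height, boxes=boxes,
                         filename=root.findtext("filename") or path.stem)


def write_voc_xml(image: Union[AnnotatedImage, VocAnnotation], path: PathLike) -> None:
    """Write an annotation as Pascal VOC XML (boxes validated against the raster)."""
    if isinstance(image, AnnotatedImage):
        width, height, boxes = image.width, image.height, image.boxes
        filename = image.source_id or Path(path).stem
    else:
        width, height, boxes = image.width, image.height, image.boxes
        filename = image.filename or Path(path).stem
    for b in boxes:
        if b.x2 > width or b.y2 > height:
            raise ValueError(f"box {b} lies outside the {width}x{height} image")

    root = etree.Element("annotation")
    etree.SubElement(root, "folder").text = str(Path(path).parent.name)
    etree.SubElement(root, "filename").text = filename
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(int(width))
    etree.SubElement(size, "height").text = str(int(height))
    etree.SubElement(size, "depth").text = "3"
    for b in boxes:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = b.cls
        etree.SubElement(obj, "pose").text = "Unspecified"
        etree.SubElement(obj, "truncated").text = "0"
        etree.SubElement(obj, "difficult").text = "0"
        bb = etree.SubElement(obj, "bndbox")
        etree.SubElement(bb, "xmin").text = str(int(round(b.x1)) + 1)
        etree.SubElement(bb, "ymin").text = str(int(round(b.y1)) + 1)
        etree.SubElement(bb, "xmax").text = str(int(round(b.x2)))
        etree.SubElement(bb, "ymax").text = str(int(round(b.y2)))
    etree.ElementTree(root).write(str(path), pretty_print=True,
                                  xml_declaration=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# YOLO txt labels
# ---------------------------------------------------------------------------

def boxes_to_yolo(boxes: Sequence[Box], image_size: tuple[int, int]) -> list[str]:
    """Convert absolute corner boxes to normalized ``cls cx cy w h`` lines."""
    w, h = image_size
    lines = []
    for b in boxes:
        cx, cy = (b.x1 + b.x2) / 2 / w, (b.y1 + b.y2) / 2 / h
        bw, bh = b.width / w, b.height / h
        for v in (cx, cy, bw, bh):
            if not (0.0 <= v <= 1.0):
                raise ValueError(
                    f"normalized value {v} outside [0,1] for box {b} in {w}x{h} image"
                )
        lines.append(f"{b.cls_index} {cx:.6f} {cy:.6f} {bw:.6f} {bh:.6f}")
    return lines


def yolo_to_boxes(lines: Iterable[str], image_size: tuple[int, int]) -> list[Box]:
    """Invert :func:`boxes_to_yolo`."""
    w, h = image_size
    boxes = []
    for ln in lines:
        ln = ln.strip()
        if not ln:
            continue
        parts = ln.split()
        k = int(parts[0])
        cx, cy, bw, bh = (float(p) for p in parts[1:5])
        for v in (cx, cy, bw, bh):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"normalized value {v} outside [0,1] in line {ln!r}")
        boxes.append(Box((cx - bw / 2) * w, (cy - bh / 2) * h,
                         (cx + bw / 2) * w, (cy + bh / 2) * h, CLASSES[k]))
    return boxes


def yolo_txt_convert(data, image_size: tuple[int, int], direction: str):
    """Dispatching wrapper: ``direction`` is ``to_yolo`` or ``from_yolo``."""
    if direction == "to_yolo":
        return boxes_to_yolo(data, image_size)
    if direction == "from_yolo":
        return yolo_to_boxes(data, image_size)
    raise ValueError(f"direction must be 'to_yolo' or 'from_yolo', got {direction!r}")


# ---------------------------------------------------------------------------
# Behavior-record CSV
# ---------------------------------------------------------------------------

def write_record_csv(records: Sequence[BehaviorRecord], path: PathLike) -> None:
    """Write per-second behavior records with the fixed column order."""
    rows = []
    for r in records:
        rows.append({
            "Date": r.date.isoformat(),
            "Time": r.time.strftime("%H:%M:%S"),
            "Standing": r.standing,
            "Drinking": r.drinking,
            "LyingDown": r.lying_down,
            "Feeding": r.feeding,
        })
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    df.to_csv(path, index=False, encoding="utf-8")


def read_record_csv(path: PathLike) -> list[BehaviorRecord]:
    df = pd.read_csv(path, dtype={"Date": str, "Time": str})
    if list(df.columns) != RECORD_COLUMNS:
        raise ValueError(
            f"record CSV must have columns {RECORD_COLUMNS}, got {list(df.columns)}"
        )
    records = []
    for _, row in df.iterrows():
        records.append(BehaviorRecord(
            date=_dt.date.fromisoformat(row["Date"]),
            time=_dt.time.fromisoformat(row["Time"]),
            standing=int(row["Standing"]),
            drinking=int(row["Drinking"]),
            lying_down=int(row["LyingDown"]),
            feeding=int(row["Feeding"]),
        ))
    return records


# ---------------------------------------------------------------------------
# Images and frame streams
# ---------------------------------------------------------------------------

def read_image(path: PathLike) -> np.ndarray:
    """Read an image as H x W x 3 uint8 RGB."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return np.ascontiguousarray(arr.astype(np.uint8))


def write_image(image: np.ndarray, path: PathLike) -> None:
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def frame_stream(
    source: PathLike,
    sample_interval: int = 1,
    fps: float = 30.0,
) -> Iterator[tuple[np.ndarray, float]]:
    """Yield every ``sample_interval``-th frame with a monotone timestamp.

    ``source`` may be a directory of ordered image files or a multi-frame
    image file (TIFF/GIF stack).  The first sampled frame is index 0 and the
    timestamp of frame ``i`` is ``i / fps`` seconds.

    An unreadable source raises ``IOError``; a source with zero frames yields
    nothing (empty iterator, not an error).
    """
    if sample_interval < 1:
        raise ValueError(f"sample_interval must be >= 1, got {sample_interval}")
    source = Path(source)
    if not source.exists():
        raise IOError(f"frame source {source} does not exist")

    def frames() -> Iterator[np.ndarray]:
        if source.is_dir():
            files = sorted(p for p in source.iterdir()
                           if p.suffix.lower() in IMAGE_EXTENSIONS)
            for f in files:
                yield read_image(f)
        else:
            try:
                for frame in iio.imiter(source):
                    frame = np.asarray(frame)
                    if frame.ndim == 2:
                        frame = np.stack([frame] * 3, axis=-1)
                    yield frame[:, :, :3].astype(np.uint8)
            except Exception as exc:  # pragma: no cover - codec-dependent
                raise IOError(f"cannot read frames from {source}: {exc}") from exc

    for idx, frame in enumerate(frames()):
        if idx % sample_interval == 0:
            yield frame, idx / fps
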
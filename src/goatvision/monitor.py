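"""The online monitoring pipeline as a deterministic batch computation:
frame sampling, mode-selectable detection, per-second behavior counting,
record persistence, time-budget aggregation, system-vs-manual comparison,
and a VOC-style mAP evaluator.

A monitoring session samples one representative frame per elapsed second
(the first frame falling in that second), runs the detector, counts the
detected boxes per behavior class, and appends one record row.  Summing
``count x record period`` over the session gives the per-behavior time
budget in goat-seconds.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Optional, Sequence, Union

import numpy as np

from .formats_io import PathLike, frame_stream, write_record_csv
from .model_zoo import Detector, EvalProtocol, iou_matrix, predict
from .synthetic import DEFAULT_START
from .types import CLASSES, BehaviorRecord, Box

#: operation mode -> detector variant, as the monitoring system defines them
MODE_VARIANTS = {"fast": "snca", "balanced": "gnca", "precise": "gsca"}


@dataclass(frozen=True)
class ModeConfig:
    mode: str = "precise"
    protocol: EvalProtocol = field(default_factory=EvalProtocol)
    record_hz: float = 1.0

    def __post_init__(self):
        if self.mode not in MODE_VARIANTS:
            raise ValueError(f"mode must be one of {sorted(MODE_VARIANTS)}")
        if self.record_hz <= 0:
            raise ValueError("record_hz must be positive")

    @property
    def variant(self) -> str:
        return MODE_VARIANTS[self.mode]


@dataclass(frozen=True)
class TimeBudget:
    """Per-behavior accumulated goat-time, in seconds."""

    standing: float = 0.0
    drinking: float = 0.0
    lying_down: float = 0.0
    feeding: float = 0.0

    def __post_init__(self):
        for name in ("standing", "drinking", "lying_down", "feeding"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} time must be >= 0")

    def as_dict(self) -> dict[str, float]:
        return {"standing": self.standing, "drinking": self.drinking,
                "lying_down": self.lying_down, "feeding": self.feeding}


DetectorLike = Union[Detector, Callable[[np.ndarray], list[Box]]]


def _as_detector_fn(detector: DetectorLike, protocol: EvalProtocol
                    ) -> Callable[[np.ndarray], list[Box]]:
    if isinstance(detector, Detector):
        return lambda frame: predict(detector, frame, protocol)
    return detector


def keyframe_extract(frames: Iterable, interval_s: float, fps: float
                     ) -> Iterator:
    """Yield every ``floor(interval_s * fps)``-th item of a frame iterable.

    Sampled indices form the arithmetic progression 0, step, 2*step, ...
    """
    step = int(interval_s * fps)
    if step < 1:
        raise ValueError("interval_s * fps must be >= 1")
    for i, item in enumerate(frames):
        if i % step == 0:
            yield item


def per_second_counts(detections_for_second: Sequence[Box],
                      timestamp: _dt.datetime) -> BehaviorRecord:
    """Count post-NMS boxes per class into one record row."""
    counts = {c: 0 for c in CLASSES}
    for b in detections_for_second:
        counts[b.cls] += 1
    return BehaviorRecord.from_class_counts(timestamp.date(), timestamp.time(),
                                            counts)


def run_monitor(source, mode_config: ModeConfig, detector: DetectorLike,
                duration: int, fps: float = 30.0,
                out_csv: Optional[PathLike] = None,
                start: Optional[_dt.datetime] = None
                ) -> tuple[list[BehaviorRecord], TimeBudget]:
    """Produce one behavior record per elapsed second of ``source``.

    ``source`` may be a path (handed to the frame-stream reader) or an
    iterable of ``(frame, seconds)`` pairs.  The representative frame of each
    second is the first frame whose timestamp falls in it.  If the source
    runs out before ``duration`` seconds, the record stream is truncated with
    a warning.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    start = start or DEFAULT_START
    detect = _as_detector_fn(detector, mode_config.protocol)
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        stream: Iterable = frame_stream(source, sample_interval=1, fps=fps)
    else:
        stream = source

    records: list[BehaviorRecord] = []
    next_second = 0
    for frame, ts in stream:
        if next_second >= duration:
            break
        if ts >= next_second:
            t = start + _dt.timedelta(seconds=next_second)
            records.append(per_second_counts(detect(frame), t))
            next_second += 1
    if next_second < duration:
        warnings.warn(
            f"frame source exhausted after {next_second} of {duration} "
            f"seconds; record stream truncated")
    if out_csv is not None:
        write_record_csv(records, out_csv)
    return records, aggregate_time_budget(records, period_s=1.0 / mode_config.record_hz)


def aggregate_time_budget(records: Sequence[BehaviorRecord],
                          period_s: float = 1.0) -> TimeBudget:
    """Per-behavior goat-seconds: sum of count x record period."""
    if period_s <= 0:
        raise ValueError("period_s must be positive")
    acc = {"standing": 0.0, "drinking": 0.0, "lying_down": 0.0, "feeding": 0.0}
    for r in records:
        for k, v in r.counts().items():
            acc[k] += v * period_s
    return TimeBudget(**acc)


def compare_budgets(system: TimeBudget, manual: TimeBudget
                    ) -> dict[str, Optional[float]]:
    """Relative differences 100 * (system - manual) / manual, per behavior.

    Also reports the pooled feeding+standing difference — the reconciliation
    check for goats that stand at the trough without actually eating, which
    detection attributes to feeding but a human observer counts as standing.
    Behaviors with zero manual time are reported as ``None`` (undefined).
    """
    out: dict[str, Optional[float]] = {}
    s, m = system.as_dict(), manual.as_dict()
    for k in s:
        out[k] = 100.0 * (s[k] - m[k]) / m[k] if m[k] > 0 else None
    pooled_m = m["feeding"] + m["standing"]
    pooled_s = s["feeding"] + s["standing"]
    out["feeding_plus_standing"] = (
        100.0 * (pooled_s - pooled_m) / pooled_m if pooled_m > 0 else None)
    return out


# ---------------------------------------------------------------------------
# mAP evaluation
# ---------------------------------------------------------------------------

@dataclass
class MapResult:
    per_class_ap: dict[str, float]
    map50: float


def _average_precision(recall: np.ndarray, precision: np.ndarray) -> float:
    """101-point interpolated area under the PR curve."""
    r_samples = np.linspace(0, 1, 101)
    # precision envelope: max precision at recall >= r
    ap = 0.0
    for r in r_samples:
        mask = recall >= r - 1e-12
        ap += precision[mask].max() if mask.any() else 0.0
    return ap / 101.0


def evaluate_map(detections: Sequence[Sequence[Box]],
                 ground_truth: Sequence[Sequence[Box]],
                 protocol: EvalProtocol = EvalProtocol(),
                 match_iou: float = 0.5) -> MapResult:
    """Per-class AP and mAP by greedy confidence-ordered matching at IoU 0.5.

    ``detections[i]`` and ``ground_truth[i]`` hold the boxes of image i;
    detections must carry confidences.  Each truth is matched at most once.
    A class absent from the ground truth has undefined AP and is excluded
    from the mean with a warning.
    """
    if len(detections) != len(ground_truth):
        raise ValueError("detections and ground_truth must cover the same images")
    per_class_ap: dict[str, float] = {}
    for cls in CLASSES:
        n_gt = sum(1 for boxes in ground_truth for b in boxes if b.cls == cls)
        if n_gt == 0:
            warnings.warn(f"class {cls!r} absent from ground truth; "
                          f"AP undefined and excluded from the mean")
            continue
        rows = []  # (conf, image_idx, det_box)
        for i, boxes in enumerate(detections):
            for b in boxes:
                if b.cls == cls:
                    if b.conf is None:
                        raise ValueError("detections must carry confidences")
                    if b.conf >= protocol.conf_threshold:
                        rows.append((b.conf, i, b))
        rows.sort(key=lambda r: -r[0])
        matched: dict[int, set[int]] = {}
        tp = np.zeros(len(rows))
        fp = np.zeros(len(rows))
        gt_per_img = [
            [b for b in boxes if b.cls == cls] for boxes in ground_truth]
        for k, (conf, i, det) in enumerate(rows):
            gts = gt_per_img[i]
            used = matched.setdefault(i, set())
            best_iou, best_j = 0.0, -1
            if gts:
                ious = iou_matrix(det.xyxy(), np.stack([g.xyxy() for g in gts]))[0]
                for j in np.argsort(-ious):
                    if j in used:
                        continue
                    best_iou, best_j = float(ious[j]), int(j)
                    break
            if best_j >= 0 and best_iou >= match_iou:
                tp[k] = 1
                used.add(best_j)
            else:
                fp[k] = 1
        if len(rows) == 0:
            per_class_ap[cls] = 0.0
            continue
        ctp, cfp = np.cumsum(tp), np.cumsum(fp)
        recall = ctp / n_gt
        precision = ctp / np.maximum(ctp + cfp, 1e-12)
        per_class_ap[cls] = _average_precision(recall, precision)
    map50 = float(np.mean(list(per_class_ap.values()))) if per_class_ap else 0.0
    return MapResult(per_class_ap=per_class_ap, map50=map50)
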
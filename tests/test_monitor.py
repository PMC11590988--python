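"""Monitoring pipeline: sampling, counting, budgets, comparison and mAP."""

import datetime as dt

import numpy as np
import pytest

from goatvision.formats_io import read_record_csv
from goatvision.monitor import (MODE_VARIANTS, MapResult, ModeConfig,
                                TimeBudget, aggregate_time_budget,
                                compare_budgets, evaluate_map,
                                keyframe_extract, per_second_counts,
                                run_monitor)
from goatvision.synthetic import DEFAULT_START, PenSceneConfig, generate_video
from goatvision.types import BehaviorRecord, Box


class TestKeyframeExtract:
    def test_one_second_interval_at_30fps(self):
        out = list(keyframe_extract(range(90), interval_s=1, fps=30))
        assert out == [0, 30, 60]

    def test_step_one_yields_all(self):
        assert list(keyframe_extract(range(7), interval_s=1, fps=1)) == list(range(7))

    def test_indices_are_arithmetic_progression(self):
        out = list(keyframe_extract(range(100), interval_s=0.4, fps=30))
        diffs = {b - a for a, b in zip(out, out[1:])}
        assert diffs == {12} and out[0] == 0

    def test_sub_frame_interval_rejected(self):
        with pytest.raises(ValueError):
            list(keyframe_extract(range(5), interval_s=0.01, fps=10))


class TestPerSecondCounts:
    def test_known_monitoring_row(self):
        boxes = ([Box(i * 10, 0, i * 10 + 5, 5, "stand", conf=0.9) for i in range(8)]
                 + [Box(0, 10, 5, 15, "drink", conf=0.9)]
                 + [Box(i * 10, 20, i * 10 + 5, 25, "lying", conf=0.9) for i in range(10)]
                 + [Box(i * 10, 30, i * 10 + 5, 35, "eat", conf=0.9) for i in range(3)])
        rec = per_second_counts(boxes, dt.datetime(2023, 10, 8, 9, 15, 3))
        assert (rec.standing, rec.drinking, rec.lying_down, rec.feeding) == (8, 1, 10, 3)
        assert rec.time == dt.time(9, 15, 3)

    def test_empty_detections_zero_record(self):
        rec = per_second_counts([], DEFAULT_START)
        assert rec.total == 0

    def test_counts_sum_equals_detection_count(self, rng):
        for _ in range(100):
            n = int(rng.integers(0, 30))
            boxes = [Box(1, 1, 5, 5, ("lying", "stand", "drink", "eat")[rng.integers(4)],
                         conf=0.5) for _ in range(n)]
            assert per_second_counts(boxes, DEFAULT_START).total == n


class TestModeConfig:
    def test_mode_variant_mapping(self):
        assert ModeConfig(mode="fast").variant == "snca"
        assert ModeConfig(mode="balanced").variant == "gnca"
        assert ModeConfig(mode="precise").variant == "gsca"
        assert set(MODE_VARIANTS) == {"fast", "balanced", "precise"}

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            ModeConfig(mode="turbo")


@pytest.fixture(scope="module")
def video():
    return generate_video(PenSceneConfig(image_size=(320, 240), n_goats=5, seed=21),
                          n_seconds=10, fps=2, motion=0.3)


def oracle_detector(video):
    """Ground-truth lookup detector over the generated frames."""
    table = {k: [Box(b.x1, b.y1, b.x2, b.y2, b.cls, conf=1.0) for b in boxes]
             for k, boxes in enumerate(video.boxes_per_frame)}

    frames = [(f, i / video.fps) for i, f in enumerate(video.frames)]

    def detect_by_index(frame):
        for k, (f, _) in enumerate(frames):
            if f is frame:
                return table[k]
        raise AssertionError("unknown frame")

    return frames, detect_by_index


class TestRunMonitor:
    def test_oracle_detector_reproduces_ground_truth(self, video, tmp_path):
        frames, detect = oracle_detector(video)
        out = tmp_path / "records.csv"
        records, budget = run_monitor(iter(frames), ModeConfig(mode="precise"),
                                      detect, duration=10, out_csv=out)
        assert records == video.records
        assert read_record_csv(out) == records  # CSV round-trip
        truth_budget = aggregate_time_budget(video.records)
        assert budget == truth_budget

    def test_zero_duration_empty(self, video):
        frames, detect = oracle_detector(video)
        records, budget = run_monitor(iter(frames), ModeConfig(), detect, duration=0)
        assert records == [] and budget == TimeBudget()

    def test_truncation_warns(self, video):
        frames, detect = oracle_detector(video)
        with pytest.warns(UserWarning, match="truncated"):
            records, _ = run_monitor(iter(frames), ModeConfig(), detect,
                                     duration=99)
        assert len(records) == 10


class TestTimeBudget:
    def test_single_record(self):
        r = BehaviorRecord(dt.date(2023, 10, 8), dt.time(9, 15, 3), 8, 1, 10, 3)
        b = aggregate_time_budget([r])
        assert b == TimeBudget(standing=8, drinking=1, lying_down=10, feeding=3)

    def test_empty_stream_zero_budget(self):
        assert aggregate_time_budget([]) == TimeBudget()

    def test_additive_over_concatenation(self, rng):
        recs = [BehaviorRecord(dt.date(2023, 10, 8),
                               (dt.datetime(2023, 10, 8, 9) +
                                dt.timedelta(seconds=i)).time(),
                               *(int(v) for v in rng.integers(0, 9, 4)))
                for i in range(20)]
        whole = aggregate_time_budget(recs)
        a = aggregate_time_budget(recs[:7])
        b = aggregate_time_budget(recs[7:])
        for k in whole.as_dict():
            assert whole.as_dict()[k] == a.as_dict()[k] + b.as_dict()[k]

    def test_period_scaling(self):
        r = BehaviorRecord(dt.date(2023, 10, 8), dt.time(9, 0), 4, 0, 2, 1)
        assert aggregate_time_budget([r], period_s=2.0).standing == 8.0


class TestCompareBudgets:
    def test_identical_budgets_zero_everywhere(self):
        b = TimeBudget(10, 5, 20, 8)
        out = compare_budgets(b, b)
        assert all(v == 0.0 for v in out.values())

    def test_ten_percent_difference(self):
        out = compare_budgets(TimeBudget(standing=110, drinking=1,
                                         lying_down=1, feeding=1),
                              TimeBudget(standing=100, drinking=1,
                                         lying_down=1, feeding=1))
        assert out["standing"] == pytest.approx(10.0)

    def test_pooled_feeding_standing_hand_oracle(self):
        system = TimeBudget(standing=90, drinking=2, lying_down=50, feeding=60)
        manual = TimeBudget(standing=100, drinking=2, lying_down=50, feeding=50)
        out = compare_budgets(system, manual)
        assert out["feeding"] == pytest.approx(20.0)
        assert out["standing"] == pytest.approx(-10.0)
        # pooled: (150 - 150) / 150 = 0
        assert out["feeding_plus_standing"] == pytest.approx(0.0)

    def test_zero_manual_reported_undefined(self):
        out = compare_budgets(TimeBudget(drinking=3), TimeBudget())
        assert out["drinking"] is None


class TestEvaluateMap:
    def gt(self):
        return [[Box(10, 10, 50, 50, "lying"), Box(60, 60, 90, 90, "stand")],
                [Box(5, 5, 30, 30, "drink"), Box(40, 40, 70, 70, "eat")]]

    def as_detections(self, truths, conf=1.0):
        return [[Box(b.x1, b.y1, b.x2, b.y2, b.cls, conf=conf) for b in boxes]
                for boxes in truths]

    def test_perfect_detections_map_one(self):
        truths = self.gt()
        res = evaluate_map(self.as_detections(truths), truths)
        assert res.map50 == pytest.approx(1.0)
        assert set(res.per_class_ap) == {"lying", "stand", "drink", "eat"}

    def test_no_detections_map_zero(self):
        truths = self.gt()
        res = evaluate_map([[], []], truths)
        assert res.map50 == 0.0

    def test_hand_built_pr_curve(self):
        """One class, two truths, one TP (conf .9) and one FP (conf .8):
        the 101-point interpolated AP is 51/101."""
        truths = [[Box(10, 10, 50, 50, "lying"), Box(100, 100, 140, 140, "lying")]]
        dets = [[Box(10, 10, 50, 50, "lying", conf=0.9),
                 Box(200, 10, 240, 50, "lying", conf=0.8)]]
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # three classes absent from truth
            res = evaluate_map(dets, truths)
        assert res.per_class_ap["lying"] == pytest.approx(51 / 101)

    def test_invariant_to_detection_order(self, rng):
        truths = self.gt()
        dets = self.as_detections(truths, conf=0.7)
        dets[0].append(Box(1, 1, 8, 8, "lying", conf=0.3))
        shuffled = [list(rng.permutation(np.array(d, dtype=object))) for d in dets]
        a = evaluate_map(dets, truths).map50
        b = evaluate_map(shuffled, truths).map50
        assert a == pytest.approx(b)

    def test_absent_class_excluded_with_warning(self):
        truths = [[Box(10, 10, 50, 50, "lying")]]
        dets = self.as_detections(truths)
        with pytest.warns(UserWarning, match="absent"):
            res = evaluate_map(dets, truths)
        assert set(res.per_class_ap) == {"lying"}
        assert isinstance(res, MapResult)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            evaluate_map([[]], [[], []])
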
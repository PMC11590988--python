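"""Independent oracles for the box-regression, distribution and class losses.

The oracle implementations here are straight-line numpy float computations of
the published formulas, written without reference to the package's autodiff
path.
"""

import math

import numpy as np
import pytest

from goatvision import losses
from goatvision.losses import (Assignment, LossWeights, alpha_ciou_loss,
                               box_loss, ciou_loss, cls_loss, dfl_loss,
                               eiou_loss, iou, siou_loss, total_loss)
from goatvision.nn import Tensor
from goatvision.types import Box


def rand_pairs(rng, n, lo=0.0, hi=100.0):
    xy = rng.uniform(lo, hi - 10, (n, 2, 2))
    wh = rng.uniform(0.5, 40.0, (n, 2, 2))
    boxes = np.concatenate([xy, xy + wh], axis=2)  # (n, 2, 4)
    return boxes[:, 0], boxes[:, 1]


# -- straight-line oracles -----------------------------------------------------

def oracle_iou(p, t):
    iw = max(0.0, min(p[2], t[2]) - max(p[0], t[0]))
    ih = max(0.0, min(p[3], t[3]) - max(p[1], t[1]))
    inter = iw * ih
    union = (p[2] - p[0]) * (p[3] - p[1]) + (t[2] - t[0]) * (t[3] - t[1]) - inter
    return inter / union if union > 0 else 0.0


def oracle_ciou_terms(p, t):
    i = oracle_iou(p, t)
    pcx, pcy = (p[0] + p[2]) / 2, (p[1] + p[3]) / 2
    tcx, tcy = (t[0] + t[2]) / 2, (t[1] + t[3]) / 2
    rho2 = (pcx - tcx) ** 2 + (pcy - tcy) ** 2
    cw = max(p[2], t[2]) - min(p[0], t[0])
    ch = max(p[3], t[3]) - min(p[1], t[1])
    c2 = cw ** 2 + ch ** 2
    pw, ph = p[2] - p[0], p[3] - p[1]
    tw, th = t[2] - t[0], t[3] - t[1]
    v = 4 / math.pi ** 2 * (math.atan(tw / th) - math.atan(pw / ph)) ** 2
    alpha = v / ((1 - i) + v) if i < 1 else 0.0
    return i, rho2, c2, v, alpha, cw, ch, pw, ph, tw, th, pcx, pcy, tcx, tcy


def oracle_ciou(p, t):
    i, rho2, c2, v, alpha, *_ = oracle_ciou_terms(p, t)
    return 1 - i + rho2 / c2 + alpha * v


def oracle_eiou(p, t):
    i, rho2, c2, v, alpha, cw, ch, pw, ph, tw, th, *_ = oracle_ciou_terms(p, t)
    return 1 - i + rho2 / c2 + (pw - tw) ** 2 / cw ** 2 + (ph - th) ** 2 / ch ** 2


def oracle_siou(p, t):
    (i, rho2, c2, v, alpha, cw, ch, pw, ph, tw, th,
     pcx, pcy, tcx, tcy) = oracle_ciou_terms(p, t)
    s_cw, s_ch = tcx - pcx, tcy - pcy
    sigma = math.hypot(s_cw, s_ch)
    if sigma == 0:
        angle = 0.0
    else:
        sin_a, sin_b = abs(s_ch) / sigma, abs(s_cw) / sigma
        x = sin_b if sin_a > math.sqrt(2) / 2 else sin_a
        angle = math.sin(2 * math.asin(min(1.0, x)))
    gamma = 2 - angle
    dist = (1 - math.exp(-gamma * (s_cw / cw) ** 2)) \
        + (1 - math.exp(-gamma * (s_ch / ch) ** 2))
    ww = abs(pw - tw) / max(pw, tw)
    wh = abs(ph - th) / max(ph, th)
    shape = (1 - math.exp(-ww)) ** 4 + (1 - math.exp(-wh)) ** 4
    return 1 - i + (dist + shape) / 2


class TestIoU:
    def test_identical_boxes(self):
        b = Box(3, 4, 10, 12, "eat")
        assert losses.pair_value(iou, b, b) == pytest.approx(1.0, abs=1e-8)

    def test_disjoint_boxes(self):
        assert losses.pair_value(iou, Box(0, 0, 2, 2, "eat"),
                                 Box(5, 5, 8, 8, "eat")) == 0.0

    def test_hand_case_one_seventh(self):
        v = losses.pair_value(iou, Box(0, 0, 2, 2, "eat"), Box(1, 1, 3, 3, "eat"))
        assert v == pytest.approx(1 / 7, abs=1e-9)

    def test_exhaustive_pixel_enumeration_small_grid(self):
        """IoU equals unit-cell enumeration for every integer box pair in a
        10x10 grid (vectorized over all ~3000^2 pairs)."""
        n = 10
        cells = []
        coords = []
        for x1 in range(n):
            for x2 in range(x1 + 1, n + 1):
                for y1 in range(n):
                    for y2 in range(y1 + 1, n + 1):
                        m = np.zeros((n, n), dtype=np.float32)
                        m[y1:y2, x1:x2] = 1
                        cells.append(m.ravel())
                        coords.append([x1, y1, x2, y2])
        masks = np.stack(cells)                      # (B, 100)
        coords = np.array(coords, dtype=float)       # (B, 4)
        inter = masks @ masks.T                      # pixel-count intersections
        areas = masks.sum(axis=1)
        union = areas[:, None] + areas[None, :] - inter
        expected = inter / union
        got = iou(Tensor(np.repeat(coords, len(coords), axis=0)),
                  Tensor(np.tile(coords, (len(coords), 1)))).data.reshape(
                      len(coords), len(coords))
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_degenerate_box_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="degenerate"):
            v = iou(Tensor(np.array([[0.0, 0, 0, 5]])),
                    Tensor(np.array([[0.0, 0, 4, 4]])))
        assert v.data.item() == 0.0


class TestRegressionLossFamily:
    @pytest.mark.parametrize("loss,oracle", [
        (ciou_loss, oracle_ciou),
        (eiou_loss, oracle_eiou),
        (siou_loss, oracle_siou),
    ])
    def test_dual_implementation_on_random_pairs(self, rng, loss, oracle):
        p, t = rand_pairs(rng, 1000)
        got = loss(Tensor(p), Tensor(t)).data.ravel()
        want = np.array([oracle(pi, ti) for pi, ti in zip(p, t)])
        np.testing.assert_allclose(got, want, atol=1e-6)
        ious = iou(Tensor(p), Tensor(t)).data.ravel()
        assert np.all(got >= 1 - ious - 1e-7)   # penalty terms are additive
        assert np.all(got <= 4.0 + 1e-7)        # loose declared upper bound

    @pytest.mark.parametrize("loss", [ciou_loss, eiou_loss, siou_loss,
                                      lambda p, t: alpha_ciou_loss(p, t, 3.0)])
    def test_zero_on_coincident_boxes(self, rng, loss):
        b = rng.uniform(0, 50, (200, 2))
        wh = rng.uniform(1, 30, (200, 2))
        boxes = np.concatenate([b, b + wh], axis=1)
        v = loss(Tensor(boxes), Tensor(boxes.copy())).data
        np.testing.assert_allclose(v, 0.0, atol=1e-8)

    @pytest.mark.parametrize("loss", [ciou_loss, eiou_loss, siou_loss,
                                      lambda p, t: alpha_ciou_loss(p, t, 2.0)])
    def test_translation_and_scale_invariance(self, rng, loss):
        p, t = rand_pairs(rng, 300)
        base = loss(Tensor(p), Tensor(t)).data
        shift = rng.uniform(5, 50, (300, 2))
        shifted = loss(Tensor(p + np.tile(shift, 2)),
                       Tensor(t + np.tile(shift, 2))).data
        np.testing.assert_allclose(shifted, base, atol=1e-6)
        k = 3.7
        scaled = loss(Tensor(p * k), Tensor(t * k)).data
        np.testing.assert_allclose(scaled, base, atol=1e-6)

    def test_concentric_same_aspect_reduces_to_iou_term(self, rng):
        # rho = 0 and v = 0, so ciou_loss = 1 - iou exactly
        for _ in range(50):
            cx, cy = rng.uniform(40, 80, 2)
            w, h = rng.uniform(5, 12, 2)
            k = rng.uniform(1.1, 2.5)
            p = Box(cx - w, cy - h, cx + w, cy + h, "eat")
            t = Box(cx - k * w, cy - k * h, cx + k * w, cy + k * h, "eat")
            lc = losses.pair_value(ciou_loss, p, t)
            li = 1 - losses.pair_value(iou, p, t)
            assert lc == pytest.approx(li, abs=1e-9)


class TestAlphaCiou:
    def test_alpha_one_equals_ciou_machine_precision(self, rng):
        p, t = rand_pairs(rng, 1000)
        a1 = alpha_ciou_loss(Tensor(p), Tensor(t), a=1.0).data
        c = ciou_loss(Tensor(p), Tensor(t)).data
        np.testing.assert_array_equal(a1, c)

    def test_zero_for_any_exponent_on_identical(self):
        b = Box(5, 5, 20, 25, "stand")
        for a in (1.0, 2.0, 3.0, 5.0):
            assert losses.pair_value(alpha_ciou_loss, b, b, a=a) \
                == pytest.approx(0.0, abs=1e-8)
        # fractional exponents carry the differentiability guard's eps^a floor
        assert losses.pair_value(alpha_ciou_loss, b, b, a=0.5) \
            == pytest.approx(0.0, abs=1e-4)

    def test_higher_exponent_increases_loss_when_iou_below_one(self, rng):
        # concentric same-aspect pairs: loss = 1 - iou^a, increasing in a
        for _ in range(50):
            cx, cy = rng.uniform(40, 80, 2)
            w, h = rng.uniform(5, 12, 2)
            k = rng.uniform(1.2, 2.5)
            p = Box(cx - w, cy - h, cx + w, cy + h, "eat")
            t = Box(cx - k * w, cy - k * h, cx + k * w, cy + k * h, "eat")
            l3 = losses.pair_value(alpha_ciou_loss, p, t, a=3.0)
            l1 = losses.pair_value(alpha_ciou_loss, p, t, a=1.0)
            assert l3 > l1

    def test_exponent_validation(self):
        with pytest.raises(ValueError):
            alpha_ciou_loss(Tensor(np.zeros((1, 4))), Tensor(np.zeros((1, 4))), a=0)


class TestDfl:
    def test_one_hot_large_margin_approaches_zero(self):
        logits = np.full((1, 16), -20.0)
        logits[0, 5] = 20.0
        assert float(dfl_loss(logits, np.array([5.0])).data) < 1e-6

    def test_midway_target_weights_halves(self):
        logits = np.zeros((1, 16))  # uniform distribution: log p = -log 16
        v = float(dfl_loss(logits, np.array([7.5])).data)
        assert v == pytest.approx(math.log(16.0))

    def test_matches_hand_computed_cross_entropy(self, rng):
        logits = rng.standard_normal((5, 16))
        t = rng.uniform(0, 15, 5)
        got = float(dfl_loss(logits, t).data)
        want = 0.0
        for k in range(5):
            p = np.exp(logits[k]) / np.exp(logits[k]).sum()
            l, r = int(np.floor(min(t[k], 15 - 1e-6))), int(np.floor(min(t[k], 15 - 1e-6))) + 1
            want += -((r - t[k]) * np.log(p[l]) + (t[k] - l) * np.log(p[r]))
        assert got == pytest.approx(want / 5, rel=1e-6)

    def test_out_of_range_target_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            v = dfl_loss(np.zeros((1, 16)), np.array([99.0]))
        assert np.isfinite(v.data)


class TestClsLoss:
    def test_confident_correct_approaches_zero(self):
        z = np.where(np.eye(4, dtype=bool), 30.0, -30.0)
        assert float(cls_loss(z, np.eye(4)).data) < 1e-9

    def test_zero_logits_balanced_targets_ln2(self):
        targets = np.zeros((10, 4))
        targets[:5] = 1.0
        v = float(cls_loss(np.zeros((10, 4)), targets).data)
        assert v == pytest.approx(math.log(2.0))

    def test_matches_scalar_oracle(self, rng):
        z = rng.standard_normal((6, 4))
        t = (rng.random((6, 4)) > 0.5).astype(float)
        want = np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z))))
        assert float(cls_loss(z, t).data) == pytest.approx(want, rel=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cls_loss(np.zeros((2, 4)), np.zeros((3, 4)))


class _FakeOutput:
    """Minimal detector-output stand-in for objective composition tests."""

    def __init__(self, rng, nc=4, reg_max=16):
        self.strides = (8, 16, 32)
        self.box_maps = [Tensor(rng.standard_normal((1, 4 * reg_max, s, s)))
                         for s in (8, 4, 2)]
        self.cls_maps = [Tensor(rng.standard_normal((1, nc, s, s)))
                         for s in (8, 4, 2)]


class TestTotalLoss:
    def make_assignment(self, rng, output):
        from goatvision.losses import anchor_grid
        shapes = [(m.shape[2], m.shape[3]) for m in output.box_maps]
        pts, strides = anchor_grid(output.strides, shapes)
        M = len(pts)
        fg = np.zeros((1, M), dtype=bool)
        fg[0, [3, 40, 70]] = True
        tb = np.zeros((1, M, 4))
        for m in (3, 40, 70):
            c = pts[m]
            tb[0, m] = [c[0] - 5, c[1] - 4, c[0] + 6, c[1] + 7]
        tc = np.zeros((1, M), dtype=int)
        tc[0, 40] = 2
        return Assignment(pts, strides, fg, tb, tc)

    def test_total_is_weighted_sum(self, rng):
        out = _FakeOutput(rng)
        asg = self.make_assignment(rng, out)
        w = LossWeights(box=7.5, dfl=1.5, cls=0.5)
        b = total_loss(out, asg, w, box_loss_kind="ciou")
        assert b.total == pytest.approx(
            7.5 * b.box_loss + 1.5 * b.dfl_loss + 0.5 * b.cls_loss, rel=1e-6)

    def test_switching_box_loss_changes_only_box_component(self, rng):
        out = _FakeOutput(rng)
        asg = self.make_assignment(rng, out)
        a = total_loss(out, asg, box_loss_kind="ciou")
        b = total_loss(out, asg, box_loss_kind="siou")
        c = total_loss(out, asg, box_loss_kind="alpha_ciou", a=3.0)
        assert a.dfl_loss == b.dfl_loss == c.dfl_loss
        assert a.cls_loss == b.cls_loss == c.cls_loss
        assert len({a.box_loss, b.box_loss, c.box_loss}) == 3

    def test_no_positive_anchors(self, rng):
        out = _FakeOutput(rng)
        from goatvision.losses import anchor_grid
        shapes = [(m.shape[2], m.shape[3]) for m in out.box_maps]
        pts, strides = anchor_grid(out.strides, shapes)
        M = len(pts)
        asg = Assignment(pts, strides, np.zeros((1, M), dtype=bool),
                         np.zeros((1, M, 4)), np.zeros((1, M), dtype=int))
        b = total_loss(out, asg)
        assert b.box_loss == 0.0 and b.dfl_loss == 0.0 and b.cls_loss > 0.0

    def test_unknown_kind_rejected(self, rng):
        out = _FakeOutput(rng)
        asg = self.make_assignment(rng, out)
        with pytest.raises(ValueError):
            total_loss(out, asg, box_loss_kind="giou")

    def test_box_loss_dispatch(self):
        p = Tensor(np.array([[0.0, 0, 4, 4]]))
        t = Tensor(np.array([[1.0, 1, 5, 5]]))
        assert box_loss(p, t, "alpha_ciou", a=1.0).data.item() \
            == pytest.approx(ciou_loss(p, t).data.item())
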
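"""Architecture contracts: blocks, variants, letterbox, decode and NMS."""

import numpy as np
import pytest

from goatvision import nn
from goatvision.model_zoo import (ArchitectureConfig, CBAM, ChannelAttention,
                                  EvalProtocol, GhostModule, GSConv,
                                  NonLocalBlock, attention_block,
                                  attention_heatmap, build_detector,
                                  count_parameters, gc_c2f, iou_matrix,
                                  letterbox, load_weights, nms, predict,
                                  save_weights, sc_c2f, variant_config)
from goatvision.nn import Tensor
from goatvision.types import Box

rng = np.random.default_rng(0)


def conv3x3_params(cin, cout):
    """Parameters of a standard 3x3 conv + batch norm."""
    return cin * cout * 9 + 2 * cout


class TestParameterCounts:
    # printed reference values, in millions
    REFERENCE = {"baseline": 3.02, "gnca": 2.21, "snca": 2.46, "gsca": 2.34}

    @pytest.mark.parametrize("variant", ["baseline", "gnca", "snca", "gsca"])
    def test_variant_count_matches_reference(self, variant):
        det = build_detector(variant_config(variant))
        millions = count_parameters(det) / 1e6
        assert millions == pytest.approx(self.REFERENCE[variant], rel=0.01)

    def test_lightweighting_ordering(self):
        counts = {v: count_parameters(build_detector(variant_config(v)))
                  for v in ("baseline", "gnca", "snca", "gsca")}
        assert counts["gnca"] < counts["gsca"] < counts["snca"] < counts["baseline"]

    def test_affine_map_count(self):
        assert nn.Conv2d(4, 2, 1, bias=True).count_parameters() == 10

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            ArchitectureConfig(variant="yolo9000")
        with pytest.raises(ValueError, match="attention"):
            ArchitectureConfig(fpn_attention="mamba")


class TestForwardContracts:
    def test_stride_consistent_maps(self):
        det = build_detector(variant_config("baseline"))
        det.eval()
        for size in (64, 96):
            with nn.no_grad():
                out = det(Tensor(np.zeros((1, 3, size, size), dtype=np.float32)))
            shapes = [m.shape[2:] for m in out.box_maps]
            assert shapes == [(size // 8,) * 2, (size // 16,) * 2, (size // 32,) * 2]
            assert [m.shape[1] for m in out.cls_maps] == [4, 4, 4]

    def test_non_multiple_of_32_rejected(self):
        det = build_detector(variant_config("baseline"))
        with pytest.raises(ValueError, match="divisible by 32"):
            det(Tensor(np.zeros((1, 3, 50, 50), dtype=np.float32)))


class TestGhostModule:
    def test_channel_arithmetic(self):
        g = GhostModule(64, 128, ratio=2)
        assert g.intrinsic == 64 and g.cheap_ch == 64
        g.initialize(0)
        y = g(Tensor(np.zeros((1, 64, 8, 8), dtype=np.float32)))
        assert y.shape == (1, 128, 8, 8)

    def test_parameters_below_dense_conv(self):
        g = GhostModule(64, 128, ratio=2)
        assert g.count_parameters() < conv3x3_params(64, 128)

    def test_spatial_size_preserved(self):
        g = GhostModule(16, 32).initialize(1)
        y = g(Tensor(rng.standard_normal((2, 16, 7, 5)).astype(np.float32)))
        assert y.shape == (2, 32, 7, 5)

    def test_ratio_validation(self):
        with pytest.raises(ValueError):
            GhostModule(8, 8, ratio=1)


class TestGSConv:
    def test_interleaving_shuffle_order(self):
        gs = GSConv(4, 8)
        gs.initialize(0)
        gs.eval()
        # tag the halves through the batch-norm biases: dense half i -> i+1,
        # depthwise half i -> 101+i (depthwise conv weights zeroed)
        gs.dense.conv.weight.data[...] = 0.0
        gs.dense.bn.bias.data[...] = np.arange(1, 5)
        gs.dw.conv.weight.data[...] = 0.0
        gs.dw.bn.bias.data[...] = np.arange(101, 105)
        y = gs(Tensor(np.zeros((1, 4, 3, 3), dtype=np.float32))).data[0, :, 0, 0]
        silu = lambda v: v / (1 + np.exp(-v))
        np.testing.assert_allclose(y[0::2], silu(np.arange(1.0, 5.0)), atol=1e-5)
        np.testing.assert_allclose(y[1::2], silu(silu(np.arange(101.0, 105.0))),
                                   atol=1e-3)

    def test_shuffle_is_permutation(self):
        gs = GSConv(6, 6).initialize(2)
        gs.eval()
        x = Tensor(rng.standard_normal((1, 6, 4, 4)).astype(np.float32))
        y = gs(x)
        a = gs.dense(x)
        b = gs.dw(a)
        pre = np.concatenate([a.data, b.data], axis=1)
        assert sorted(y.data.sum(axis=(0, 2, 3))) == pytest.approx(
            sorted(pre.sum(axis=(0, 2, 3))))

    def test_parameters_below_dense_conv(self):
        assert GSConv(64, 64, k=3).count_parameters() < conv3x3_params(64, 64)

    def test_odd_channels_rejected(self):
        with pytest.raises(ValueError, match="even"):
            GSConv(8, 7)


class TestLightweightStages:
    @pytest.mark.parametrize("factory", [gc_c2f, sc_c2f])
    def test_output_shape_and_param_saving(self, factory):
        from goatvision.model_zoo import Bottleneck, C2f
        light = factory(32, 32, 2, True).initialize(0)
        standard = C2f(32, 32, 2, True, lambda c, s: Bottleneck(c, s))
        y = light(Tensor(rng.standard_normal((1, 32, 8, 8)).astype(np.float32)))
        assert y.shape == (1, 32, 8, 8)
        assert light.count_parameters() < standard.count_parameters()

    def test_shortcut_flag_changes_structure(self):
        with_sc = gc_c2f(16, 16, 1, True).initialize(3)
        without = gc_c2f(16, 16, 1, False).initialize(3)
        x = Tensor(rng.standard_normal((1, 16, 6, 6)).astype(np.float32))
        with_sc.eval(), without.eval()
        assert not np.allclose(with_sc(x).data, without(x).data)


class TestAttention:
    @pytest.mark.parametrize("kind", ["ca", "se", "cbam", "nonlocal"])
    def test_shape_preserved(self, kind):
        blk = attention_block(kind, 32).initialize(0)
        blk.eval()
        x = Tensor(rng.standard_normal((2, 32, 6, 6)).astype(np.float32))
        assert blk(x).shape == x.shape

    def test_channel_gates_strictly_in_unit_interval(self):
        blk = ChannelAttention(32, reduction=16).initialize(1)
        blk.eval()
        x = Tensor(np.abs(rng.standard_normal((1, 32, 5, 5))).astype(np.float32) + 0.1)
        ratio = blk(x).data / x.data
        assert np.all(ratio > 0) and np.all(ratio < 1)

    def test_cbam_spatial_gate_uniform_on_uniform_input(self):
        blk = CBAM(32, reduction=16).initialize(2)
        blk.eval()
        x = Tensor(np.ones((1, 32, 12, 12), dtype=np.float32))
        y = blk(x).data
        # uniform away from the zero-padded border of the 7x7 spatial conv
        inner = y[:, :, 3:-3, 3:-3]
        assert np.allclose(inner, inner[:, :, :1, :1])

    def test_nonlocal_zeroed_projection_is_identity(self):
        blk = NonLocalBlock(16).initialize(3)
        blk.out.weight.data[...] = 0.0
        blk.out.bias.data[...] = 0.0
        x = Tensor(rng.standard_normal((1, 16, 4, 4)).astype(np.float32))
        np.testing.assert_array_equal(blk(x).data, x.data)

    def test_reduction_guard(self):
        with pytest.raises(ValueError, match="reduction"):
            ChannelAttention(8, reduction=16)


class TestLetterbox:
    def test_square_input_unchanged(self):
        img = rng.integers(0, 255, (640, 640, 3), dtype=np.uint8)
        canvas, tf = letterbox(img)
        assert np.array_equal(canvas, img)
        assert tf.pad_x == 0 and tf.pad_y == 0 and tf.scale == 1.0

    def test_monitoring_frame_gray_bands(self):
        img = rng.integers(0, 255, (720, 1280, 3), dtype=np.uint8)
        canvas, tf = letterbox(img)
        assert canvas.shape == (640, 640, 3)
        assert tf.scale == 0.5 and tf.pad_y == 140
        assert np.all(canvas[:140] == 114) and np.all(canvas[-140:] == 114)

    def test_box_roundtrip_within_one_pixel(self):
        img = np.zeros((720, 1280, 3), dtype=np.uint8)
        _, tf = letterbox(img)
        for _ in range(50):
            x1, y1 = rng.uniform(0, 1200), rng.uniform(0, 600)
            b = np.array([x1, y1, x1 + rng.uniform(1, 80), y1 + rng.uniform(1, 80)])
            back = tf.canvas_to_source(tf.source_to_canvas(b))
            np.testing.assert_allclose(back, b, atol=1.0)


class TestNms:
    def brute_force(self, boxes, scores, thr):
        order = np.argsort(-scores, kind="stable")
        keep, dead = [], set()
        for i in order:
            if i in dead:
                continue
            keep.append(i)
            for j in order:
                if j not in dead and j != i \
                        and iou_matrix(boxes[i:i + 1], boxes[j:j + 1])[0, 0] > thr:
                    dead.add(j)
            dead.add(i)
        return keep

    def test_two_identical_boxes_one_survivor(self):
        boxes = np.array([[0, 0, 10, 10], [0, 0, 10, 10]], dtype=float)
        assert len(nms(boxes, np.array([0.8, 0.8]), 0.5)) == 1

    def test_matches_brute_force_oracle(self):
        for trial in range(10):
            r = np.random.default_rng(trial)
            n = 50
            xy = r.uniform(0, 80, (n, 2))
            wh = r.uniform(5, 40, (n, 2))
            boxes = np.concatenate([xy, xy + wh], axis=1)
            scores = r.uniform(0, 1, n)
            got = list(nms(boxes, scores, 0.5))
            want = self.brute_force(boxes, scores, 0.5)
            assert got == want


@pytest.fixture(scope="module")
def detector():
    return build_detector(variant_config("gsca"), seed=5)


class TestPredictAndHeatmap:
    def test_predict_returns_valid_boxes(self, detector, pen_scene):
        boxes = predict(detector, pen_scene.pixels,
                        EvalProtocol(conf_threshold=0.3, nms_iou=0.5), target=64)
        for b in boxes:
            assert isinstance(b, Box)
            assert 0 <= b.x1 < b.x2 <= pen_scene.width
            assert 0 <= b.y1 < b.y2 <= pen_scene.height
            assert 0 <= b.conf <= 1

    def test_heatmap_contract(self, detector, pen_scene):
        h = attention_heatmap(detector, pen_scene.pixels, neck_level=1, target=64)
        assert h.shape == (pen_scene.height, pen_scene.width)
        assert h.min() >= 0.0 and h.max() <= 1.0
        h2 = attention_heatmap(detector, pen_scene.pixels, neck_level=1, target=64)
        np.testing.assert_array_equal(h, h2)  # deterministic for fixed weights

    def test_heatmap_zero_input_constant(self, detector):
        img = np.zeros((96, 96, 3), dtype=np.uint8)
        h = attention_heatmap(detector, img, neck_level=0, target=64)
        assert np.ptp(h) == pytest.approx(0.0, abs=1e-9)

    def test_heatmap_guards(self, detector):
        img = np.zeros((64, 64, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="neck_level"):
            attention_heatmap(detector, img, neck_level=9, target=64)
        plain = build_detector(variant_config("baseline"))
        with pytest.raises(ValueError, match="attention"):
            attention_heatmap(plain, img, neck_level=0, target=64)

    def test_weight_io_roundtrip(self, detector, tmp_path):
        p = tmp_path / "w.npz"
        save_weights(detector, p)
        other = build_detector(variant_config("gsca"), seed=99)
        load_weights(other, p)
        x = Tensor(rng.standard_normal((1, 3, 64, 64)).astype(np.float32))
        detector.eval(), other.eval()
        with nn.no_grad():
            a, b = detector(x), other(x)
        np.testing.assert_array_equal(a.cls_maps[0].data, b.cls_maps[0].data)
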
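"""EDC block, fusion node, NMS and the miniature detector."""

import numpy as np
import pytest

from thermoroi.detector_core import (
    Detection,
    EdcParams,
    FusionNode,
    TinyDetector,
    db_fuse,
    edc_forward,
    edc_modulate,
    gelu,
    nms,
    sigmoid,
    spatial_channel_attention,
)
from thermoroi.text_prior import load_text_bank
from thermoroi.training_strategy import Box


class TestAttention:
    def test_zero_input_gives_half_weights(self):
        x = np.zeros((1, 3, 4, 5))
        out = spatial_channel_attention(x)
        assert np.allclose(out, 0.0)  # 0 * 0.5 * 0.5

    def test_shape_preserved(self, rng):
        for _ in range(5):
            shape = tuple(rng.integers(1, 6, size=4))
            x = rng.standard_normal(shape)
            assert spatial_channel_attention(x).shape == shape

    def test_matches_loop_broadcast(self, rng):
        x = rng.standard_normal((2, 3, 4, 4))
        out = spatial_channel_attention(x)
        for b in range(2):
            for c in range(3):
                for i in range(4):
                    for j in range(4):
                        a_s = sigmoid(np.array([x[b, :, i, j].mean()]))[0]
                        a_c = sigmoid(np.array([x[b, c].mean()]))[0]
                        assert out[b, c, i, j] == pytest.approx(x[b, c, i, j] * a_s * a_c)


class TestEdc:
    def test_identity_modulation(self, rng):
        c, d = 6, 16
        params = EdcParams.init(d, c, mode="identity")
        x = rng.standard_normal((1, c, 5, 5))
        t = rng.standard_normal(d)
        assert np.allclose(edc_modulate(x, t, params), x)

    def test_pure_shift_modulation(self, rng):
        c, d = 4, 16
        params = EdcParams.init(d, c, mode="zeros")
        shift = rng.standard_normal(c)
        params.b_out[2 + c:] = shift  # cb only; gs = cs = 0
        x = rng.standard_normal((2, c, 3, 3))
        out = edc_modulate(x, np.zeros(d), params)
        assert np.allclose(out, shift[None, :, None, None] * np.ones_like(x))

    def test_matches_broadcast_arithmetic(self, rng):
        c, d = 5, 16
        params = EdcParams.init(d, c, seed=2, mode="zeros")
        params.w_out = rng.standard_normal(params.w_out.shape) * 0.1
        t = rng.standard_normal(d)
        gs, gb, cs, cb, _, _ = params.modulation(t)
        x = rng.standard_normal((1, c, 4, 3))
        out = edc_modulate(x, t, params)
        expected = x * gs * cs[None, :, None, None] + gb + cb[None, :, None, None]
        assert np.allclose(out, expected)

    def test_channel_mismatch_rejected(self, rng):
        params = EdcParams.init(16, 4)
        with pytest.raises(ValueError, match="channel"):
            edc_modulate(rng.standard_normal((1, 5, 2, 2)), np.zeros(16), params)

    def test_identity_at_init_exact(self, rng):
        c, d = 8, 32
        params = EdcParams.init(d, c, mode="zeros")
        x = rng.uniform(-10, 10, size=(2, c, 6, 7))
        t = rng.standard_normal(d)
        assert np.array_equal(edc_forward(x, t, params), x)

    def test_forward_finite_and_normalised(self, rng):
        c, d = 8, 32
        params = EdcParams.init(d, c, seed=1, mode="identity")
        params.w_out = rng.standard_normal(params.w_out.shape) * 0.05
        x = rng.uniform(-10, 10, size=(1, c, 5, 5))
        t = rng.standard_normal(d)
        out = edc_forward(x, t, params)
        assert np.all(np.isfinite(out))
        # the pre-GELU tensor is channel-normalised at every position
        from thermoroi.detector_core import _layer_norm

        gs, gb, cs, cb, _, _ = params.modulation(t)
        xh = (
            spatial_channel_attention(x) * gs * cs[None, :, None, None]
            + gb
            + cb[None, :, None, None]
        )
        z, _ = _layer_norm(xh)
        assert np.abs(z.mean(axis=1)).max() < 1e-9
        assert np.abs(z.var(axis=1) - 1.0).max() < 1e-3


class TestFusion:
    def test_equal_weights_give_mean(self, rng):
        a, b = rng.standard_normal((2, 1, 3, 4, 4))
        node = FusionNode(np.array([1.0, 1.0]), epsilon=1e-12)
        assert np.allclose(db_fuse([a, b], node), (a + b) / 2, atol=1e-9)

    def test_zero_weight_selects_other_branch(self, rng):
        a, b = rng.standard_normal((2, 1, 2, 3, 3))
        node = FusionNode(np.array([1.0, 0.0]), epsilon=1e-12)
        assert np.allclose(db_fuse([a, b], node), a, atol=1e-9)

    def test_convex_combination_bounds(self, rng):
        arrs = [rng.standard_normal((1, 2, 4, 4)) for _ in range(3)]
        node = FusionNode(rng.uniform(0.1, 2.0, size=3))
        out = db_fuse(arrs, node)
        lo = np.minimum.reduce(arrs)
        hi = np.maximum.reduce(arrs)
        slack = 1e-3 * np.maximum(1.0, np.abs(hi))
        assert np.all(out >= lo - np.abs(lo) * 1e-3 - slack)
        assert np.all(out <= hi + np.abs(hi) * 1e-3 + slack)

    def test_normalised_weights_sum_below_one(self):
        node = FusionNode(np.array([2.0, 3.0]), epsilon=0.5)
        w = node.normalized()
        assert w.sum() == pytest.approx(5.0 / 5.5)
        node0 = FusionNode(np.array([2.0, 3.0]), epsilon=0.0)
        assert node0.normalized().sum() == pytest.approx(1.0)

    def test_shape_mismatch_rejected(self, rng):
        node = FusionNode(np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            db_fuse([rng.standard_normal((1, 2, 3, 3)), rng.standard_normal((1, 2, 4, 3))], node)


class TestNms:
    def test_suppresses_overlapping_same_class(self):
        d1 = Detection(Box(0, 0, 10, 10), np.array([0.9, 0.1]), 0)
        d2 = Detection(Box(1, 1, 11, 11), np.array([0.8, 0.1]), 0)
        d3 = Detection(Box(50, 50, 60, 60), np.array([0.7, 0.2]), 0)
        kept = nms([d1, d2, d3], 0.5)
        assert [k.confidence for k in kept] == [0.9, 0.7]

    def test_classes_do_not_suppress_each_other(self):
        d1 = Detection(Box(0, 0, 10, 10), np.array([0.9, 0.0]), 0)
        d2 = Detection(Box(0, 0, 10, 10), np.array([0.0, 0.8]), 1)
        assert len(nms([d1, d2], 0.5)) == 2


@pytest.fixture(scope="module")
def detector(default_bank):
    return TinyDetector(bank=default_bank, seed=0)


@pytest.fixture(scope="module")
def image():
    rng = np.random.default_rng(5)
    return (rng.random((120, 160, 3)) * 255).astype(np.uint8)


class TestTinyDetector:
    def test_deterministic_forward(self, detector, image):
        a = detector.predict(image)
        b = detector.predict(image)
        assert len(a) == len(b)
        for da, db_ in zip(a, b):
            assert da.box == db_.box
            assert np.array_equal(da.class_scores, db_.class_scores)

    def test_confidence_equals_max_class_score(self, detector, image):
        for d in detector.predict(image):
            assert d.confidence == np.max(d.class_scores)
            assert d.category == int(np.argmax(d.class_scores))

    def test_bank_change_moves_scores_not_boxes(self, default_bank, image):
        det_a = TinyDetector(bank=default_bank, seed=0, score_thr=0.0)
        det_b = TinyDetector(bank=list(reversed(default_bank)), seed=0, score_thr=0.0)
        img01_a = img01_b = image.astype(float) / 255.0
        from thermoroi.detector_core import resize, _INPUT_H, _INPUT_W

        small = resize(img01_a, (_INPUT_H, _INPUT_W), anti_aliasing=True)
        ca = det_a._forward_features(small)
        cb = det_b._forward_features(small)
        *_, scores_a, boxes_a = det_a._heads(ca["fused"])
        *_, scores_b, boxes_b = det_b._heads(cb["fused"])
        assert np.allclose(boxes_a, boxes_b)
        assert not np.allclose(scores_a, scores_b)

    def test_checkpoint_round_trip(self, tmp_path, default_bank, image):
        det = TinyDetector(bank=default_bank, seed=3)
        path = tmp_path / "weights.npz"
        det.save(path)
        det2 = TinyDetector(bank=default_bank, seed=99)
        det2.load(path)
        a, b = det.predict(image), det2.predict(image)
        assert len(a) == len(b)
        for da, db_ in zip(a, b):
            assert da.box == db_.box

    def test_analytic_gradients_match_finite_differences(self, default_bank):
        """Backprop of the full training loss checked against FD."""
        rng = np.random.default_rng(7)
        det = TinyDetector(bank=default_bank, seed=11)
        img01 = rng.random((144, 192, 3))
        gts = [
            (Box(40.0, 40.0, 80.0, 90.0), 0),
            (Box(120.0, 60.0, 150.0, 100.0), 1),
        ]
        cache = det._forward_features(img01)
        _, _, _, _, scores, boxes = det._heads(cache["fused"])
        frozen = det._compute_targets(scores, boxes, gts)
        loss0, grads = det._image_loss_and_grads(img01, gts, frozen=frozen)
        assert np.isfinite(loss0)
        eps = 1e-5
        keys = (
            "w_emb", "b_emb", "tau", "bias_cls", "w_box", "b_box",
            "edc_b_out", "edc_w_out", "edc_b_hidden", "fusion_raw",
        )
        for key in keys:
            flat = det.params[key].ravel()
            gflat = grads[key].ravel()
            idxs = rng.choice(flat.size, size=min(4, flat.size), replace=False)
            for idx in idxs:
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _ = det._image_loss_and_grads(img01, gts, frozen=frozen)
                flat[idx] = orig - eps
                lm, _ = det._image_loss_and_grads(img01, gts, frozen=frozen)
                flat[idx] = orig
                fd = (lp - lm) / (2 * eps)
                if key in ("w_box", "b_box"):
                    # the box loss gradient is itself a 0.01-px central
                    # difference; decode clipping kinks limit agreement
                    assert gflat[idx] == pytest.approx(fd, abs=1e-3, rel=0.1), key
                else:
                    assert gflat[idx] == pytest.approx(fd, abs=2e-4, rel=0.02), key
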
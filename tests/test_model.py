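"""Network contracts: backbone shapes, proposals, heads, losses, training."""

import numpy as np
import pytest

import pointcell as pc
from pointcell import nn
from pointcell.model import (
    PointCellModel,
    mask_target,
    point_labels,
    scene_losses,
    tight_box,
)
from pointcell.sampling import Box, PointSet

TINY = pc.ModelConfig(widths=(4, 8, 16, 32), fpn_width=8, seed=3, epochs=2)


@pytest.fixture(scope="module")
def model():
    return PointCellModel(TINY)


class TestBackbone:
    def test_stride_arithmetic(self, model):
        pyr = model.backbone(np.zeros((128, 128)))
        assert pyr["P2"].data.shape[1:] == (32, 32)
        assert pyr["P5"].data.shape[1:] == (4, 4)
        pyr2 = model.backbone(np.zeros((256, 256)))
        assert pyr2["P2"].data.shape[1:] == (64, 64)

    def test_deterministic_forward(self, model, rng):
        img = rng.uniform(size=(64, 64))
        a = model.backbone(img)["P3"].data
        b = model.backbone(img)["P3"].data
        np.testing.assert_array_equal(a, b)

    def test_indivisible_input_padded(self, model):
        pyr = model.backbone(np.zeros((100, 100)))
        assert pyr["P2"].data.shape[1:] == (32, 32)  # padded up to 128


class TestPropose:
    def test_tight_box_half_open_convention(self):
        m = np.zeros((64, 64), bool)
        m[10:20, 20:40] = True  # rows 10-19, cols 20-39
        b = tight_box(m)
        assert (b.x1, b.y1, b.x2, b.y2) == (20.0, 10.0, 40.0, 20.0)

    def test_zero_jitter_returns_exact_tight_boxes(self, small_scene):
        _, masks, _ = small_scene
        cfg = pc.ModelConfig(box_jitter=0.0)
        boxes = pc.propose(np.zeros(masks.shape), masks, cfg, rng=np.random.default_rng(0))
        for b, m in zip(boxes, masks.masks):
            assert b.as_array() == pytest.approx(tight_box(m).as_array())

    def test_empty_scene_empty_proposals(self):
        cfg = pc.ModelConfig()
        assert pc.propose(np.zeros((64, 64)), None, cfg) == []

    def test_jitter_bounded_and_seeded(self, small_scene):
        _, masks, _ = small_scene
        cfg = pc.ModelConfig(box_jitter=0.1)
        b1 = pc.propose(np.zeros(masks.shape), masks, cfg, rng=np.random.default_rng(5))
        b2 = pc.propose(np.zeros(masks.shape), masks, cfg, rng=np.random.default_rng(5))
        for a, b, m in zip(b1, b2, masks.masks):
            assert a.as_array() == pytest.approx(b.as_array())
            t = tight_box(m)
            assert abs(a.x1 - t.x1) <= 0.1 * t.width + 1e-9
            assert abs(a.y2 - t.y2) <= 0.1 * t.height + 1e-9


class TestMaskHead:
    def test_output_is_28x28(self, model, rng):
        pyr = model.backbone(rng.uniform(size=(64, 64)))
        roi = model.roi_feature(pyr, Box(10, 10, 40, 40))
        logits, coarse = model.mask_head(roi, Box(10, 10, 40, 40))
        assert logits.data.shape == (1, 28, 28)
        assert coarse.probs.shape == (28, 28)

    def test_zero_final_layer_gives_half_probs(self, rng):
        m = PointCellModel(TINY)
        m.mask_logit.weight.data[:] = 0.0
        m.mask_logit.bias.data[:] = 0.0
        pyr = m.backbone(rng.uniform(size=(64, 64)))
        roi = m.roi_feature(pyr, Box(5, 5, 30, 30))
        _, coarse = m.mask_head(roi, Box(5, 5, 30, 30))
        np.testing.assert_allclose(coarse.probs, 0.5)

    def test_scaling_logits_pushes_probs_from_half(self, model, rng):
        pyr = model.backbone(rng.uniform(size=(64, 64)))
        box = Box(8, 8, 36, 36)
        roi = model.roi_feature(pyr, box)
        logits, _ = model.mask_head(roi, box)
        p1 = nn.sigmoid(logits.data)
        p2 = nn.sigmoid(2.0 * logits.data)
        assert np.all(np.abs(p2 - 0.5) >= np.abs(p1 - 0.5) - 1e-12)

    def test_wrong_roi_size_rejected(self, model):
        with pytest.raises(ValueError):
            model.mask_head(nn.Tensor(np.zeros((8, 5, 5))), Box(0, 0, 10, 10))

    def test_mask_out_must_be_four_times_roi_out(self):
        with pytest.raises(ValueError, match="mask_out"):
            pc.ModelConfig(mask_out=21, roi_out=7)


class TestPointHead:
    def test_zero_final_layer_gives_half_probs(self, rng):
        m = PointCellModel(TINY)
        m.point_logit.weight.data[:] = 0.0
        m.point_logit.bias.data[:] = 0.0
        x = nn.Tensor(rng.normal(size=(10, 2 * TINY.fpn_width)))
        probs = nn.sigmoid(m.point_head(x).data)
        np.testing.assert_allclose(probs, 0.5)

    def test_pointwise_permutation_equivariance(self, model, rng):
        x = rng.normal(size=(12, 2 * TINY.fpn_width))
        perm = rng.permutation(12)
        out = model.point_head(nn.Tensor(x)).data
        out_p = model.point_head(nn.Tensor(x[perm])).data
        np.testing.assert_allclose(out_p, out[perm], atol=1e-12)

    def test_identity_extra_layer_matches_shallower_head(self, rng):
        """alpha=3 with the middle layer set to identity reproduces alpha=2.

        Valid because point features pass through ReLU: an identity layer
        on nonnegative activations is a no-op.
        """
        cfg2 = pc.ModelConfig(widths=TINY.widths, fpn_width=8, alpha=2, seed=11)
        cfg3 = pc.ModelConfig(widths=TINY.widths, fpn_width=8, alpha=3, seed=11)
        m2, m3 = PointCellModel(cfg2), PointCellModel(cfg3)
        # copy layer 0 and final; make layer 1 of m3 the identity; map m3
        # layer 2 from m2 layer 1
        w = cfg3.point_head_width
        m3.point_layers[0].weight.data = m2.point_layers[0].weight.data.copy()
        m3.point_layers[0].bias.data = m2.point_layers[0].bias.data.copy()
        m3.point_layers[1].weight.data = np.eye(w)
        m3.point_layers[1].bias.data = np.zeros(w)
        m3.point_layers[2].weight.data = m2.point_layers[1].weight.data.copy()
        m3.point_layers[2].bias.data = m2.point_layers[1].bias.data.copy()
        m3.point_logit.weight.data = m2.point_logit.weight.data.copy()
        m3.point_logit.bias.data = m2.point_logit.bias.data.copy()
        x = nn.Tensor(rng.normal(size=(9, 16)))
        np.testing.assert_allclose(m3.point_head(x).data, m2.point_head(x).data, atol=1e-12)

    def test_alpha_outside_supported_set_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            pc.ModelConfig(alpha=5)


class TestTargetsAndLosses:
    def test_mask_target_is_binary_28x28(self, small_scene):
        _, masks, _ = small_scene
        t = mask_target(masks.masks[0], tight_box(masks.masks[0]))
        assert t.shape == (28, 28)
        assert set(np.unique(t)) <= {0.0, 1.0}
        assert t.sum() > 0

    def test_point_labels_nearest_pixel(self):
        m = np.zeros((8, 8))
        m[0:4, 0:4] = 1.0
        box = Box(0, 0, 8, 8)
        pts = PointSet(np.array([[0.2, 0.2], [0.9, 0.9]]), "normalized")
        np.testing.assert_array_equal(point_labels(m, box, pts), [1.0, 0.0])

    def test_point_loss_examples(self):
        assert pc.point_loss(np.full(4, 20.0), np.ones(4)) < 1e-6
        assert pc.point_loss(np.zeros(1), np.ones(1)) == pytest.approx(np.log(2))
        assert pc.point_loss(np.zeros(2), np.array([0.0, 1.0])) == pytest.approx(np.log(2))

    def test_total_loss_is_exact_sum(self):
        lb = pc.total_loss(1.0, 2.0, 3.0, 4.0)
        assert lb.total == 10.0
        assert pc.total_loss(0, 0, 0, 0).total == 0.0
        with pytest.raises(FloatingPointError):
            pc.total_loss(np.nan, 0, 0, 0)

    def test_scene_loss_breakdown_identity(self, small_scene):
        img, masks, _ = small_scene
        m = PointCellModel(TINY)
        _, lb = scene_losses(m, img, masks, np.random.default_rng(0))
        assert lb.total == lb.mask + lb.point + lb.box + lb.cls


class TestTraining:
    def test_loss_decreases_on_tiny_dataset(self, ci_train_scenes):
        cfg = pc.ModelConfig(widths=(4, 8, 16, 32), fpn_width=8, epochs=12,
                             beta_train=64, seed=2)
        res = pc.train(ci_train_scenes[:10], cfg, log_every=0)
        first = np.mean([c.total for c in res.curves[:3]])
        last = np.mean([c.total for c in res.curves[-3:]])
        assert last < first

    def test_zero_epochs_checkpoint_equals_init(self, ci_train_scenes, tmp_path):
        cfg = pc.ModelConfig(widths=(4, 8, 16, 32), fpn_width=8, epochs=0, seed=4)
        res = pc.train(ci_train_scenes[:4], cfg, log_every=0)
        init = PointCellModel(cfg)
        for (n1, p1), (n2, p2) in zip(res.model.named_params(), init.named_params()):
            assert n1 == n2
            np.testing.assert_array_equal(p1.data, p2.data)

    def test_same_seed_identical_curves(self, ci_train_scenes):
        cfg = pc.ModelConfig(widths=(4, 8, 16, 32), fpn_width=8, epochs=3,
                             beta_train=32, seed=6)
        r1 = pc.train(ci_train_scenes[:6], cfg, log_every=0)
        r2 = pc.train(ci_train_scenes[:6], cfg, log_every=0)
        assert [c.total for c in r1.curves] == [c.total for c in r2.curves]

    def test_needs_two_scenes(self, ci_train_scenes):
        with pytest.raises(ValueError):
            pc.train(ci_train_scenes[:1], TINY)


class TestCheckpoint:
    def test_round_trip_preserves_weights_and_config(self, ci_train_scenes, tmp_path):
        cfg = pc.ModelConfig(widths=(4, 8, 16, 32), fpn_width=8, epochs=1,
                             beta_train=16, seed=8)
        res = pc.train(ci_train_scenes[:4], cfg, log_every=0)
        path = tmp_path / "ckpt.npz"
        pc.save_checkpoint(path, res)
        loaded = pc.load_checkpoint(path)
        assert loaded.config == cfg
        for (_, p1), (_, p2) in zip(res.model.named_params(), loaded.model.named_params()):
            np.testing.assert_array_equal(p1.data, p2.data)
        assert [c.total for c in loaded.curves] == [c.total for c in res.curves]

    def test_version_mismatch_rejected(self, tmp_path):
        import json

        meta = {"config": {}, "version": 999, "curves": []}
        np.savez(tmp_path / "bad.npz", __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8))
        with pytest.raises(ValueError, match="version"):
            pc.load_checkpoint(tmp_path / "bad.npz")


class TestRpn:
    def test_rpn_proposals_are_valid_scored_boxes(self, rng):
        cfg = pc.ModelConfig(widths=(4, 8, 16, 32), fpn_width=8,
                             proposal_mode="learned_rpn", score_threshold=0.0, seed=1)
        m = PointCellModel(cfg)
        props = m.rpn_propose(rng.uniform(size=(64, 64)))
        assert len(props) > 0
        for b, s in props:
            assert 0.0 <= s <= 1.0 and b.area > 0
        # NMS: no two kept boxes overlap above the IoU threshold
        from pointcell.model import _box_iou

        for i, (bi, _) in enumerate(props):
            for bj, _ in props[i + 1 :]:
                assert _box_iou(bi, bj) < cfg.nms_iou

    def test_learned_rpn_training_step_runs(self, ci_train_scenes):
        cfg = pc.ModelConfig(widths=(4, 8, 16, 32), fpn_width=8, epochs=1,
                             beta_train=16, proposal_mode="learned_rpn", seed=9)
        res = pc.train(ci_train_scenes[:4], cfg, log_every=0)
        assert np.isfinite(res.curves[0].total)
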
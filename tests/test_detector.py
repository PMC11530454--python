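import numpy as np
import pytest

from stainshift.datamodel import LabelSet
from stainshift.detector import (DetectorConfig, EarlyStopper, FCOSModel,
                                 FusionBlock, augment, augment_pair,
                                 centerness_target, fuse_features, model_summary,
                                 points_to_boxes, rotate_points,
                                 sample_training_patches, train_detector,
                                 _fcos_targets)
from stainshift.nn import Tensor, count_parameters


def tiny_model(mode="single", seed=0, **kw):
    cfg = DetectorConfig(mode=mode, backbone="tiny", patch_size=128,
                         box_size_px=32, seed=seed, **kw)
    return FCOSModel(cfg, rng=np.random.default_rng(seed)), cfg


class TestBackboneContract:
    def test_incompatible_size_names_divisibility(self):
        model, _ = tiny_model()
        x = Tensor(np.zeros((1, 3, 100, 100), dtype=np.float32))
        with pytest.raises(ValueError, match="divisible"):
            model.backbone_forward(x)

    def test_three_levels_with_halving_sizes(self, rng):
        model, _ = tiny_model()
        x = Tensor(rng.normal(size=(1, 3, 128, 128)).astype(np.float32))
        maps = model.backbone_forward(x)
        sizes = [m.shape[2] for m in maps]
        assert sizes == [32, 16, 8]


class TestFusion:
    def _maps(self, rng, c=16, hw=16, n=2):
        a = Tensor(rng.normal(size=(n, c, hw, hw)).astype(np.float32))
        b = Tensor(rng.normal(size=(n, c, hw, hw)).astype(np.float32))
        return a, b

    def test_output_channels_halved_back_and_nonnegative(self, rng):
        fb = FusionBlock(16, rng=np.random.default_rng(1))
        a, b = self._maps(rng)
        out = fb(a, b)
        assert out.shape == a.shape
        assert (out.data >= 0).all()

    def test_order_sensitivity(self, rng):
        fb = FusionBlock(16, rng=np.random.default_rng(1))
        a, b = self._maps(rng)
        assert not np.allclose(fb(a, b).data, fb(b, a).data)

    def test_deterministic_forward(self, rng):
        fb = FusionBlock(16, rng=np.random.default_rng(1))
        a, b = self._maps(rng)
        np.testing.assert_array_equal(fb(a, b).data, fb(a, b).data)

    def test_shape_mismatch_rejected(self, rng):
        fb = FusionBlock(16, rng=np.random.default_rng(1))
        a, _ = self._maps(rng)
        b_small = Tensor(np.zeros((2, 16, 8, 8), dtype=np.float32))
        with pytest.raises(ValueError, match="shapes differ"):
            fb(a, b_small)

    def test_per_level_fusion_through_model(self, rng):
        model, _ = tiny_model(mode="dual")
        he = Tensor(rng.normal(size=(1, 3, 128, 128)).astype(np.float32))
        ph = Tensor(rng.normal(size=(1, 3, 128, 128)).astype(np.float32))
        hmaps = model.backbone_forward(he, "he")
        pmaps = model.backbone_forward(ph, "phh3")
        fused = fuse_features(model.fusion, hmaps, pmaps)
        for f, h in zip(fused, hmaps):
            assert f.shape == h.shape
            assert (f.data >= 0).all()


class TestTargetsAndBoxes:
    def test_centerness_is_one_at_box_center(self):
        assert centerness_target(16, 16, 16, 16) == pytest.approx(1.0)
        assert centerness_target(4, 16, 28, 16) == pytest.approx(
            np.sqrt((4 / 28) * 1.0))

    def test_encode_decode_recovers_box_at_center(self):
        # a box whose centre falls exactly on a stride-4 location
        box = np.array([[50.0, 30.0, 82.0, 62.0]])  # centre (66, 46), side 32
        t_cls, t_ctr, t_reg = _fcos_targets([box], 32, 32, 4, 0.0, 32.0)
        iy, ix = 11, 16  # location centre (66.0, 46.0)
        assert t_cls[0, iy, ix] == 1.0
        left, top, right, bottom = t_reg[0, iy, ix]
        cx, cy = ix * 4 + 2.0, iy * 4 + 2.0
        np.testing.assert_allclose(
            [cx - left, cy - top, cx + right, cy + bottom], box[0])
        assert t_ctr[0, iy, ix] == pytest.approx(
            centerness_target(left, top, right, bottom))

    def test_points_to_boxes_examples(self):
        b = points_to_boxes([(100.0, 100.0)], 50)
        np.testing.assert_allclose(b[0], (75, 75, 125, 125))
        corner = points_to_boxes([(0.0, 0.0)], 50, image_size=(512, 512))[0]
        assert corner[2] > corner[0] and corner[3] > corner[1]
        assert corner[0] == 0 and corner[1] == 0
        # round trip away from borders
        x0, y0, x1, y1 = points_to_boxes([(64.0, 80.0)], 40,
                                         image_size=(512, 512))[0]
        assert ((x0 + x1) / 2, (y0 + y1) / 2) == (64.0, 80.0)


class TestPatchSampling:
    def _images(self, small_study):
        study, label_sets, _ = small_study
        return study.images, label_sets["he_only_labels"]

    def test_positive_fraction_at_least_half(self, small_study):
        images, labels = self._images(small_study)
        cfg = DetectorConfig(patch_size=128, mf_patch_fraction=0.5)
        rng = np.random.default_rng(0)
        gen = sample_training_patches(images, labels, cfg, rng, n_patches=400)
        n_pos = sum(1 for s in gen if s["points"])
        se = np.sqrt(0.25 / 400)
        assert n_pos / 400 >= 0.5 - 3 * se

    def test_label_free_image_never_positive(self, small_study):
        images, _ = self._images(small_study)
        empty = LabelSet("he_only_labels", {im.image_id: [] for im in images})
        empty.points[images[0].image_id] = [(100.0, 100.0, 6)]
        cfg = DetectorConfig(patch_size=128, mf_patch_fraction=1.0)
        gen = sample_training_patches(images, empty, cfg,
                                      np.random.default_rng(1), n_patches=50)
        assert all(s["image_id"] == images[0].image_id for s in gen)

    def test_fixed_seed_reproducible(self, small_study):
        images, labels = self._images(small_study)
        cfg = DetectorConfig(patch_size=128)
        a = [s["origin"] for s in sample_training_patches(
            images, labels, cfg, np.random.default_rng(5), n_patches=30)]
        b = [s["origin"] for s in sample_training_patches(
            images, labels, cfg, np.random.default_rng(5), n_patches=30)]
        assert a == b


class TestAugmentation:
    def test_zero_probabilities_identity(self, rng):
        cfg = DetectorConfig(aug_color_p=0, aug_blur_p=0, aug_drop_p=0,
                             aug_rot_p=0)
        patch = (rng.random((64, 64, 3)) * 255).astype(np.uint8)
        out = augment(patch, rng, config=cfg)
        np.testing.assert_array_equal(out, patch.astype(np.float32))

    def test_rotation_consistency_of_points(self, rng):
        patch = np.zeros((64, 64, 3), dtype=np.float32)
        patch[10, 20] = 255.0  # a single bright pixel at (x=20, y=10)
        for k in range(4):
            rot = np.rot90(patch, k=k, axes=(0, 1))
            (px, py), = rotate_points([(20, 10)], k, 64)
            assert rot[int(py), int(px), 0] == 255.0

    def test_pixel_drop_rate(self, rng):
        cfg = DetectorConfig(aug_color_p=0, aug_blur_p=0, aug_drop_p=1.0,
                             aug_drop_rate=0.1, aug_rot_p=0)
        patch = np.full((128, 128, 3), 200, dtype=np.uint8)
        out = augment(patch, rng, config=cfg)
        frac = (out == 0).all(axis=2).mean()
        assert abs(frac - 0.1) < 3 * np.sqrt(0.1 * 0.9 / 128 ** 2) + 0.01

    def test_dual_mode_spatial_sync_color_independent(self, rng):
        cfg = DetectorConfig(aug_color_p=1.0, aug_blur_p=0, aug_drop_p=0,
                             aug_rot_p=1.0)
        he = (rng.random((64, 64, 3)) * 255).astype(np.uint8)
        he[5, 7] = 255
        phh3 = he.copy()
        pts = [(7, 5)]
        he_a, ph_a, pts_a = augment_pair(he, phh3, pts, rng, cfg)
        # same spatial transform: the marker pixel is the maximum of both
        assert np.unravel_index(he_a.sum(2).argmax(), (64, 64)) == \
            np.unravel_index(ph_a.sum(2).argmax(), (64, 64))
        # independent color transforms: images differ even from a shared source
        assert not np.allclose(he_a, ph_a)


class TestEarlyStopping:
    def test_worsening_scores_stop_after_patience_plus_one(self):
        stopper = EarlyStopper(patience=5)
        scores = [0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2]
        n = 0
        for s in scores:
            n += 1
            if stopper.update(s):
                break
        assert n == 6  # the best evaluation plus 5 non-improving ones

    def test_improvement_resets_patience(self):
        stopper = EarlyStopper(patience=2)
        assert not stopper.update(0.5)
        assert not stopper.update(0.4)
        assert not stopper.update(0.6)  # new best
        assert not stopper.update(0.5)
        assert stopper.update(0.5)


class TestTraining:
    def test_empty_labels_refused(self, small_study):
        study, label_sets, splits = small_study
        empty = LabelSet("he_only_labels",
                         {im.image_id: [] for im in study.images})
        cfg = DetectorConfig(mode="single", backbone="tiny", patch_size=128)
        with pytest.raises(ValueError, match="empty training labels"):
            train_detector(cfg, splits[0], empty, study.images)

    def test_history_and_best_checkpoint(self, trained_tiny):
        model, history = trained_tiny
        assert len(history) >= 1
        assert model.best_val_ap == pytest.approx(max(history))
        # learning happened: the best validation AP is well above chance
        assert max(history) > 0.3

    def test_pretrained_weights_not_bundled(self):
        with pytest.raises(ValueError, match="pretrained"):
            FCOSModel(DetectorConfig(mode="single", backbone="tiny",
                                     patch_size=128, pretrained=True))

    def test_dual_forward_requires_phh3(self, rng):
        model, _ = tiny_model(mode="dual")
        x = Tensor(rng.normal(size=(1, 3, 128, 128)).astype(np.float32))
        with pytest.raises(ValueError, match="PHH3"):
            model.forward(x, None)


class TestParameterAccounting:
    def test_ordering_single18_dual18_single101(self):
        rng = np.random.default_rng(0)
        common = dict(patch_size=512, fpn_channels=256)
        single18 = FCOSModel(DetectorConfig(mode="single", backbone="resnet18",
                                            **common), rng=rng)
        n_single18 = count_parameters(single18)
        dual18 = FCOSModel(DetectorConfig(mode="dual", backbone="resnet18",
                                          **common), rng=rng)
        n_dual18 = count_parameters(dual18)
        del single18, dual18
        single101 = FCOSModel(DetectorConfig(mode="single", backbone="resnet101",
                                             **common), rng=rng)
        n_single101 = count_parameters(single101)
        assert n_single18 < n_dual18 < n_single101

    def test_summary_parts_add_up(self):
        model, _ = tiny_model(mode="dual")
        s = model_summary(model)
        assert s["total"] == sum(s["parts"].values())
        assert set(s["parts"]) == {"backbone_he", "backbone_phh3", "fusion",
                                   "pyramid_and_heads"}
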
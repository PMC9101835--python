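import math

import numpy as np
import pytest

from dsanet.segnet import (
    SegLossWeights, SegModel, SegModelConfig, build_model, combined_bce_dice,
    loss_ltd, loss_total, make_folds, predict_segmentation, train_segmentation,
)
from dsanet.preprocess import KeyFrameBundle


def _l1_loop_oracle(a, b):
    total = 0.0
    for x, y in zip(a.flat, b.flat):
        total += abs(x - y)
    return total / a.size


def _bce_dice_loop_oracle(p, g, a, eps=1e-7, smooth=1.0):
    bce = 0.0
    inter = psum = gsum = 0.0
    for pi, gi in zip(p.flat, g.flat):
        pc = min(max(pi, eps), 1 - eps)
        bce += -(gi * math.log(pc) + (1 - gi) * math.log(1 - pc))
        inter += pc * gi
        psum += pc
        gsum += gi
    bce /= p.size
    dice = (2 * inter + smooth) / (psum + gsum + smooth)
    return a * bce + (1 - a) * (1 - dice)


class TestLossLtd:
    def test_identity(self):
        x = np.random.default_rng(0).random((8, 8))
        assert loss_ltd(x, x) == 0.0

    def test_constant_offset(self):
        assert loss_ltd(np.full((4, 4), 0.5), np.zeros((4, 4))) == pytest.approx(0.5)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((8, 8)), rng.random((8, 8))
        assert loss_ltd(a, b) == pytest.approx(_l1_loop_oracle(a, b), abs=1e-6)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            loss_ltd(np.zeros((4, 4)), np.zeros((4, 5)))


class TestCombinedBceDice:
    def test_perfect_prediction_near_zero(self):
        g = (np.random.default_rng(0).random((16, 16)) < 0.4).astype(float)
        assert combined_bce_dice(g, g, a=0.5) < 1e-5 + 0.5 * (
            1 - (2 * g.sum() + 1) / (2 * g.sum() + 1))  # dice term exact 0
        assert combined_bce_dice(g, g, a=0.5) == pytest.approx(0.0, abs=1e-5)

    def test_half_probability_closed_form(self):
        p = np.full((16, 16), 0.5)
        g = np.ones((16, 16))
        # 256 px: BCE = ln 2; soft dice = (2*128 + 1)/(128 + 256 + 1)
        expected = 0.5 * math.log(2) + 0.5 * (1 - (2 * 128 + 1) / (128 + 256 + 1))
        assert combined_bce_dice(p, g, a=0.5) == pytest.approx(expected, abs=1e-9)

    def test_a_one_is_pure_bce(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.05, 0.95, (8, 8))
        g = (rng.random((8, 8)) < 0.5).astype(float)
        bce = -np.mean(g * np.log(p) + (1 - g) * np.log(1 - p))
        assert combined_bce_dice(p, g, a=1.0) == pytest.approx(bce, rel=1e-6)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        for shape in [(8, 8), (16, 16), (32, 32)]:
            p = rng.uniform(0, 1, shape)
            g = (rng.random(shape) < 0.3).astype(float)
            for a in (0.0, 0.5, 1.0):
                assert combined_bce_dice(p, g, a) == pytest.approx(
                    _bce_dice_loop_oracle(p, g, a), abs=1e-6)

    def test_non_binary_target_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            combined_bce_dice(np.full((4, 4), 0.5), np.full((4, 4), 0.3))

    def test_nonnegative(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            p = rng.uniform(0, 1, (6, 6))
            g = (rng.random((6, 6)) < 0.5).astype(float)
            assert combined_bce_dice(p, g, a=rng.random()) >= 0.0


class TestLossTotal:
    def test_default_weights_arithmetic(self):
        assert loss_total(0.2, 0.3, 0.4) == pytest.approx(0.72)

    def test_zero_weights(self):
        w = SegLossWeights(a=0.5, lambda0=0.0, lambda1=0.0)
        assert loss_total(0.9, 0.8, 0.7, w) == pytest.approx(0.7)

    def test_all_zero(self):
        assert loss_total(0.0, 0.0, 0.0) == 0.0

    def test_linearity(self):
        w = SegLossWeights()
        rng = np.random.default_rng(0)
        for _ in range(10):
            a, b, c = rng.random(3)
            s = rng.uniform(0.5, 2.0)
            assert loss_total(s * a, s * b, s * c, w) == pytest.approx(
                s * loss_total(a, b, c, w))

    def test_invalid_weights(self):
        with pytest.raises(ValueError):
            SegLossWeights(a=1.5)
        with pytest.raises(ValueError):
            SegLossWeights(lambda0=-0.1)


def _tiny_cfg(variant, **kw):
    defaults = dict(variant=variant, base_channels=4, unet_depth=2,
                    image_size=16, epochs=2, seed=0)
    defaults.update(kw)
    return SegModelConfig(**defaults)


def _rand_bundle(rng, size=16):
    frames = rng.random((12, size, size)).astype(np.float32)
    from dsanet.preprocess import build_key_frame_bundle
    return build_key_frame_bundle(frames, 8)


class TestBuildModel:
    def test_ffs_forward_contract(self):
        rng = np.random.default_rng(0)
        model = build_model(_tiny_cfg("ffs"))
        model.trained = True
        out = predict_segmentation(model, _rand_bundle(rng))
        assert out.tumor_prob.shape == (16, 16)
        assert 0.0 <= out.tumor_prob.min() and out.tumor_prob.max() <= 1.0
        assert out.liver_prob is not None and out.ltd_map is not None
        assert set(np.unique(out.tumor_mask)) <= {0, 1}

    def test_baseline_has_no_aux_maps(self):
        rng = np.random.default_rng(1)
        model = build_model(_tiny_cfg("baseline"))
        model.trained = True
        out = predict_segmentation(model, _rand_bundle(rng))
        assert out.liver_prob is None and out.ltd_map is None
        assert out.liver_mask is None

    def test_same_seed_identical_params(self):
        a = build_model(_tiny_cfg("ffs", seed=3))
        b = build_model(_tiny_cfg("ffs", seed=3))
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.v, pb.v)

    def test_invalid_variant(self):
        with pytest.raises(ValueError, match="variant"):
            SegModelConfig(variant="nope")

    def test_untrained_predict_rejected(self):
        model = build_model(_tiny_cfg("baseline"))
        with pytest.raises(RuntimeError, match="trained"):
            predict_segmentation(model, _rand_bundle(np.random.default_rng(0)))

    def test_size_mismatch_rejected(self):
        model = build_model(_tiny_cfg("baseline"))
        model.trained = True
        with pytest.raises(ValueError, match="size"):
            predict_segmentation(model, _rand_bundle(np.random.default_rng(0),
                                                     size=32))

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        model = build_model(_tiny_cfg("ffs"))
        model.trained = True
        bundle = _rand_bundle(rng)
        before = predict_segmentation(model, bundle)
        model.save(tmp_path / "ckpt")
        loaded = SegModel.load(tmp_path / "ckpt")
        after = predict_segmentation(loaded, bundle)
        np.testing.assert_array_equal(before.tumor_prob, after.tumor_prob)


class TestPredictDeterminism:
    def test_same_bundle_twice(self):
        rng = np.random.default_rng(0)
        model = build_model(_tiny_cfg("ffs"))
        model.trained = True
        b = _rand_bundle(rng)
        o1, o2 = predict_segmentation(model, b), predict_segmentation(model, b)
        np.testing.assert_array_equal(o1.tumor_prob, o2.tumor_prob)

    def test_all_zero_input(self):
        model = build_model(_tiny_cfg("ffs"))
        model.trained = True
        frames = np.zeros((12, 16, 16), dtype=np.float32)
        from dsanet.preprocess import build_key_frame_bundle
        out = predict_segmentation(model, build_key_frame_bundle(frames, 8))
        assert np.isfinite(out.tumor_prob).all()
        assert 0.0 <= out.tumor_prob.min() and out.tumor_prob.max() <= 1.0


class TestFolds:
    def test_partition_property(self):
        folds = make_folds(40, 5, seed=0)
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == list(range(40))
        assert len(all_idx) == len(set(all_idx))

    def test_too_few_patients(self):
        with pytest.raises(ValueError):
            make_folds(3, 5, seed=0)


@pytest.fixture(scope="module")
def trained_tiny(easy_seg_dataset_10):
    cfg = SegModelConfig(variant="ffs", base_channels=8, unet_depth=3,
                         image_size=64, epochs=3, seed=0)
    models, cv = train_segmentation(easy_seg_dataset_10, cfg, folds=5)
    return models, cv, easy_seg_dataset_10


class TestTraining:
    def test_loss_decreases_and_each_patient_validated_once(self, trained_tiny):
        models, cv, dataset = trained_tiny
        assert len(models) == 5
        assert sorted(cv["patient_id"]) == sorted(d["patient_id"] for d in dataset)
        assert cv.groupby("patient_id").size().max() == 1
        by_fold = cv.drop_duplicates("fold")
        assert (by_fold["final_epoch_loss"] < by_fold["first_epoch_loss"]).all()

    def test_learns_overlap(self, trained_tiny):
        models, cv, dataset = trained_tiny
        entry = dataset[0]
        fold = int(cv.set_index("patient_id").loc[entry["patient_id"], "fold"])
        out = predict_segmentation(models[fold], entry["bundle"])
        from dsanet.evalstats import dice_coefficient
        assert dice_coefficient(out.tumor_mask, entry["tumor_mask"]) > 0.0

    def test_deterministic_rerun(self, easy_seg_dataset_10):
        cfg = SegModelConfig(variant="baseline", base_channels=4, unet_depth=2,
                             image_size=64, epochs=1, seed=1)
        _, cv1 = train_segmentation(easy_seg_dataset_10, cfg, folds=5)
        _, cv2 = train_segmentation(easy_seg_dataset_10, cfg, folds=5)
        assert cv1.equals(cv2)

    def test_too_few_patients(self, easy_seg_dataset_10):
        cfg = SegModelConfig(variant="baseline", image_size=64, epochs=1)
        with pytest.raises(ValueError):
            train_segmentation(easy_seg_dataset_10[:3], cfg, folds=5)
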
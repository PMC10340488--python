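"""U-Net architecture, Mish, Unified Focal Loss, and training-harness tests."""

import numpy as np
import pytest

from leukoseg import (AugmentPolicy, FoldPlan, LossParams, TrainConfig,
                      UNetSpec, build_unet, evaluate, make_smear_batch, mish,
                      predict_mask, train_crossval, train_unet,
                      unified_focal_loss)
from leukoseg.deepseg import unified_focal_loss_tensor
from leukoseg.exceptions import ConfigError, DimensionError, ModelError
from leukoseg import nn

TINY_SPEC = UNetSpec(channels_per_level=(2, 3, 4, 5, 6), dropout_p=0.0)


class TestMish:
    def test_point_values(self):
        assert mish(0.0) == 0.0
        assert mish(30.0) == pytest.approx(30.0, abs=1e-6)   # identity asymptote
        assert mish(1.0) == pytest.approx(0.865098388267, abs=1e-9)

    def test_lower_bound_and_asymptotes(self):
        x = np.linspace(-50, 50, 10001)
        y = mish(x)
        assert np.all(y >= -0.31)
        assert abs(mish(-40.0)) < 1e-12                       # -> 0 as x -> -inf
        assert mish(100.0) / 100.0 == pytest.approx(1.0, abs=1e-12)

    def test_continuity_on_fine_grid(self):
        x = np.linspace(-5, 5, 100001)
        y = mish(x)
        assert np.max(np.abs(np.diff(y))) < 2.1 * (x[1] - x[0])  # slope bounded


class TestUnifiedFocalLoss:
    GT = np.array([[1.0, 0.0], [0.0, 0.0]])
    PRED = np.array([[0.9, 0.1], [0.2, 0.1]])
    PARAMS = LossParams(delta=0.6, gamma=0.5, lam=0.5)

    def test_perfect_hard_prediction_is_zero(self, rng):
        gt = (rng.random((6, 6)) < 0.5).astype(float)
        assert unified_focal_loss(gt, gt) == pytest.approx(0.0, abs=1e-6)

    def test_hand_computed_toy_oracle(self):
        # frozen from an exact rational evaluation of the focal and Tversky
        # terms on this 2x2 example
        loss = unified_focal_loss(self.PRED, self.GT, self.PARAMS)
        assert loss == pytest.approx(0.392484700576, abs=1e-9)

    def test_lambda_endpoints(self):
        focal_only = unified_focal_loss(self.PRED, self.GT,
                                        LossParams(0.6, 0.5, lam=1.0))
        tversky_only = unified_focal_loss(self.PRED, self.GT,
                                          LossParams(0.6, 0.5, lam=0.0))
        assert focal_only == pytest.approx(0.0299619887062, abs=1e-9)
        assert tversky_only == pytest.approx(0.755007412445, abs=1e-9)

    def test_affine_in_lambda(self):
        l0 = unified_focal_loss(self.PRED, self.GT, LossParams(0.6, 0.5, 0.0))
        l1 = unified_focal_loss(self.PRED, self.GT, LossParams(0.6, 0.5, 1.0))
        for lam in (0.25, 0.5, 0.8):
            mixed = unified_focal_loss(self.PRED, self.GT,
                                       LossParams(0.6, 0.5, lam))
            assert mixed == pytest.approx(lam * l1 + (1 - lam) * l0, abs=1e-12)

    def test_loss_decreases_toward_target(self, rng):
        gt = (rng.random((8, 8)) < 0.5).astype(float)
        pred = np.clip(rng.random((8, 8)), 0.05, 0.95)
        losses = [unified_focal_loss(t * gt + (1 - t) * pred, gt)
                  for t in np.linspace(0, 0.99, 8)]
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_param_validation(self):
        with pytest.raises(ConfigError):
            LossParams(delta=1.5)
        with pytest.raises(ConfigError):
            LossParams(gamma=-0.1)
        with pytest.raises(ConfigError):
            LossParams(lam=2.0)

    def test_conventional_exponent_flag(self):
        printed = unified_focal_loss(self.PRED, self.GT,
                                     LossParams(0.6, 0.5, 1.0, printed_exponent=True))
        conv = unified_focal_loss(self.PRED, self.GT,
                                  LossParams(0.6, 0.5, 1.0, printed_exponent=False))
        # gamma = 0.5 makes both exponents 0.5, so they agree there...
        assert printed == pytest.approx(conv)
        # ...but differ for gamma != 0.5
        p2 = unified_focal_loss(self.PRED, self.GT,
                                LossParams(0.6, 2.0, 1.0, printed_exponent=True))
        c2 = unified_focal_loss(self.PRED, self.GT,
                                LossParams(0.6, 2.0, 1.0, printed_exponent=False))
        assert p2 != pytest.approx(c2)

    def test_tensor_version_matches_numpy_and_differentiates(self, rng):
        pred0 = np.clip(rng.random((1, 1, 4, 4)), 0.05, 0.95)
        gt = (rng.random((1, 1, 4, 4)) < 0.5).astype(float)
        t = nn.Tensor(pred0.copy(), requires_grad=True)
        loss = unified_focal_loss_tensor(t, gt, self.PARAMS)
        assert float(loss.data) == pytest.approx(
            unified_focal_loss(pred0, gt, self.PARAMS), abs=1e-9)
        loss.backward()
        eps = 1e-6
        num = np.zeros_like(pred0)
        for i in range(pred0.size):
            p = pred0.copy().ravel()
            p[i] += eps
            hi = unified_focal_loss(p.reshape(pred0.shape), gt, self.PARAMS)
            p[i] -= 2 * eps
            lo = unified_focal_loss(p.reshape(pred0.shape), gt, self.PARAMS)
            num.ravel()[i] = (hi - lo) / (2 * eps)
        assert np.allclose(t.grad, num, atol=1e-5)


class TestArchitecture:
    def test_forward_shape_contract(self, rng):
        model = build_unet(TINY_SPEC, seed=0)
        out = model.forward(rng.random((1, 3, 64, 64)))
        assert out.shape == (1, 1, 64, 64)
        assert out.data.min() >= 0.0 and out.data.max() <= 1.0

    def test_bottleneck_reduction_is_product_of_strides(self):
        assert UNetSpec().reduction == 16
        assert TINY_SPEC.reduction == 16

    def test_default_channel_widths(self):
        assert UNetSpec().channels_per_level == (32, 64, 128, 256, 512)
        model = build_unet(UNetSpec(dropout_p=0.5), seed=0)
        # encoder conv widths follow the spec
        assert [blk.w1.shape[0] for blk in model.enc] == [32, 64, 128, 256, 512]

    def test_indivisible_input_raises(self, rng):
        model = build_unet(TINY_SPEC)
        with pytest.raises(DimensionError, match="divisible"):
            model.forward(rng.random((1, 3, 50, 50)))

    def test_spec_validation(self):
        with pytest.raises(ConfigError):
            UNetSpec(channels_per_level=(8, 16), levels=3)
        with pytest.raises(ConfigError):
            UNetSpec(strides=(2, 2, 2, 2, 2))

    def test_save_load_roundtrip(self, tmp_path, rng):
        model = build_unet(TINY_SPEC, seed=1)
        model.trained = True
        x = rng.random((1, 3, 32, 32))
        before = model.forward(x).data
        model.save(tmp_path / "m.npz")
        from leukoseg import UNet
        restored = UNet.load(tmp_path / "m.npz", TINY_SPEC)
        assert np.array_equal(restored.forward(x).data, before)
        assert restored.trained


class TestFoldPlan:
    @pytest.mark.parametrize("n,k,seed", [(10, 10, 0), (23, 10, 5), (101, 7, 9)])
    def test_partition_property(self, n, k, seed):
        a = FoldPlan(n_folds=k, shuffle_seed=seed).assign(n)
        sizes = np.bincount(a, minlength=k)
        assert sizes.sum() == n
        assert sizes.max() - sizes.min() <= 1

    def test_too_few_samples(self):
        with pytest.raises(ConfigError):
            FoldPlan(n_folds=10).assign(5)

    def test_seed_determinism(self):
        a1 = FoldPlan(n_folds=4, shuffle_seed=3).assign(17)
        a2 = FoldPlan(n_folds=4, shuffle_seed=3).assign(17)
        assert np.array_equal(a1, a2)


def _tiny_dataset(n=4, size=32):
    pairs = make_smear_batch(n, seed=5, image_size=size, n_nuclei=1,
                             nucleus_radius_range=(6.0, 9.0), n_rbc=3)
    return [p[0] for p in pairs], [p[1] for p in pairs]


class TestTraining:
    def test_fixed_seed_reproduces_first_epoch_loss(self):
        imgs, msks = _tiny_dataset()
        kw = dict(spec=TINY_SPEC, params=LossParams(),
                  augment=AugmentPolicy(resize_to=(32, 32)),
                  train_cfg=TrainConfig(epochs=1, seed=11, batch_size=4))
        _, h1 = train_unet(imgs, msks, **kw)
        _, h2 = train_unet(imgs, msks, **kw)
        assert h1["train_loss"].iloc[0] == h2["train_loss"].iloc[0]

    def test_single_image_overfit_and_inference(self):
        imgs, msks = _tiny_dataset(n=1, size=48)
        spec = UNetSpec(channels_per_level=(4, 8, 16, 32, 64), dropout_p=0.0)
        model, hist = train_unet(
            imgs, msks, spec, LossParams(),
            AugmentPolicy(enabled=False, resize_to=(48, 48)),
            TrainConfig(epochs=120, learning_rate=3e-3, batch_size=1, seed=0))
        pred = predict_mask(model, imgs[0])
        assert evaluate(pred, msks[0]).iou >= 0.95
        # inference determinism
        assert np.array_equal(pred, predict_mask(model, imgs[0]))

    def test_all_background_target_gives_empty_mask(self):
        imgs, _ = _tiny_dataset(n=2, size=32)
        empty = [np.zeros((32, 32), dtype=bool)] * 2
        spec = UNetSpec(channels_per_level=(4, 8, 16, 32, 64), dropout_p=0.0)
        model, _ = train_unet(
            imgs, empty, spec, LossParams(),
            AugmentPolicy(enabled=False, resize_to=(32, 32)),
            TrainConfig(epochs=60, learning_rate=1e-2, batch_size=2, seed=0))
        assert not predict_mask(model, imgs[0]).any()

    def test_untrained_model_rejected(self):
        model = build_unet(TINY_SPEC)
        with pytest.raises(ModelError):
            predict_mask(model, np.zeros((32, 32, 3), dtype=np.uint8))

    def test_crossval_structure(self):
        imgs, msks = _tiny_dataset(n=6, size=32)
        result = train_crossval(
            imgs, msks, TINY_SPEC, LossParams(), FoldPlan(n_folds=3, shuffle_seed=0),
            AugmentPolicy(enabled=False, resize_to=(32, 32)),
            TrainConfig(epochs=1, batch_size=4, seed=0))
        assert len(result["folds"]) == 3
        assert sorted(result["test_masks"]) == list(range(6))
        for hist in result["folds"]:
            assert {"epoch", "train_loss", "val_loss", "train_iou",
                    "val_iou"} <= set(hist.columns)


class TestAugmentation:
    def test_validation_path_only_resizes(self, rng):
        imgs, msks = _tiny_dataset(n=1, size=32)
        pol = AugmentPolicy(resize_to=(64, 64))
        img, msk = pol.apply(imgs[0], msks[0], rng, train=False)
        assert img.shape == (64, 64, 3) and msk.shape == (64, 64)

    def test_geometry_keeps_mask_registered(self):
        # a nucleus-only image: after any augmentation the bright (purple)
        # pixels should still coincide with the mask
        imgs, msks = _tiny_dataset(n=1, size=32)
        pol = AugmentPolicy(resize_to=(32, 32), p_photo=0.0)
        rng = np.random.default_rng(123)
        img, msk = pol.apply(imgs[0], msks[0], rng, train=True)
        if msk.any() and (~msk).any():
            # nucleus pixels are darker in G than background in this palette
            assert img[msk, 1].mean() < img[~msk, 1].mean()
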
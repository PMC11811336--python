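"""Model building, augmentation semantics, training loop, and prediction."""

import numpy as np
import pytest

from gazemap.reconstruction import (
    AugmentationPolicy,
    ModelSpec,
    TrainConfig,
    augment_pair,
    build_model,
    load_checkpoint,
    predict_heatmaps,
    save_checkpoint,
    train_model,
)
from gazemap.slide_tiling import PatchPair


def _pair(rng, p=32):
    return PatchPair(
        image=rng.integers(0, 255, (p, p, 3)).astype(np.uint8),
        target=rng.random((p, p)),
        origin=(0, 0),
        case_id="c",
    )


class TestBuildModel:
    def test_unknown_arch_rejected(self):
        with pytest.raises(ValueError, match="arch"):
            ModelSpec(arch="vae")

    def test_pretrained_requires_checkpoint_path(self):
        with pytest.raises(ValueError, match="pretrained"):
            build_model(ModelSpec(arch="unet", encoder_width=4, pretrained=True))

    def test_pretrained_loads_from_checkpoint(self, tmp_path):
        spec = ModelSpec(arch="unet", encoder_width=4, seed=0)
        model = build_model(spec)
        path = tmp_path / "ck.npz"
        save_checkpoint(path, model, spec)
        warm = build_model(ModelSpec(arch="unet", encoder_width=4, seed=99,
                                     pretrained=True, pretrained_path=str(path)))
        for pa, pb in zip(model.parameters(), warm.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)


class TestAugmentation:
    def test_hflip_is_involution_and_joint(self, rng):
        pair = _pair(rng)
        policy = AugmentationPolicy(ops=("hflip",), p=1.0)
        once = augment_pair(pair, policy, np.random.default_rng(0))
        np.testing.assert_array_equal(once.image, pair.image[:, ::-1])
        np.testing.assert_array_equal(once.target, pair.target[:, ::-1])
        twice = augment_pair(once, policy, np.random.default_rng(0))
        np.testing.assert_array_equal(twice.image, pair.image)
        np.testing.assert_array_equal(twice.target, pair.target)

    def test_photometric_ops_never_touch_target(self, rng):
        pair = _pair(rng)
        policy = AugmentationPolicy(
            ops=("sharpen", "emboss", "brightness", "hue_saturation",
                 "grayscale", "contrast"),
            p=1.0,
        )
        out = augment_pair(pair, policy, np.random.default_rng(3))
        np.testing.assert_array_equal(out.target, pair.target)

    def test_random_crop_applied_jointly(self, rng):
        pair = PatchPair(
            image=np.zeros((32, 32, 3), dtype=np.uint8),
            target=np.zeros((32, 32)),
            origin=(0, 0), case_id="c",
        )
        pair.image[8:12, 8:12] = 255
        pair.target[8:12, 8:12] = 1.0
        policy = AugmentationPolicy(ops=("random_crop",), p=1.0)
        out = augment_pair(pair, policy, np.random.default_rng(5))
        img_mass = np.argwhere(out.image[..., 0] > 128).mean(axis=0)
        tgt_mass = np.argwhere(out.target > 0.5).mean(axis=0)
        np.testing.assert_allclose(img_mass, tgt_mass, atol=1.5)
        assert out.target.min() >= 0 and out.target.max() <= 1

    def test_full_policy_replays_deterministically(self, rng):
        pair = _pair(rng)
        policy = AugmentationPolicy(p=0.7)
        a = augment_pair(pair, policy, np.random.default_rng(11))
        b = augment_pair(pair, policy, np.random.default_rng(11))
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.target, b.target)


class TestTraining:
    def _pairs(self, rng, n, p=32, zero_target=False):
        out = []
        for _ in range(n):
            pr = _pair(rng, p)
            if zero_target:
                pr = PatchPair(pr.image, np.zeros((p, p)), pr.origin, pr.case_id)
            out.append(pr)
        return out

    def test_empty_split_rejected(self, rng):
        model = build_model(ModelSpec(arch="convae", encoder_width=4))
        with pytest.raises(ValueError):
            train_model(model, [], self._pairs(rng, 2), TrainConfig(max_epochs=1))

    def test_constant_zero_targets_drive_val_loss_to_zero(self, rng):
        pairs = self._pairs(rng, 12, zero_target=True)
        model = build_model(ModelSpec(arch="unet", encoder_width=4, seed=0))
        config = TrainConfig(batch_size=2, max_epochs=20,
                             early_stopping_patience=20, seed=0)
        model, history = train_model(model, pairs, pairs[:4], config)
        assert min(h["val_loss"] for h in history) < 0.01

    def test_val_loss_improves_over_initial(self, rng):
        pairs = self._pairs(rng, 12)
        model = build_model(ModelSpec(arch="unet", encoder_width=4, seed=0))
        config = TrainConfig(batch_size=4, max_epochs=3, seed=0)
        model, history = train_model(model, pairs[:8], pairs[8:], config)
        assert history[-1]["val_loss"] < history[0]["val_loss"] * 1.05

    def test_same_seed_replays_identical_history(self, rng):
        pairs = self._pairs(rng, 8)
        config = TrainConfig(batch_size=4, max_epochs=2, seed=7)
        runs = []
        for _ in range(2):
            model = build_model(ModelSpec(arch="convae", encoder_width=4, seed=7))
            _, history = train_model(model, pairs[:6], pairs[6:], config)
            runs.append(history)
        assert runs[0] == runs[1]

    def test_early_stopping_restores_best_weights(self, rng):
        pairs = self._pairs(rng, 8)
        model = build_model(ModelSpec(arch="convae", encoder_width=4, seed=0))
        config = TrainConfig(batch_size=4, max_epochs=20,
                             early_stopping_patience=2, seed=0)
        model, history = train_model(model, pairs[:6], pairs[6:], config)
        best = min(h["val_loss"] for h in history)
        from gazemap.reconstruction import _eval_loss

        assert _eval_loss(model, pairs[6:], config) == pytest.approx(best, rel=1e-5)


class TestPredict:
    def test_output_count_shape_and_range(self, rng):
        model = build_model(ModelSpec(arch="unet", encoder_width=4, seed=0))
        pairs = [_pair(rng) for _ in range(3)]
        preds = predict_heatmaps(model, pairs, TrainConfig(batch_size=2))
        assert len(preds) == 3
        for p in preds:
            assert p.shape == (32, 32)
            assert 0 < p.min() and p.max() < 1

    def test_batch_order_equivariance(self, rng):
        model = build_model(ModelSpec(arch="unet", encoder_width=4, seed=0))
        pairs = [_pair(rng) for _ in range(4)]
        config = TrainConfig(batch_size=4)
        fwd = predict_heatmaps(model, pairs, config)
        rev = predict_heatmaps(model, pairs[::-1], config)
        for a, b in zip(fwd, rev[::-1]):
            np.testing.assert_allclose(a, b, atol=1e-6)


def test_checkpoint_round_trip(tmp_path, rng):
    spec = ModelSpec(arch="attention_unet", encoder_width=4, seed=2)
    config = TrainConfig(batch_size=2, max_epochs=1)
    model = build_model(spec)
    path = tmp_path / "model.npz"
    save_checkpoint(path, model, spec, config)
    loaded, spec2, config2 = load_checkpoint(path)
    assert spec2 == spec
    assert config2 == config
    x = rng.integers(0, 255, (32, 32, 3)).astype(np.uint8)
    a = predict_heatmaps(model, [x], config)[0]
    b = predict_heatmaps(loaded, [x], config)[0]
    np.testing.assert_array_equal(a, b)
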
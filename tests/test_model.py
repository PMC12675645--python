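"""Residual U-Net construction, loss, schedule, training and inference."""

import numpy as np
import pytest

from fluorosynth.model import (
    ModelConfig,
    TrainedSynthesizer,
    build_model,
    linear_lr,
    mse_loss,
    synthesize,
    train,
)
from fluorosynth.des import TrainingPair
from fluorosynth.projection import RadiographImage


def make_pairs(n, shape=(16, 16), seed=0):
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n):
        se = rng.random(shape) * 0.8 + 0.1
        des = np.sqrt(se)  # smooth deterministic mapping
        pairs.append(
            TrainingPair(
                se=RadiographImage(se, (1.0, 1.0), {"kind": "SE"}),
                des=RadiographImage(des, (1.0, 1.0), {"kind": "DES"}),
            )
        )
    return pairs


SMALL = ModelConfig(depth=2, base_filters=4, input_shape=(16, 16), epochs=2, seed=3)


class TestBuildModel:
    def test_seeded_init_reproducible(self):
        a, b = build_model(SMALL), build_model(SMALL)
        for wa, wb in zip(a.get_weights(), b.get_weights()):
            assert np.array_equal(wa, wb)

    def test_forward_preserves_shape(self, rng):
        net = build_model(ModelConfig(depth=3, base_filters=8, input_shape=(64, 64)))
        x = rng.random((2, 1, 64, 64)).astype(np.float32)
        assert net.forward(x).shape == (2, 1, 64, 64)

    def test_parameter_count_matches_hand_tally(self):
        # depth 3, base 8, 1 block/level, instance norm, global skip.
        # Residual block (cin -> c): conv3x3 cin->c, conv3x3 c->c, norm x2
        # (2c each), 1x1 projection when cin != c.
        def block(cin, c):
            n = (cin * 9 + 1) * c + (c * 9 + 1) * c + 2 * (2 * c)
            if cin != c:
                n += (cin + 1) * c
            return n

        expected = (
            block(1, 8) + block(8, 16) + block(16, 32)  # encoder
            + block(32, 64)  # bottleneck
            + block(64, 32) + block(32, 16) + block(16, 8)  # decoder (after concat)
            + (64 + 1) * 32 + (32 + 1) * 16 + (16 + 1) * 8  # 1x1 up-convolutions
            + (8 + 1) * 1  # final 1x1
        )
        net = build_model(ModelConfig(depth=3, base_filters=8, input_shape=(64, 64)))
        assert net.n_parameters() == expected

    def test_indivisible_shape_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(depth=3, input_shape=(60, 60))

    def test_gradients_match_finite_differences(self, rng):
        cfg = ModelConfig(depth=2, base_filters=2, input_shape=(8, 8), epochs=1)
        net = build_model(cfg)
        for obj, attr, _ in net.param_slots():
            setattr(obj, attr, getattr(obj, attr).astype(np.float64))
        x = rng.normal(size=(2, 1, 8, 8))
        y = rng.normal(size=(2, 1, 8, 8))
        pred = net.forward(x)
        net.backward((2.0 / pred.size) * (pred - y))
        slots = net.param_slots()
        grads = [getattr(o, g).copy() for o, _, g in slots]
        for si in range(0, len(slots), 5):
            obj, attr, _ = slots[si]
            p = getattr(obj, attr)
            i = np.unravel_index(p.size // 2, p.shape)
            eps, orig = 1e-6, p[i]
            p[i] = orig + eps
            lp = mse_loss(net.forward(x), y)
            p[i] = orig - eps
            lm = mse_loss(net.forward(x), y)
            p[i] = orig
            num = (lp - lm) / (2 * eps)
            assert grads[si][i] == pytest.approx(num, abs=1e-6, rel=1e-4)


class TestMseLoss:
    def test_zero_for_identical(self, rng):
        a = rng.random((5, 7))
        assert mse_loss(a, a) == 0.0

    def test_constant_offset(self, rng):
        a = rng.random((6, 6))
        assert mse_loss(a, a + 2.0) == pytest.approx(4.0)

    def test_matches_double_loop(self, rng):
        pred, target = rng.random((3, 3)), rng.random((3, 3))
        expected = sum(
            (target[i, j] - pred[i, j]) ** 2 for i in range(3) for j in range(3)
        ) / 9.0
        assert mse_loss(pred, target) == pytest.approx(expected, rel=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mse_loss(np.zeros((2, 2)), np.zeros((2, 3)))


class TestSchedule:
    def test_endpoints_and_midpoint(self):
        assert linear_lr(0.02, 1e-4, 0, 20) == pytest.approx(0.02)
        assert linear_lr(0.02, 1e-4, 19, 20) == pytest.approx(1e-4)
        mid = linear_lr(0.02, 1e-4, 19 / 2, 20)
        assert mid == pytest.approx((0.02 + 1e-4) / 2, abs=1e-9)


class TestTrain:
    def test_zero_epochs_keeps_initial_weights(self):
        cfg = ModelConfig(depth=2, base_filters=4, input_shape=(16, 16), epochs=0, seed=3)
        net = build_model(cfg)
        w0 = net.get_weights()
        ts = train(net, make_pairs(4), cfg)
        assert ts.history == []
        for a, b in zip(w0, ts.net.get_weights()):
            assert np.array_equal(a, b)

    def test_single_pair_overfits(self):
        cfg = ModelConfig(
            depth=2, base_filters=4, input_shape=(16, 16), epochs=200, batch_size=1,
            val_fraction=0.0, seed=3,
        )
        ts = train(build_model(cfg), make_pairs(1), cfg)
        losses = [h["train_loss"] for h in ts.history]
        assert losses[-1] < 1e-3 * max(losses[0], 1e-6) or losses[-1] < 1e-6

    def test_smoothed_loss_non_increasing(self):
        cfg = ModelConfig(depth=2, base_filters=4, input_shape=(16, 16), epochs=15, seed=3)
        ts = train(build_model(cfg), make_pairs(12), cfg)
        losses = np.array([h["train_loss"] for h in ts.history])
        k = 5
        sm = np.convolve(losses, np.ones(k) / k, mode="valid")
        assert np.all(np.diff(sm) <= 1e-6 + 0.05 * sm[:-1])  # Adam jitter allowance

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train(build_model(SMALL), [], SMALL)

    def test_seeded_training_reproducible(self):
        pairs = make_pairs(6)
        a = train(build_model(SMALL), pairs, SMALL)
        b = train(build_model(SMALL), pairs, SMALL)
        assert a.history == b.history
        for wa, wb in zip(a.net.get_weights(), b.net.get_weights()):
            assert np.array_equal(wa, wb)


class TestSynthesize:
    def _trained(self):
        return TrainedSynthesizer(net=build_model(SMALL), config=SMALL)

    def test_deterministic_inference(self, rng):
        ts = self._trained()
        se = RadiographImage(rng.random((16, 16)) + 0.1, (1.0, 1.0), {"kind": "SE"})
        a, b = synthesize(ts, se), synthesize(ts, se)
        assert np.array_equal(a.pixels, b.pixels)
        assert a.meta["kind"] == "synthesized_DES"

    def test_output_unpadded_to_input_shape(self, rng):
        ts = self._trained()
        se = RadiographImage(rng.random((13, 18)) + 0.1, (1.0, 1.0), {"kind": "SE"})
        assert synthesize(ts, se).shape == (13, 18)

    def test_save_load_round_trip(self, rng, tmp_path):
        ts = train(build_model(SMALL), make_pairs(4), SMALL)
        path = tmp_path / "model.bin"
        ts.save(path)
        loaded = TrainedSynthesizer.load(path)
        assert loaded.config == ts.config
        assert loaded.history == ts.history
        se = RadiographImage(rng.random((16, 16)) + 0.1, (1.0, 1.0), {"kind": "SE"})
        assert np.array_equal(synthesize(ts, se).pixels, synthesize(loaded, se).pixels)
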
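"""U-Net architecture, losses, gradients, and training-loop contracts."""

import numpy as np
import pytest

from pectus.errors import ParameterError
from pectus.nn import TrainConfig, UNet, train
from pectus.nn.losses import active_contour_loss, ce_loss, dice_loss, loss
from pectus.nn.train import dice_score

TINY = TrainConfig(input_size=16, base_filters=2, depth=2, seed=3,
                   max_epochs=2, batch_size=2, learning_rate=1e-3)


class TestArchitecture:
    def test_classic_depth4_configuration_has_23_layers(self):
        model = UNet(TrainConfig(input_size=128, base_filters=8, depth=4))
        assert model.n_weighted_layers() == 23

    def test_forward_preserves_shape_and_probability_range(self):
        model = UNet(TINY)
        x = np.random.default_rng(0).random((3, 1, 16, 16), dtype=np.float32)
        prob = model.forward(x)
        assert prob.shape == (3, 1, 16, 16)
        assert prob.min() >= 0.0 and prob.max() <= 1.0

    def test_same_seed_builds_identical_parameters(self):
        cfg = TrainConfig(input_size=32, base_filters=4, depth=2, seed=11)
        assert UNet(cfg).checksum() == UNet(cfg).checksum()
        other = TrainConfig(input_size=32, base_filters=4, depth=2, seed=12)
        assert UNet(cfg).checksum() != UNet(other).checksum()

    def test_indivisible_input_size_rejected_before_training(self):
        with pytest.raises(ParameterError, match="divisible"):
            TrainConfig(input_size=100, depth=4).validate()

    def test_save_load_round_trip(self, tmp_path):
        model = UNet(TINY)
        model.save(tmp_path / "ckpt")
        loaded = UNet.load(tmp_path / "ckpt")
        assert loaded.checksum() == model.checksum()


class TestLosses:
    def test_perfect_binary_prediction_has_zero_dice_loss(self):
        t = (np.random.default_rng(0).random((32, 32)) > 0.5).astype(float)
        value, _ = dice_loss(t, t)
        assert value == pytest.approx(0.0, abs=1e-6)

    def test_uniform_half_prediction_gives_log2_cross_entropy(self):
        t = (np.random.default_rng(1).random((16, 16)) > 0.5).astype(float)
        value, _ = ce_loss(np.full((16, 16), 0.5), t)
        assert value == pytest.approx(np.log(2.0), rel=1e-9)

    def test_checkerboard_has_larger_length_term_than_constant(self):
        t = np.zeros((16, 16))
        rr, cc = np.mgrid[:16, :16]
        checker = ((rr + cc) % 2).astype(float)
        const = np.full((16, 16), 0.5)
        # Region terms are equal: both predictions average 0.5 against t = 0.
        v_check, _ = active_contour_loss(checker, t)
        v_const, _ = active_contour_loss(const, t)
        assert v_check > v_const

    def test_length_term_vanishes_for_constant_map(self):
        t = np.ones((8, 8))
        value, _ = active_contour_loss(np.full((8, 8), 0.3), t,
                                       region_weight=0.0, eps=0.0)
        assert value == 0.0

    def test_losses_are_nonnegative(self):
        rng = np.random.default_rng(2)
        p = rng.random((12, 12))
        t = (rng.random((12, 12)) > 0.5).astype(float)
        for kind in ("ce", "dice", "active_contour"):
            value, _ = loss(p, t, kind)
            assert value >= 0.0

    def test_dice_loss_complements_evaluation_dice_on_binary_maps(self):
        rng = np.random.default_rng(3)
        p = (rng.random((64, 64)) > 0.4)
        t = (rng.random((64, 64)) > 0.5)
        value, _ = dice_loss(p.astype(float), t.astype(float))
        assert value == pytest.approx(1.0 - dice_score(p, t), abs=1e-6)

    def test_nan_prediction_is_a_numeric_error(self):
        p = np.full((4, 4), np.nan)
        with pytest.raises(FloatingPointError):
            dice_loss(p, np.ones((4, 4)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ParameterError, match="mismatch"):
            ce_loss(np.zeros((4, 4)), np.zeros((4, 5)))


class TestGradients:
    @pytest.mark.parametrize("kind", ["ce", "dice", "active_contour"])
    def test_backward_matches_numerical_gradient(self, kind):
        model = UNet(TrainConfig(input_size=8, base_filters=2, depth=1, seed=0))
        rng = np.random.default_rng(4)
        x = rng.random((2, 1, 8, 8), dtype=np.float32)
        t = (rng.random((2, 1, 8, 8)) > 0.5).astype(np.float32)
        prob = model.forward(x, keep_cache=True)
        _, dp = loss(prob, t, kind)
        grads = model.backward(dp)
        h = 1e-3
        for name in ("enc0a_w", "up0_w", "out_w", "botb_b"):
            p = model.params[name]
            idx = (0,) * p.ndim
            orig = p[idx]
            p[idx] = orig + h
            v1, _ = loss(model.forward(x), t, kind)
            p[idx] = orig - h
            v2, _ = loss(model.forward(x), t, kind)
            p[idx] = orig
            num = (v1 - v2) / (2 * h)
            assert grads[name][idx] == pytest.approx(num, rel=0.02, abs=1e-6)


class TestTrainingLoop:
    def _pairs(self, n=8, size=16, seed=0):
        rng = np.random.default_rng(seed)
        pairs = []
        for _ in range(n):
            img = rng.random((size, size), dtype=np.float32) * 0.2
            mask = np.zeros((size, size), np.float32)
            r, c = rng.integers(4, size - 4, 2)
            mask[r - 3:r + 3, c - 3:c + 3] = 1.0
            img += mask * 0.8
            pairs.append((img, mask))
        return pairs

    def test_zero_epochs_returns_initial_model_and_empty_history(self):
        cfg = TrainConfig(input_size=16, base_filters=2, depth=2, seed=3,
                          max_epochs=0)
        model = UNet(cfg)
        before = model.checksum()
        model, history = train(model, self._pairs(), cfg)
        assert history == []
        assert model.checksum() == before

    def test_identical_seed_gives_identical_history(self):
        cfg = TrainConfig(input_size=16, base_filters=2, depth=2, seed=3,
                          max_epochs=2, batch_size=2, learning_rate=1e-3)
        _, h1 = train(UNet(cfg), self._pairs(), cfg)
        _, h2 = train(UNet(cfg), self._pairs(), cfg)
        assert h1 == h2

    def test_training_reduces_loss_on_easy_blobs(self):
        cfg = TrainConfig(input_size=16, base_filters=4, depth=2, seed=5,
                          max_epochs=15, batch_size=4, learning_rate=3e-3)
        _, history = train(UNet(cfg), self._pairs(n=16, seed=5), cfg)
        assert history[-1]["train_loss"] < history[0]["train_loss"]

    def test_fewer_than_two_pairs_rejected(self):
        cfg = TrainConfig(input_size=16, base_filters=2, depth=2)
        with pytest.raises(ParameterError, match="at least 2"):
            train(UNet(cfg), self._pairs(n=1), cfg)
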
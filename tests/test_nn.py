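"""Network shape contracts, gradient correctness, loss, training behavior."""

import numpy as np
import pytest

from halluxmetry.errors import ConfigurationError
from halluxmetry.heatmaps import make_heatmaps
from halluxmetry.nn import (ModelConfig, TrainConfig, build_model,
                            load_checkpoint, predict, rmse_loss,
                            save_checkpoint, train)
from halluxmetry.phantoms import PhantomSpec, generate_phantom


def _tiny_config(size=32, levels=3, filters=4):
    return ModelConfig(input_size=size, n_levels=levels, out_channels=6,
                       base_filters=filters, convs_per_block=1)


class TestShapes:
    @pytest.mark.parametrize("size", [64, 128])
    def test_output_matches_input_resolution(self, size):
        net = build_model(ModelConfig(input_size=size, n_levels=5,
                                      base_filters=4, convs_per_block=1), seed=0)
        out = net.forward(np.zeros((1, 1, size, size)))
        assert out.shape == (1, 6, size, size)

    def test_all_zero_input_bounded_output(self):
        net = build_model(_tiny_config(), seed=1)
        out = net.forward(np.zeros((2, 1, 32, 32)))
        assert np.isfinite(out).all()
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(input_size=100, n_levels=5)

    def test_wrong_input_shape_rejected(self):
        net = build_model(_tiny_config(), seed=0)
        with pytest.raises(ValueError):
            net.forward(np.zeros((1, 1, 64, 64)))


class TestGradients:
    def test_backprop_matches_numeric_gradient(self):
        """Central-difference check of d(RMSE)/d(theta) on a tiny network."""
        cfg = ModelConfig(input_size=8, n_levels=2, out_channels=2,
                          base_filters=2, convs_per_block=1)
        net = build_model(cfg, seed=0)
        rng = np.random.default_rng(0)
        x = rng.random((2, 1, 8, 8))
        t = rng.random((2, 2, 8, 8))

        out = net.forward(x)
        diff = out - t
        loss = np.sqrt(np.mean(diff ** 2))
        net.backward(diff / (diff.size * loss))

        eps = 1e-6
        for p, g in zip(net.params, net.grads):
            flat_idx = rng.integers(0, p.size, size=2)
            for fi in flat_idx:
                idx = np.unravel_index(fi, p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp = np.sqrt(np.mean((net.forward(x) - t) ** 2))
                p[idx] = orig - eps
                lm = np.sqrt(np.mean((net.forward(x) - t) ** 2))
                p[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert g[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-9)


class TestRmseLoss:
    def test_identical_stacks(self):
        a = np.random.default_rng(0).random((8, 8, 6))
        assert rmse_loss(a, a) == 0.0

    def test_constant_offset(self):
        a = np.zeros((8, 8, 6))
        assert rmse_loss(a + 0.5, a) == pytest.approx(0.5)

    def test_full_scale_error(self):
        assert rmse_loss(np.zeros((4, 4, 6)), np.ones((4, 4, 6))) == pytest.approx(1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse_loss(np.zeros((4, 4, 6)), np.zeros((8, 8, 6)))


def _phantom_pair(size=64, seed=3):
    spec = PhantomSpec(image_height=size, image_width=size, seed=seed)
    sample = generate_phantom(spec)
    return sample.image, make_heatmaps(sample.annotation).values


class TestTraining:
    def test_single_batch_overfit(self):
        """One phantom, 200 iterations: loss must drop below 0.1x initial."""
        img, target = _phantom_pair()
        cfg = ModelConfig(input_size=64, n_levels=5, base_filters=8,
                          convs_per_block=1)
        net = build_model(cfg, seed=0)
        x = img[None, None]
        t = target.transpose(2, 0, 1)[None]
        opt = net.make_optimizer(3e-3)
        initial = None
        for _ in range(200):
            out = net.forward(x)
            diff = out - t
            loss = float(np.sqrt(np.mean(diff ** 2)))
            if initial is None:
                initial = loss
            net.backward(diff / (diff.size * max(loss, 1e-12)))
            opt.step()
        final = float(np.sqrt(np.mean((net.forward(x) - t) ** 2)))
        assert final < 0.1 * initial

    def test_descent_and_bookkeeping(self):
        pairs = [_phantom_pair(size=32, seed=s) for s in range(4)]
        pairs = [(img, t) for img, t in pairs]
        cfg = TrainConfig(max_epochs=3, minibatch_size=2,
                          initial_learning_rate=1e-3,
                          validation_frequency=2, validation_patience=10, seed=0)
        net = build_model(_tiny_config(size=32), seed=0)
        history = train(net, pairs, pairs[:2], cfg)
        n_iters = len(history.iterations)
        assert n_iters <= int(np.ceil(3 * len(pairs) / 2))
        assert history.train_rmse[-1] <= history.train_rmse[0]
        assert history.best_val_rmse <= history.val_rmse[0]

    def test_early_stopping_restores_best_weights(self):
        """Aggressively overfitting one phantom while validating on a
        different one must trigger patience-based stopping and roll the
        network back to the best-validation checkpoint."""
        train_pair = [_phantom_pair(size=32, seed=9)]
        val_pair = [_phantom_pair(size=32, seed=10)]
        cfg = TrainConfig(max_epochs=300, minibatch_size=1,
                          initial_learning_rate=3e-2,
                          validation_frequency=1, validation_patience=3, seed=0)
        net = build_model(_tiny_config(size=32), seed=0)
        history = train(net, train_pair, val_pair, cfg)
        assert history.stopped_early
        x = val_pair[0][0][None, None]
        t = val_pair[0][1].transpose(2, 0, 1)[None]
        restored = float(np.sqrt(np.mean((net.forward(x) - t) ** 2)))
        assert restored == pytest.approx(history.best_val_rmse, rel=1e-6)

    def test_empty_dataset_rejected(self):
        net = build_model(_tiny_config(), seed=0)
        with pytest.raises(ValueError):
            train(net, [], None, TrainConfig())

    def test_seeded_training_reproducible(self):
        pairs = [_phantom_pair(size=32, seed=s) for s in range(3)]
        cfg = TrainConfig(max_epochs=2, minibatch_size=2,
                          initial_learning_rate=1e-3,
                          validation_frequency=100, seed=5)
        nets = []
        for _ in range(2):
            net = build_model(_tiny_config(size=32), seed=7)
            train(net, pairs, None, cfg)
            nets.append(net)
        for a, b in zip(nets[0].params, nets[1].params):
            assert np.array_equal(a, b)


class TestPredictAndCheckpoint:
    def test_predict_contract(self):
        img, _ = _phantom_pair(size=32)
        net = build_model(_tiny_config(size=32), seed=0)
        stack = predict(net, img)
        assert stack.values.shape == (32, 32, 6)
        assert stack.values.min() >= 0.0 and stack.values.max() <= 1.0
        again = predict(net, img)
        assert np.array_equal(stack.values, again.values)

    def test_wrong_image_size_rejected(self):
        net = build_model(_tiny_config(size=32), seed=0)
        with pytest.raises(ValueError):
            predict(net, np.zeros((64, 64)))

    def test_checkpoint_round_trip(self, tmp_path):
        img, _ = _phantom_pair(size=32)
        net = build_model(_tiny_config(size=32), seed=3)
        path = tmp_path / "model.ckpt.npz"
        save_checkpoint(net, path)
        loaded = load_checkpoint(path)
        assert loaded.config == net.config
        assert np.array_equal(predict(loaded, img).values,
                              predict(net, img).values)
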
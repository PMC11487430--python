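import numpy as np
import pytest

from p300wave import (
    ArchitectureSpec,
    TrainingConfig,
    ValidationError,
    balance_batches,
    build_model,
    predict_scores,
    train_classifier,
)
from p300wave.cnn import _mse


class TestArchitectureSpecs:
    def test_vgg16_spatial_trace_and_flatten(self):
        spec = ArchitectureSpec.preset("vgg16")
        assert spec.spatial_trace == (150, 75, 38, 19, 10, 5)
        assert spec.conv_depths == (32, 64, 128, 128, 256)
        assert spec.flatten_size == 5 * 5 * 256 == 6400
        assert spec.dense_sizes == (1024, 512, 256)

    def test_sv16_spatial_trace_and_flatten(self):
        spec = ArchitectureSpec.preset("sv16")
        assert spec.spatial_trace == (150, 75, 38, 19)
        assert spec.flatten_size == 19 * 19 * 128 == 46208
        assert spec.dense_sizes == (512, 256)

    def test_msv16_is_sv16_with_8_channel_input(self):
        sv, msv = ArchitectureSpec.preset("sv16"), ArchitectureSpec.preset("msv16")
        assert msv.input_depth == 8 and sv.input_depth == 1
        assert msv.conv_depths == sv.conv_depths
        assert msv.dense_sizes == sv.dense_sizes

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValidationError):
            ArchitectureSpec.preset("resnet")

    def test_width_factor_narrows_but_keeps_depth_count(self):
        spec = ArchitectureSpec.preset("msv16", width_factor=0.125)
        assert len(spec.conv_depths) == 3
        assert spec.conv_depths == (4, 8, 16)
        assert spec.input_depth == 8
        assert spec.spatial_trace == (150, 75, 38, 19)

    def test_training_defaults_per_variant(self):
        vgg = TrainingConfig.for_variant("vgg16")
        assert (vgg.learning_rate, vgg.batch_size, vgg.early_stopping_epochs) == (
            5e-4, 20, None,
        )
        sv = TrainingConfig.for_variant("sv16")
        assert (sv.learning_rate, sv.batch_size, sv.early_stopping_epochs) == (
            5e-4, 20, 7,
        )
        msv = TrainingConfig.for_variant("msv16")
        assert (msv.learning_rate, msv.batch_size, msv.early_stopping_epochs) == (
            3e-3, 6, 7,
        )


class TestModelShapes:
    def test_layerwise_spatial_trace_matches_spec(self):
        """Feeding an image through the pooling stack reproduces the
        printed side lengths at every stage."""
        from p300wave.cnn import MaxPool2

        spec = ArchitectureSpec.preset("vgg16", width_factor=1 / 32)
        model = build_model(spec, seed=0)
        x = np.zeros((1, 150, 150, 1), dtype=np.float32)
        sides = [x.shape[1]]
        rng = np.random.default_rng(0)
        for layer in model.layers:
            x = layer.forward(x, False, rng)
            if isinstance(layer, MaxPool2):
                sides.append(x.shape[1])
            if x.ndim == 2:
                break
        assert tuple(sides) == spec.spatial_trace

    def test_wrong_input_depth_rejected(self):
        model = build_model(ArchitectureSpec.preset("msv16", width_factor=0.05), seed=0)
        with pytest.raises(ValidationError, match="expects input"):
            model.forward(np.zeros((1, 150, 150, 1), dtype=np.float32))

    def test_output_is_scalar_sigmoid_per_image(self):
        model = build_model(ArchitectureSpec.preset("sv16", width_factor=0.05), seed=0)
        out = model.forward(np.random.default_rng(0).random((3, 150, 150, 1)))
        assert out.shape == (3,)
        assert ((out > 0) & (out < 1)).all()


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients agree with central differences on a small net."""
        spec = ArchitectureSpec(
            variant="sv16", conv_depths=(2, 3), dense_sizes=(4,),
            input_depth=1, input_size=8, dropout_rate=0.0,
        )
        model = build_model(spec, seed=3)
        rng = np.random.default_rng(0)
        x = rng.random((2, 8, 8, 1)).astype(np.float32)
        y = np.array([1.0, 0.0], dtype=np.float32)
        pred = model.forward(x, train=True)
        _loss, g = _mse(pred, y)
        model.backward(g)
        for p, grad in model.parameters():
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                eps, orig = 1e-3, p[idx]
                p[idx] = orig + eps
                lp, _ = _mse(model.forward(x), y)
                p[idx] = orig - eps
                lm, _ = _mse(model.forward(x), y)
                p[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert grad[idx] == pytest.approx(numeric, abs=2e-3, rel=5e-2)


class TestBalanceBatches:
    def test_every_batch_is_half_and_half(self, rng):
        labels = np.array([1] * 20 + [0] * 100)
        batches = balance_batches(labels, 20, rng)
        assert len(batches) == 2  # 20 positives fill two batches of 10+10
        for idx in batches:
            assert labels[idx].sum() == 10
            assert len(idx) == 20
        used = np.concatenate(batches)
        assert len(set(used.tolist())) == len(used)  # without replacement

    def test_balanced_input_fully_consumed(self, rng):
        labels = np.array([0, 1] * 12)
        batches = balance_batches(labels, 6, rng)
        assert sum(len(b) for b in batches) == 24

    def test_seeded_reproducibility(self):
        labels = np.array([1] * 30 + [0] * 150)
        a = balance_batches(labels, 6, np.random.default_rng(5))
        b = balance_batches(labels, 6, np.random.default_rng(5))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_class_counts_over_many_draws(self, rng):
        labels = np.array([1] * 9 + [0] * 40)
        for _ in range(200):
            for idx in balance_batches(labels, 6, rng):
                assert labels[idx].sum() == 3

    def test_empty_class_rejected(self, rng):
        with pytest.raises(ValidationError):
            balance_batches(np.zeros(10), 4, rng)

    def test_odd_batch_size_rejected(self, rng):
        with pytest.raises(ValidationError):
            balance_batches(np.array([0, 1]), 3, rng)


def _separable_set(rng, n=40, size=24, depth=1):
    """Bright-square vs dark images: trivially separable."""
    x = rng.random((n, size, size, depth)).astype(np.float32) * 40
    y = (np.arange(n) % 2).astype(float)
    x[y == 1, 6:18, 6:18] += 180
    return x, y


class TestTraining:
    @pytest.fixture(scope="class")
    def toy_model_spec(self):
        return ArchitectureSpec(
            variant="sv16", conv_depths=(4, 8), dense_sizes=(16,),
            input_depth=1, input_size=24, dropout_rate=0.0,
        )

    def test_separable_set_reaches_full_training_accuracy(self, toy_model_spec):
        rng = np.random.default_rng(0)
        x, y = _separable_set(rng)
        model = build_model(toy_model_spec, seed=1)
        cfg = TrainingConfig(learning_rate=1e-3, batch_size=10, max_epochs=25, seed=1)
        history = train_classifier(model, x, y, cfg)
        assert history["accuracy"][-1] == 1.0
        # epoch-level loss decreases overall
        assert history["loss"][-1] < history["loss"][0] / 5

    def test_zero_epochs_is_a_no_op(self, toy_model_spec):
        rng = np.random.default_rng(0)
        x, y = _separable_set(rng, n=10)
        model = build_model(toy_model_spec, seed=1)
        before = model.get_weights()
        history = train_classifier(
            model, x, y, TrainingConfig(max_epochs=0, seed=0)
        )
        assert history == {"loss": [], "accuracy": []}
        for b, a in zip(before, model.get_weights()):
            np.testing.assert_array_equal(b, a)

    def test_early_stopping_halts_after_patience(self, toy_model_spec):
        rng = np.random.default_rng(3)
        x, y = _separable_set(rng, n=20)
        # validation labels are random: no improvement possible once fitted
        xv = rng.random((10, 24, 24, 1)).astype(np.float32) * 255
        yv = (np.arange(10) % 2).astype(float)
        model = build_model(toy_model_spec, seed=1)
        cfg = TrainingConfig(
            learning_rate=1e-3, batch_size=10, max_epochs=60,
            early_stopping_epochs=7, seed=1,
        )
        history = train_classifier(model, x, y, cfg, validation=(xv, yv))
        assert len(history["loss"]) < 60
        best = int(np.argmin(history["val_loss"]))
        assert len(history["val_loss"]) <= best + 1 + 7

    def test_seeded_training_reproducible(self, toy_model_spec):
        rng = np.random.default_rng(0)
        x, y = _separable_set(rng, n=16)
        runs = []
        for _ in range(2):
            model = build_model(toy_model_spec, seed=5)
            h = train_classifier(
                model, x, y, TrainingConfig(batch_size=8, max_epochs=3, seed=5)
            )
            runs.append((h["loss"], predict_scores(model, x)))
        assert runs[0][0] == runs[1][0]
        np.testing.assert_array_equal(runs[0][1], runs[1][1])

    def test_non_binary_labels_rejected(self, toy_model_spec):
        model = build_model(toy_model_spec, seed=0)
        with pytest.raises(ValidationError):
            train_classifier(
                model,
                np.zeros((4, 24, 24, 1)),
                np.array([0.0, 0.5, 1.0, 1.0]),
                TrainingConfig(max_epochs=1),
            )


class TestPrediction:
    def test_scores_order_preserving_and_deterministic(self):
        spec = ArchitectureSpec(
            variant="sv16", conv_depths=(2,), dense_sizes=(4,),
            input_depth=1, input_size=16, dropout_rate=0.5,
        )
        model = build_model(spec, seed=2)
        rng = np.random.default_rng(0)
        x = rng.random((5, 16, 16, 1)) * 255
        s1 = predict_scores(model, x)
        s2 = predict_scores(model, x)
        np.testing.assert_array_equal(s1, s2)  # dropout off at inference
        dup = predict_scores(model, np.concatenate([x, x[:1]]))
        assert dup[5] == s1[0]
        assert ((s1 > 0) & (s1 < 1)).all()
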
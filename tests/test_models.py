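import numpy as np
import pytest

import ecgfuse as ef
from ecgfuse.errors import ConfigurationError, TrainingDivergedError
from ecgfuse.models import (
    Adam,
    FcNetworkSpec,
    ResNetSpec,
    TrainConfig,
    build_fc,
    build_resnet,
    cross_entropy,
    fc_parameter_count,
    load_model,
    save_model,
)
from ecgfuse.preprocessing import BeatDataset


def separable_dataset(n_classes=4, per_class=60, n=40, seed=0):
    """Gaussian bumps at class-specific positions: trivially separable."""
    rng = np.random.default_rng(seed)
    t = np.arange(n)
    X, y = [], []
    for c in range(n_classes):
        center = 5 + c * (n - 10) / max(1, n_classes - 1)
        base = np.exp(-0.5 * ((t - center) / 2.5) ** 2)
        X.append(base + rng.normal(0, 0.05, size=(per_class, n)))
        y.append(np.full(per_class, c))
    return BeatDataset(np.vstack(X), np.concatenate(y))


class TestFcNetwork:
    def test_weighted_layer_count_is_five(self):
        net = build_fc(FcNetworkSpec())
        assert net.weighted_layers == 5 == FcNetworkSpec().weighted_layers

    def test_probabilities_sum_to_one(self):
        net = build_fc(FcNetworkSpec())
        p = net.predict_proba(np.random.default_rng(0).normal(size=(3, 260)))
        assert p.shape == (3, 16)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(p >= 0)

    def test_first_weight_shape_260_by_256(self):
        net = build_fc(FcNetworkSpec(input_units=260))
        dense = [l for l in net.layers if hasattr(l, "W")][0]
        assert dense.W.shape == (260, 256)

    def test_parameter_count_closed_form(self):
        spec = FcNetworkSpec()
        net = build_fc(spec)
        expected = fc_parameter_count(spec)  # dense weights + biases
        dense_params = sum(
            l.W.size + l.b.size for l in net.layers if hasattr(l, "W")
        )
        assert dense_params == expected
        assert expected == (260 * 256 + 256) + 3 * (256 * 256 + 256) + (256 * 16 + 16)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            FcNetworkSpec(input_units=0)
        with pytest.raises(ConfigurationError):
            FcNetworkSpec(n_classes=1)


class TestResNet:
    def test_weighted_layer_count_is_twelve(self):
        net = build_resnet(ResNetSpec())
        assert net.weighted_layers == 12 == ResNetSpec().weighted_layers

    def test_block_channels(self):
        from ecgfuse.models import ResidualBlock
        net = build_resnet(ResNetSpec())
        blocks = [l for l in net.layers if isinstance(l, ResidualBlock)]
        assert [b.main.layers[0].out_ch for b in blocks] == [64, 128, 128]
        assert [b.main.layers[0].k for b in blocks] == [8, 8, 8]
        assert [b.main.layers[3].k for b in blocks] == [5, 5, 5]
        assert [b.main.layers[6].k for b in blocks] == [3, 3, 3]

    def test_zero_beat_forward_is_finite_probability(self):
        net = build_resnet(ResNetSpec())
        p = net.predict_proba(np.zeros((2, 260)))
        assert np.all(np.isfinite(p))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_too_short_input_rejected(self):
        with pytest.raises(ConfigurationError):
            ResNetSpec(input_length=5)

    def test_gradients_match_numerical(self):
        """Analytic backprop vs central differences on a tiny network."""
        spec = ResNetSpec(input_length=16, channels=(2, 3, 3),
                          kernels=(3, 3, 3), n_classes=3)
        net = build_resnet(spec, seed=1)
        rng = np.random.default_rng(0)
        X = rng.standard_normal((3, 16))
        y = np.array([0, 1, 2])
        loss, d = cross_entropy(net.forward(X, training=True), y)
        net.backward(d)
        eps = 1e-6
        for p, g in net.parameters():
            flat = p.ravel()
            for j in rng.choice(flat.size, size=min(2, flat.size), replace=False):
                orig = flat[j]
                flat[j] = orig + eps
                lp, _ = cross_entropy(net.forward(X, training=True), y)
                flat[j] = orig - eps
                lm, _ = cross_entropy(net.forward(X, training=True), y)
                flat[j] = orig
                num = (lp - lm) / (2 * eps)
                assert abs(num - g.ravel()[j]) < 1e-4 * max(1.0, abs(num))


class TestTraining:
    def test_separable_corpus_reaches_high_training_accuracy(self):
        ds = separable_dataset()
        net = build_fc(FcNetworkSpec(input_units=40, n_classes=4), seed=0)
        net, hist = ef.train(net, ds, TrainConfig(max_epochs=20, batch_size=64,
                                                  seed=0))
        assert hist["accuracy"].iloc[-1] >= 0.99

    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        ds = separable_dataset(per_class=20)
        net = build_fc(FcNetworkSpec(input_units=40, n_classes=4), seed=0)
        before = [p.copy() for p, _ in net.parameters()]
        net, _ = ef.train(net, ds, TrainConfig(learning_rate=0.0, max_epochs=1,
                                               batch_size=32, seed=0))
        for b, (p, _) in zip(before, net.parameters()):
            np.testing.assert_array_equal(b, p)

    def test_same_seed_identical_history(self):
        ds = separable_dataset(per_class=25)
        runs = []
        for _ in range(2):
            net = build_fc(FcNetworkSpec(input_units=40, n_classes=4,
                                         dropout=0.3), seed=5)
            _, hist = ef.train(net, ds, TrainConfig(max_epochs=5, batch_size=32,
                                                    seed=5))
            runs.append(hist)
        assert runs[0].equals(runs[1])

    def test_validation_split_reported(self):
        ds = separable_dataset(per_class=30)
        net = build_fc(FcNetworkSpec(input_units=40, n_classes=4), seed=0)
        _, hist = ef.train(net, ds, TrainConfig(max_epochs=3, batch_size=32,
                                                validation_fraction=0.3, seed=0))
        assert {"val_loss", "val_accuracy"} <= set(hist.columns)

    def test_label_out_of_range_rejected(self):
        ds = separable_dataset(n_classes=4)
        net = build_fc(FcNetworkSpec(input_units=40, n_classes=3), seed=0)
        with pytest.raises(ConfigurationError):
            ef.train(net, ds, TrainConfig(max_epochs=1, seed=0))

    def test_divergence_detected(self):
        ds = separable_dataset(per_class=20)
        net = build_fc(FcNetworkSpec(input_units=40, n_classes=4), seed=0)
        first_dense = next(l for l in net.layers if hasattr(l, "W"))
        first_dense.W[0, 0] = np.nan  # corrupt state -> non-finite loss
        with pytest.raises(TrainingDivergedError), np.errstate(all="ignore"):
            ef.train(net, ds, TrainConfig(max_epochs=2, batch_size=32, seed=0))

    def test_inference_deterministic_despite_dropout(self):
        net = build_fc(FcNetworkSpec(dropout=0.5), seed=0)
        X = np.random.default_rng(3).normal(size=(4, 260))
        np.testing.assert_array_equal(net.predict_proba(X), net.predict_proba(X))

    def test_resnet_trains_on_tiny_separable_set(self):
        ds = separable_dataset(n_classes=3, per_class=20, n=24)
        spec = ResNetSpec(input_length=24, channels=(4, 6, 6), kernels=(3, 3, 3),
                          n_classes=3)
        net = build_resnet(spec, seed=0)
        net, hist = ef.train(net, ds, TrainConfig(max_epochs=8, batch_size=30,
                                                  learning_rate=0.01, seed=0))
        assert hist["accuracy"].iloc[-1] >= 0.9


class TestAdam:
    def test_moves_toward_quadratic_minimum(self):
        p = np.array([10.0])
        g = np.zeros(1)
        opt = Adam([(p, g)], lr=0.5)
        for _ in range(200):
            g[...] = 2 * p  # d/dp of p^2
            opt.step()
        assert abs(p[0]) < 0.1


def test_model_save_load_round_trip(tmp_path):
    ds = separable_dataset(per_class=15)
    spec = FcNetworkSpec(input_units=40, n_classes=4)
    net = build_fc(spec, seed=0)
    net, _ = ef.train(net, ds, TrainConfig(max_epochs=2, batch_size=32, seed=0))
    X = ds.A[:7]
    save_model(net, spec, tmp_path / "m")
    back = load_model(tmp_path / "m")
    np.testing.assert_allclose(back.predict_proba(X), net.predict_proba(X),
                               atol=1e-12)
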
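"""Network architecture bookkeeping, backprop gradient check, training
determinism and the estimator contract."""

import numpy as np
import pytest

from retinasign.classifier import (
    GestureCNNClassifier,
    TrainConfig,
    build_network,
    predict,
    train,
)
from retinasign.cnn import GestureNet, softmax


def bookkeeping_counts(n_classes):
    """Independent parameter-count oracle: filters x (kh*kw*c_in + 1) for
    convolutions, (n_in + 1) x n_out for dense layers."""
    return {
        "conv1": 16 * (2 * 2 * 1 + 1),
        "conv2": 32 * (3 * 3 * 16 + 1),
        "conv3": 64 * (5 * 5 * 32 + 1),
        "fc1": (64 + 1) * 128,
        "fc2": (128 + 1) * n_classes,
    }


class TestArchitecture:
    def test_total_parameter_count_for_29_classes(self):
        net = build_network(29)
        assert net.n_parameters() == 68045

    def test_per_layer_counts_match_bookkeeping_oracle(self):
        net = build_network(29)
        assert net.layer_parameter_counts() == bookkeeping_counts(29)
        assert sum(bookkeeping_counts(29).values()) == 68045

    @pytest.mark.parametrize("n_classes", [2, 5, 29])
    def test_parameter_count_scales_with_output_width(self, n_classes):
        net = build_network(n_classes)
        assert net.n_parameters() == sum(bookkeeping_counts(n_classes).values())

    def test_forward_shape_and_softmax_normalization(self, rng):
        net = build_network(29)
        p = net.predict_proba(rng.random((3, 50, 50)))
        assert p.shape == (3, 29)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(p >= 0)

    def test_zeroed_weights_give_uniform_probabilities(self, rng):
        net = build_network(29)
        for layer in net._param_layers:
            layer.W[:] = 0
            layer.b[:] = 0
        p = net.predict_proba(rng.random((2, 50, 50)))
        np.testing.assert_allclose(p, 1.0 / 29, atol=1e-7)

    def test_wrong_input_shape_rejected(self):
        net = build_network(3)
        with pytest.raises(ValueError):
            net.forward(np.zeros((1, 40, 40)))

    def test_too_few_classes_rejected(self):
        with pytest.raises(ValueError):
            build_network(1)


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        """Central-difference check of every layer's gradient on sampled
        weight entries (float64)."""
        net = GestureNet(n_classes=3, seed=0, dtype=np.float64)
        x = rng.random((2, 50, 50))
        y = np.array([0, 2])

        def loss_only():
            logits = net.forward(x)
            p = softmax(logits)
            return -np.log(p[np.arange(2), y]).mean()

        net.loss_and_grads(x, y)
        analytic = {name: (l.dW.copy(), l.db.copy())
                    for name, l in zip(["conv1", "conv2", "conv3", "fc1", "fc2"],
                                       net._param_layers)}
        eps = 1e-6
        worst = 0.0
        for name, layer in zip(["conv1", "conv2", "conv3", "fc1", "fc2"],
                               net._param_layers):
            for arr, grad in ((layer.W, analytic[name][0]),
                              (layer.b, analytic[name][1])):
                flat = arr.reshape(-1)
                for idx in rng.choice(flat.size, size=3, replace=False):
                    orig = flat[idx]
                    flat[idx] = orig + eps
                    lp = loss_only()
                    flat[idx] = orig - eps
                    lm = loss_only()
                    flat[idx] = orig
                    numeric = (lp - lm) / (2 * eps)
                    denom = max(abs(numeric), abs(grad.reshape(-1)[idx]), 1e-8)
                    worst = max(worst,
                                abs(numeric - grad.reshape(-1)[idx]) / denom)
        assert worst < 1e-4


class TestTraining:
    def test_single_sample_single_epoch_records_finite_loss(self, rng):
        X = rng.random((1, 50, 50)) * 255
        clf = GestureCNNClassifier(classes=["a", "b"], epochs=1, seed=0)
        clf.fit(X, np.array(["a"]))
        assert len(clf.history_) == 1
        assert np.isfinite(clf.history_["loss"].iloc[0])

    def test_identical_seeds_give_identical_final_loss(self, rng):
        X = rng.random((12, 50, 50)) * 255
        y = np.array(list("abcabcabcabc"))
        runs = [
            GestureCNNClassifier(epochs=3, seed=7).fit(X, y).history_["loss"].iloc[-1]
            for _ in range(2)
        ]
        assert runs[0] == runs[1]

    def test_loss_decreases_and_memorizes_small_separable_set(self, rng):
        # 3 classes of strongly distinct images
        X = np.zeros((12, 50, 50))
        y = np.repeat(["a", "b", "c"], 4)
        X[:4, :15] = 255.0
        X[4:8, 20:35] = 255.0
        X[8:, 38:] = 255.0
        X += rng.random(X.shape) * 10
        clf = GestureCNNClassifier(epochs=25, seed=0, batch_size=4)
        clf.fit(X, y)
        assert clf.history_["loss"].iloc[-1] < clf.history_["loss"].iloc[0]
        assert (clf.predict(X) == y).all()

    def test_label_outside_class_set_rejected(self, rng):
        X = rng.random((2, 50, 50))
        clf = GestureCNNClassifier(classes=["a", "b"], epochs=1)
        with pytest.raises(ValueError):
            clf.fit(X, np.array(["a", "z"]))

    def test_invalid_train_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(optimizer="rmsprop")


class TestEstimatorContract:
    def test_clone_and_get_params_roundtrip(self):
        from sklearn.base import clone

        clf = GestureCNNClassifier(epochs=2, learning_rate=5e-4, seed=3)
        assert clone(clf).get_params() == clf.get_params()

    def test_save_load_roundtrip_preserves_predictions(self, rng, tmp_path):
        X = rng.random((6, 50, 50)) * 255
        y = np.array(list("aabbcc"))
        clf = GestureCNNClassifier(epochs=2, seed=1).fit(X, y)
        path = tmp_path / "model.npz"
        clf.save(path)
        loaded = GestureCNNClassifier.load(path)
        np.testing.assert_allclose(loaded.predict_proba(X), clf.predict_proba(X),
                                   atol=1e-6)

    def test_functional_wrappers(self, rng):
        X = rng.random((6, 50, 50)) * 255
        y = np.array(list("aabbcc"))
        clf = train(X, y, TrainConfig(epochs=2, seed=0))
        label, proba = predict(clf, X[0])
        assert label in clf.classes_
        assert proba.sum() == pytest.approx(1.0, abs=1e-6)
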
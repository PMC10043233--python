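"""The convolutional network: shape audit, gradient correctness, training
contract (schedule, determinism, separability) and serialization."""

import numpy as np
import pytest

from stopnet import cnn

#: hand-computed shape chain for the 108 x 300 input under valid convolutions
#: (kernel 64x2 / 1x11 / 1x10) and floor-semantics 1x2 pooling
EXPECTED_SHAPES = {
    "input": (1, 108, 300),
    "conv1": (6, 45, 299),
    "pool1": (6, 45, 149),
    "conv2": (12, 45, 139),
    "pool2": (12, 45, 69),
    "conv3": (12, 45, 60),
    "pool3": (12, 45, 30),
    "fc2": (2,),
}


def _tiny_spec(**kw) -> cnn.NetSpec:
    base = dict(
        n_bands=2, n_channels=8, temporal=40,
        conv1_kernel=(12, 2), conv1_filters=3,
        conv2_kernel=(1, 5), conv2_filters=4,
        conv3_kernel=(1, 4), conv3_filters=4,
        fc1_units=7, dropout_rate=0.0,
    )
    base.update(kw)
    return cnn.NetSpec(**base)


class TestArchitecture:
    def test_shape_audit(self):
        """Every built layer's output shape matches the analytic chain."""
        net = cnn.build_network(seed=0)
        assert net.output_shapes() == EXPECTED_SHAPES

    def test_too_few_spatial_rows_rejected(self):
        with pytest.raises(ValueError, match="spatial"):
            cnn.build_network(cnn.NetSpec(n_bands=1, n_channels=27))

    def test_softmax_contract(self, rng):
        net = cnn.build_network(seed=1)
        p = net.predict_proba(rng.standard_normal((3, 1, 108, 300)).astype(np.float32))
        assert np.all(p >= 0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_inference_deterministic(self, rng):
        net = cnn.build_network(seed=1)
        x = rng.standard_normal((2, 1, 108, 300)).astype(np.float32)
        np.testing.assert_array_equal(net.predict_proba(x), net.predict_proba(x))


class TestGradients:
    def test_backward_matches_numerical_gradient(self):
        """Central-difference check of every layer's weight gradient (float64,
        dropout off).  Conv biases are excluded: batch norm makes their true
        gradient identically zero, so both sides are ~0 there."""
        rng = np.random.default_rng(0)
        net = cnn.ConvNet(_tiny_spec(), rng)
        for prm in net.params():
            prm.value = prm.value.astype(np.float64)
            prm.grad = np.zeros_like(prm.value)
        x = rng.standard_normal((4, 1, 16, 40))
        y01 = np.array([0, 1, 0, 1])

        def loss():
            p = cnn.softmax(net.forward(x, train=True))
            return -np.mean(np.log(p[np.arange(4), y01]))

        p = cnn.softmax(net.forward(x, train=True))
        d = p.copy()
        d[np.arange(4), y01] -= 1
        net.backward(d)

        check_rng = np.random.default_rng(1)
        for layer in net.layers:
            params = layer.params()
            for k, prm in enumerate(params):
                if isinstance(layer, cnn.Conv2D) and k == 1:
                    assert np.abs(prm.grad).max() < 1e-8  # BN cancels conv bias
                    continue
                flat = prm.value.reshape(-1)
                for _ in range(4):
                    j = check_rng.integers(flat.size)
                    eps, old = 1e-6, flat[j]
                    flat[j] = old + eps
                    lp = loss()
                    flat[j] = old - eps
                    lm = loss()
                    flat[j] = old
                    num = (lp - lm) / (2 * eps)
                    ana = prm.grad.reshape(-1)[j]
                    assert num == pytest.approx(ana, rel=1e-4, abs=1e-9)

    def test_fast_conv_paths_match_reference(self, rng):
        """The Toeplitz (tall-kernel) and shift-add (1xk) conv paths agree
        with scipy's correlate2d."""
        from scipy.signal import correlate2d

        x = rng.standard_normal((2, 1, 30, 40)).astype(np.float32)
        w = rng.standard_normal((3, 1, 12, 2)).astype(np.float32)
        got = cnn._conv_tall_forward(x, w)
        for b in range(2):
            for f in range(3):
                ref = correlate2d(x[b, 0].astype(float), w[f, 0].astype(float),
                                  mode="valid")
                np.testing.assert_allclose(got[b, f], ref, atol=1e-4)

        x2 = rng.standard_normal((2, 5, 9, 30)).astype(np.float32)
        w2 = rng.standard_normal((4, 5, 1, 7)).astype(np.float32)
        got2 = cnn._conv_flat_forward(x2, w2)
        for b in range(2):
            for f in range(4):
                ref = sum(
                    correlate2d(x2[b, c].astype(float), w2[f, c].astype(float),
                                mode="valid")
                    for c in range(5)
                )
                np.testing.assert_allclose(got2[b, f], ref, atol=1e-4)


class TestTrainSpec:
    def test_staircase_lr_schedule(self):
        """lr = 0.01 for epochs 0-9, 0.001 for 10-19, 1e-4 for 20-29, ..."""
        spec = cnn.TrainSpec()
        for epoch in range(35):
            assert spec.lr_at(epoch) == pytest.approx(0.01 * 0.1 ** (epoch // 10))


class TestTraining:
    def _separable_data(self, rng, n=24, spec=None):
        spec = spec or _tiny_spec()
        x = rng.standard_normal((n, 1, spec.spatial, spec.temporal)).astype(np.float32)
        y = np.where(np.arange(n) % 2 == 0, 1, 2)
        x[y == 2, :, : spec.spatial // 2, :] += 3.0  # class-conditional mean shift
        return x, y

    def test_separable_data_learned(self):
        """A strong class-conditional mean shift is fit to >= 95% training
        accuracy within 50 epochs."""
        rng = np.random.default_rng(0)
        spec = _tiny_spec(dropout_rate=0.5)
        x, y = self._separable_data(rng, n=24, spec=spec)
        net = cnn.ConvNet(spec, np.random.default_rng(5))
        model = cnn.train(net, x, y, cnn.TrainSpec(max_epochs=50, batch_size=24, seed=5))
        assert model.provenance["train_accuracy"] >= 0.95

    def test_shuffled_labels_stay_at_chance(self):
        """Label-shuffled training generalizes at chance level on held-out
        data (permutation control)."""
        rng = np.random.default_rng(2)
        spec = _tiny_spec(dropout_rate=0.5)
        x, y = self._separable_data(rng, n=40, spec=spec)
        y_shuf = np.random.default_rng(3).permutation(y[:24])
        net = cnn.ConvNet(spec, np.random.default_rng(5))
        model = cnn.train(net, x[:24], y_shuf,
                          cnn.TrainSpec(max_epochs=30, batch_size=24, seed=5))
        held = model.predict_classes(x[24:])
        acc = np.mean(held == y[24:])
        assert 0.2 <= acc <= 0.8

    def test_same_seed_same_loss(self, rng):
        x, y = self._separable_data(np.random.default_rng(4))
        spec = cnn.TrainSpec(max_epochs=3, batch_size=8, seed=9)
        m1 = cnn.train(cnn.ConvNet(_tiny_spec(), np.random.default_rng(9)), x, y, spec)
        m2 = cnn.train(cnn.ConvNet(_tiny_spec(), np.random.default_rng(9)), x, y, spec)
        assert m1.provenance["final_loss"] == m2.provenance["final_loss"]

    def test_single_class_rejected(self, rng):
        x = rng.standard_normal((6, 1, 16, 40)).astype(np.float32)
        net = cnn.ConvNet(_tiny_spec(), np.random.default_rng(0))
        with pytest.raises(cnn.TrainingError, match="single class"):
            cnn.train(net, x, np.ones(6), cnn.TrainSpec(max_epochs=1))


class TestPredict:
    class _Fixed(cnn.TrainedModel):
        def __init__(self, probs):
            self._p = np.asarray(probs, dtype=float)

        def predict_proba(self, x):
            return self._p

    def test_argmax_and_tie_break(self):
        """(0.7, 0.3) -> walk; exact ties resolve to walk (conservative)."""
        model = self._Fixed([[0.7, 0.3], [0.3, 0.7], [0.5, 0.5]])
        np.testing.assert_array_equal(model.predict_classes(None), [1, 2, 1])

    def test_batch_order_preserved(self, rng):
        net = cnn.ConvNet(_tiny_spec(), np.random.default_rng(0))
        model = cnn.TrainedModel(net, cnn.TrainSpec())
        x = rng.standard_normal((5, 1, 16, 40)).astype(np.float32)
        batch = model.predict_classes(x)
        singles = [model.predict_classes(x[i : i + 1])[0] for i in range(5)]
        np.testing.assert_array_equal(batch, singles)

    def test_shape_mismatch_reported(self, rng):
        net = cnn.ConvNet(_tiny_spec(), np.random.default_rng(0))
        model = cnn.TrainedModel(net, cnn.TrainSpec())
        with pytest.raises(ValueError, match="expected"):
            model.predict_classes(rng.standard_normal((1, 1, 10, 40)))


class TestSerialization:
    def test_save_load_bit_identical_inference(self, tmp_path, rng):
        spec = _tiny_spec()
        x = rng.standard_normal((6, 1, 16, 40)).astype(np.float32)
        y = np.where(np.arange(6) % 2 == 0, 1, 2)
        net = cnn.ConvNet(spec, np.random.default_rng(1))
        model = cnn.train(net, x, y, cnn.TrainSpec(max_epochs=2, batch_size=6, seed=1))
        path = tmp_path / "model.npz"
        model.save(path)
        back = cnn.TrainedModel.load(path)
        np.testing.assert_array_equal(model.predict_proba(x), back.predict_proba(x))
        assert back.provenance["train_accuracy"] == model.provenance["train_accuracy"]
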
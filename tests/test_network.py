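import numpy as np
import pytest
from scipy.special import log_softmax, softmax

from tailmix.distill import DistillConfig
from tailmix.network import CompactConvClassifier, SmallImageClassifier, load_backbone


def fresh_conv(**kw):
    defaults = dict(image_shape=(16, 16, 3), conv_channels=(4, 6),
                    n_classes=3, epochs=2, random_state=0)
    defaults.update(kw)
    return CompactConvClassifier(**defaults)


def blobs(rng, n_per=30, n_classes=3, shape=(16, 16, 3)):
    """Linearly separable colour blobs as flat image tensors."""
    X, y = [], []
    for c in range(n_classes):
        base = np.zeros(shape)
        base[..., c % 3] = 0.8
        for _ in range(n_per):
            X.append(np.clip(base + rng.normal(0, 0.05, size=shape), 0, 1))
            y.append(c)
    return np.array(X), np.array(y)


@pytest.mark.parametrize("make", [
    lambda: SmallImageClassifier(hidden_units=8, n_classes=3, momentum=0.0,
                                 learning_rate=0.0, center_inputs=False,
                                 epochs=1, random_state=0),
    lambda: fresh_conv(image_shape=(8, 8, 3), conv_channels=(4, 5),
                       momentum=0.0, learning_rate=0.0,
                       center_inputs=False, epochs=1),
])
def test_gradients_match_finite_differences(make, rng):
    est = make()
    X = rng.normal(size=(3, 8, 8, 3)) if isinstance(est, CompactConvClassifier) \
        else rng.normal(size=(3, 12))
    y = np.array([0, 1, 2])
    est.fit(X, y)
    T = np.eye(3)[y]
    tl = rng.normal(size=(3, 3))
    kd = DistillConfig(temperature=0.5, weight=1.3)
    mask = np.array([True, False, True])

    def loss_at():
        _, logits = est._forward_cached(est._prepare_X(X))
        L = float(-(T * log_softmax(logits, axis=1)).sum(1).mean())
        idx = np.flatnonzero(mask)
        pt = softmax(tl[idx] / kd.temperature, axis=1)
        L += kd.weight * float(
            -(pt * log_softmax(logits[idx] / kd.temperature, axis=1)).sum(1).sum()
            / len(X)
        )
        return L

    cache, logits = est._forward_cached(est._prepare_X(X))
    g = (softmax(logits, axis=1) - T) / len(X)
    idx = np.flatnonzero(mask)
    q = softmax(logits[idx] / kd.temperature, axis=1)
    pt = softmax(tl[idx] / kd.temperature, axis=1)
    g[idx] += kd.weight * (q - pt) / (kd.temperature * len(X))
    grads = est._backward(cache, g)

    for prm, grad in zip(est._params(), grads):
        pos = tuple(rng.integers(0, s) for s in prm.shape)
        orig = prm[pos]
        eps = 1e-6
        prm[pos] = orig + eps
        up = loss_at()
        prm[pos] = orig - eps
        down = loss_at()
        prm[pos] = orig
        assert np.isclose((up - down) / (2 * eps), grad[pos], rtol=1e-4, atol=1e-9)


class TestTraining:
    def test_initial_loss_is_log_n_classes(self, rng):
        """With a zero step size the recorded epoch loss is the random-init
        cross-entropy, which on balanced data is ln(n_classes)."""
        X, y = blobs(rng, n_per=10)
        clf = fresh_conv(learning_rate=0.0, epochs=1).fit(X, y)
        assert clf.loss_curve_[0] == pytest.approx(np.log(3), abs=0.15)

    def test_learns_separable_blobs(self, rng):
        X, y = blobs(rng)
        clf = fresh_conv(epochs=10).fit(X, y)
        assert (clf.predict(X) == y).mean() >= 0.95

    def test_same_seed_reproducible(self, rng):
        X, y = blobs(rng, n_per=10)
        a = fresh_conv(epochs=3).fit(X, y)
        b = fresh_conv(epochs=3).fit(X, y)
        np.testing.assert_array_equal(a.loss_curve_, b.loss_curve_)
        np.testing.assert_array_equal(a.decision_function(X), b.decision_function(X))

    def test_soft_targets_match_hard_labels(self, rng):
        X, y = blobs(rng, n_per=8)
        onehot = np.eye(3)[y]
        a = fresh_conv(epochs=3).fit(X, y)
        b = fresh_conv(epochs=3).fit(X, onehot)
        np.testing.assert_allclose(a.loss_curve_, b.loss_curve_)

    def test_predict_proba_rows_sum_to_one(self, rng):
        X, y = blobs(rng, n_per=5)
        clf = fresh_conv().fit(X, y)
        p = clf.predict_proba(X)
        np.testing.assert_allclose(p.sum(axis=1), 1.0)
        assert p.shape == (len(X), 3)

    def test_transform_feature_dimension(self, rng):
        X, y = blobs(rng, n_per=5)
        clf = fresh_conv(conv_channels=(4, 7)).fit(X, y)
        assert clf.transform(X).shape == (len(X), 7)

    def test_layer_embedding_dimensions(self, rng):
        X, y = blobs(rng, n_per=5)
        clf = fresh_conv(conv_channels=(4, 7)).fit(X, y)
        assert clf.layer_embedding(X, layer=0).shape == (len(X), 4)
        np.testing.assert_array_equal(
            clf.layer_embedding(X, layer=-1), clf.transform(X)
        )

    def test_partial_train_continues(self, rng):
        X, y = blobs(rng, n_per=8)
        clf = fresh_conv(epochs=2).fit(X, y)
        n_before = len(clf.loss_curve_)
        clf.partial_train(X, y, epochs=2, learning_rate=0.01)
        assert len(clf.loss_curve_) == n_before + 2

    def test_copy_weights_transfers_predictions(self, rng):
        X, y = blobs(rng, n_per=8)
        teacher = fresh_conv(epochs=5).fit(X, y)
        student = fresh_conv(epochs=1)
        student.copy_weights_from(teacher)
        np.testing.assert_array_equal(
            student.decision_function(X), teacher.decision_function(X)
        )

    def test_mlp_backbone_trains(self, rng):
        X, y = blobs(rng, n_per=15)
        clf = SmallImageClassifier(hidden_units=16, n_classes=3, epochs=10,
                                   random_state=0).fit(X, y)
        assert (clf.predict(X) == y).mean() >= 0.9


class TestPersistence:
    @pytest.mark.parametrize("kind", ["conv", "mlp"])
    def test_save_load_roundtrip(self, kind, rng, tmp_path):
        X, y = blobs(rng, n_per=6)
        if kind == "conv":
            clf = fresh_conv(epochs=2).fit(X, y)
        else:
            clf = SmallImageClassifier(hidden_units=8, n_classes=3, epochs=2,
                                       random_state=0).fit(X, y)
        path = tmp_path / "model.npz"
        clf.save(path)
        again = load_backbone(path)
        assert type(again) is type(clf)
        np.testing.assert_array_equal(
            again.decision_function(X), clf.decision_function(X)
        )


def test_sklearn_params_clone_contract():
    from sklearn.base import clone

    est = fresh_conv(conv_channels=(3, 5), learning_rate=0.05)
    dup = clone(est)
    assert dup.get_params() == est.get_params()
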
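"""Compact neural backbones for desk-scale image classification.

Two architectures share one SGD trainer (mini-batch gradient descent,
momentum 0.9, cosine learning-rate schedule, soft-target cross-entropy, and
an optional knowledge-distillation term against frozen teacher logits):

``CompactConvClassifier``
    Two stride-2 3x3 convolution layers followed by a dense feature layer —
    the default backbone.  Its local receptive fields make patch-composed
    training images (CutMix) behave as in full-scale convolutional networks:
    each pasted region contributes evidence for its own source class.
``SmallImageClassifier``
    A single-hidden-layer perceptron on raw pixels; cheaper, but its global
    features make it a deliberately crude reference backbone.

Both follow the scikit-learn estimator contract (``fit`` / ``predict`` /
``predict_proba`` / ``transform`` / ``get_params``) and accept either hard
integer labels or soft probability-vector targets, so area-mixed CutMix
labels train correctly.  ``transform`` exposes the penultimate activations
used for herding and cosine donor retrieval; ``decision_function`` exposes
logits for distillation.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import log_softmax, softmax
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .distill import DistillConfig

__all__ = ["SmallImageClassifier", "CompactConvClassifier", "load_backbone"]


def _as_soft_targets(y, n_classes: int) -> np.ndarray:
    """Promote integer labels to one-hot rows; pass soft rows through."""
    y = np.asarray(y)
    if y.ndim == 1:
        out = np.zeros((len(y), n_classes))
        out[np.arange(len(y)), y.astype(int)] = 1.0
        return out
    if y.shape[1] != n_classes:
        raise ValueError(f"soft targets have {y.shape[1]} columns, expected {n_classes}")
    return y.astype(np.float64)


class _SGDBackboneBase(ClassifierMixin, BaseEstimator):
    """Shared SGD training loop over an architecture-specific forward/backward."""

    # subclasses define: _init_params(d, c), _forward_cached(X) -> (cache, logits),
    # _backward(cache, g_logits) -> list of grads aligned with self._params(),
    # _penultimate(X), and _prepare_X.

    def _params(self) -> list[np.ndarray]:
        raise NotImplementedError

    def _epoch_lr(self, epoch: int, total: int) -> float:
        if self.lr_schedule == "constant":
            return self.learning_rate
        if self.lr_schedule == "cosine":
            return self.learning_rate * 0.5 * (1 + np.cos(np.pi * epoch / max(total, 1)))
        raise ValueError(f"unknown lr_schedule: {self.lr_schedule!r}")

    def _step(self, Xb, Tb, lr, teacher_logits, kd_mask, kd) -> float:
        B = len(Xb)
        cache, logits = self._forward_cached(Xb)
        log_p = log_softmax(logits, axis=1)
        p = np.exp(log_p)
        loss = float(-(Tb * log_p).sum(axis=1).mean())
        g_logits = (p - Tb) / B

        if kd is not None and kd.weight > 0 and kd_mask is not None and kd_mask.any():
            # per-batch loss is (1/B) sum_i [CE_i + lambda*1{i in Ds}*KD_i];
            # normalizing by B keeps the KD per-sample gradient on the CE
            # scale no matter how many KD-scope samples land in the batch
            T = kd.temperature
            scale = kd.weight * (T * T if kd.t_squared else 1.0)
            idx = np.flatnonzero(kd_mask)
            q = softmax(logits[idx] / T, axis=1)
            pt = softmax(teacher_logits[idx] / T, axis=1)
            loss += scale * float(
                -(pt * log_softmax(logits[idx] / T, axis=1)).sum(axis=1).sum() / B
            )
            g_logits[idx] += scale * (q - pt) / (T * B)

        grads = self._backward(cache, g_logits)
        if self.weight_decay:
            for g, prm in zip(grads, self._params()):
                if prm.ndim > 1:
                    g += self.weight_decay * prm
        for v, g, prm in zip(self._velocity, grads, self._params()):
            v *= self.momentum
            v -= lr * g
            prm += v
        return loss

    def _run_epochs(self, X, T, epochs, lr_for_epoch,
                    teacher_logits=None, kd_mask=None, kd=None) -> None:
        n = len(X)
        for e in range(epochs):
            lr = lr_for_epoch(e)
            order = self._epoch_rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                b = order[start : start + self.batch_size]
                losses.append(
                    self._step(
                        X[b], T[b], lr,
                        None if teacher_logits is None else teacher_logits[b],
                        None if kd_mask is None else kd_mask[b],
                        kd,
                    )
                )
            self.loss_curve_.append(float(np.mean(losses)))

    # ------------------------------------------------------------- public API

    def fit(self, X, y, teacher_logits=None, kd_mask=None, kd: DistillConfig | None = None):
        """Train for ``epochs`` passes; ``y`` may be int labels or soft rows."""
        X = self._prepare_X(X)
        y_arr = np.asarray(y)
        if self.n_classes is not None:
            c = self.n_classes
            self.classes_ = np.arange(c)
        elif y_arr.ndim == 1:
            self.classes_ = np.unique(y_arr)
            c = len(self.classes_)
            y_arr = np.searchsorted(self.classes_, y_arr)
        else:
            c = y_arr.shape[1]
            self.classes_ = np.arange(c)
        targets = _as_soft_targets(y_arr, c)

        already = self.warm_start and hasattr(self, "loss_curve_")
        if not already:
            self._init_params(X.shape[1:], c)
            self.n_features_in_ = int(np.prod(X.shape[1:]))
        self._run_epochs(
            X, targets, self.epochs,
            lambda e: self._epoch_lr(e, self.epochs),
            teacher_logits=teacher_logits,
            kd_mask=None if kd_mask is None else np.asarray(kd_mask, dtype=bool),
            kd=kd,
        )
        return self

    def partial_train(self, X, y, epochs=1, learning_rate=None,
                      teacher_logits=None, kd_mask=None, kd=None):
        """Continue training with an externally managed learning rate.

        Drives one (or a few) epochs at a fixed step size so a caller can
        inject fresh CutMix recipes every epoch while owning the schedule.
        """
        check_is_fitted(self, "loss_curve_")
        X = self._prepare_X(X)
        targets = _as_soft_targets(np.asarray(y), len(self.classes_))
        lr = self.learning_rate if learning_rate is None else learning_rate
        self._run_epochs(
            X, targets, epochs, lambda e: lr,
            teacher_logits=teacher_logits,
            kd_mask=None if kd_mask is None else np.asarray(kd_mask, dtype=bool),
            kd=kd,
        )
        return self

    def copy_weights_from(self, other):
        """Warm-start this network from another's trained parameters."""
        check_is_fitted(other, "loss_curve_")
        self._adopt_params([p.copy() for p in other._params()])
        self._velocity = [np.zeros_like(p) for p in self._params()]
        self._epoch_rng = np.random.default_rng(
            None if self.random_state is None else self.random_state + 1
        )
        self.loss_curve_ = []
        self.classes_ = other.classes_.copy()
        self.n_features_in_ = other.n_features_in_
        return self

    def decision_function(self, X) -> np.ndarray:
        """Raw logits, one row per sample."""
        check_is_fitted(self, "loss_curve_")
        _, logits = self._forward_cached(self._prepare_X(X))
        return logits

    def predict_proba(self, X) -> np.ndarray:
        return softmax(self.decision_function(X), axis=1)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    def transform(self, X) -> np.ndarray:
        """Penultimate-layer feature embedding."""
        check_is_fitted(self, "loss_curve_")
        return self._penultimate(self._prepare_X(X))

    def save(self, path) -> None:
        check_is_fitted(self, "loss_curve_")
        arrays = {f"p{i}": p for i, p in enumerate(self._params())}
        np.savez(
            path,
            classes=self.classes_,
            arch=np.array(type(self).__name__),
            image_shape=np.array(getattr(self, "image_shape", (0, 0, 0))),
            **arrays,
        )

    @classmethod
    def load(cls, path, **params):
        data = np.load(path)
        est = cls(**params)
        n_params = sum(k.startswith("p") and k[1:].isdigit() for k in data.files)
        est._adopt_params([data[f"p{i}"] for i in range(n_params)])
        est.classes_ = data["classes"]
        est.n_features_in_ = est._infer_n_features()
        est._velocity = [np.zeros_like(p) for p in est._params()]
        est._epoch_rng = np.random.default_rng(
            None if est.random_state is None else est.random_state + 1
        )
        est.loss_curve_ = []
        return est


class SmallImageClassifier(_SGDBackboneBase):
    """Single-hidden-layer perceptron on raw pixels.

    Parameters
    ----------
    hidden_units : width of the hidden (feature) layer, default 128.
    n_classes : fixed output width; inferred from targets when omitted.
    epochs, batch_size, learning_rate, momentum, lr_schedule, weight_decay :
        SGD settings (defaults: 30, 32, 0.1, 0.9, cosine, 0).
    center_inputs : subtract 0.5 from [0, 1] pixel inputs (default True).
    warm_start : keep weights between ``fit`` calls.
    random_state : seed for init and batch shuffling.
    """

    def __init__(
        self,
        hidden_units: int = 128,
        n_classes: int | None = None,
        epochs: int = 30,
        batch_size: int = 32,
        learning_rate: float = 0.1,
        momentum: float = 0.9,
        lr_schedule: str = "cosine",
        weight_decay: float = 0.0,
        center_inputs: bool = True,
        warm_start: bool = False,
        random_state: int | None = None,
    ):
        self.hidden_units = hidden_units
        self.n_classes = n_classes
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.lr_schedule = lr_schedule
        self.weight_decay = weight_decay
        self.center_inputs = center_inputs
        self.warm_start = warm_start
        self.random_state = random_state

    def _prepare_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim > 2:
            X = X.reshape(len(X), -1)
        X = check_array(X)
        return X - 0.5 if self.center_inputs else X

    def _params(self) -> list[np.ndarray]:
        return [self.coefs_[0], self.coefs_[1],
                self.intercepts_[0], self.intercepts_[1]]

    def _adopt_params(self, params) -> None:
        self.coefs_ = [params[0], params[1]]
        self.intercepts_ = [params[2], params[3]]

    def _init_params(self, input_shape, c: int) -> None:
        d = int(np.prod(input_shape))
        rng = np.random.default_rng(self.random_state)
        h = self.hidden_units
        self.coefs_ = [
            rng.normal(0.0, np.sqrt(2.0 / d), size=(d, h)),
            rng.normal(0.0, np.sqrt(2.0 / h), size=(h, c)),
        ]
        self.intercepts_ = [np.zeros(h), np.zeros(c)]
        self._velocity = [np.zeros_like(p) for p in self._params()]
        self._epoch_rng = np.random.default_rng(
            None if self.random_state is None else self.random_state + 1
        )
        self.loss_curve_ = []

    def _forward_cached(self, X):
        hidden = np.maximum(X @ self.coefs_[0] + self.intercepts_[0], 0.0)
        logits = hidden @ self.coefs_[1] + self.intercepts_[1]
        return (X, hidden), logits

    def _backward(self, cache, g_logits):
        X, hidden = cache
        g_W2 = hidden.T @ g_logits
        g_b2 = g_logits.sum(axis=0)
        g_hidden = (g_logits @ self.coefs_[1].T) * (hidden > 0)
        g_W1 = X.T @ g_hidden
        g_b1 = g_hidden.sum(axis=0)
        return [g_W1, g_W2, g_b1, g_b2]

    def _penultimate(self, X):
        return np.maximum(X @ self.coefs_[0] + self.intercepts_[0], 0.0)

    def _infer_n_features(self) -> int:
        return int(self.coefs_[0].shape[0])


def _im2col(X: np.ndarray, stride: int) -> np.ndarray:
    """(B, H, W, C) -> (B, Ho, Wo, 3*3*C) patches, 1-pixel zero padding."""
    Xp = np.pad(X, ((0, 0), (1, 1), (1, 1), (0, 0)))
    win = sliding_window_view(Xp, (3, 3), axis=(1, 2))  # (B, H', W', C, 3, 3)
    win = win[:, ::stride, ::stride]
    b, ho, wo = win.shape[:3]
    return np.ascontiguousarray(win).reshape(b, ho, wo, -1)


def _col2im(g_cols: np.ndarray, in_shape, stride: int) -> np.ndarray:
    """Adjoint of _im2col: scatter patch gradients back to the input."""
    b, h, w, c = in_shape
    g = np.zeros((b, h + 2, w + 2, c))
    bo, ho, wo, _ = g_cols.shape
    g_cols = g_cols.reshape(bo, ho, wo, c, 3, 3)
    rows = stride * np.arange(ho)
    cols = stride * np.arange(wo)
    for ki in range(3):
        for kj in range(3):
            g[:, rows[:, None] + ki, cols[None, :] + kj, :] += g_cols[..., ki, kj]
    return g[:, 1:-1, 1:-1, :]


class CompactConvClassifier(_SGDBackboneBase):
    """Small convolutional network: a stack of stride-2 3x3 conv layers,
    global average pooling, and a linear softmax head.

    With 32x32x3 inputs and the default three conv layers the feature path
    is 32x32x3 -> 16x16xc1 -> 8x8xc2 -> 4x4xc3 -> GAP -> logits.  Global
    average pooling makes class evidence additive over image regions — the
    credit assignment that area-labelled CutMix composites rely on and the
    head design of the residual networks this backbone stands in for —
    while the deepest layer's ~15-pixel receptive fields let surrounding
    context modulate how a pasted patch is encoded, as it does in full-size
    networks.  The pooled activation of the last conv layer is the
    penultimate feature embedding.

    Parameters as in ``SmallImageClassifier`` plus ``conv_channels``
    (one entry per stride-2 layer, default (8, 16, 32)).  ``image_shape``
    must be given as (H, W, C) since inputs may arrive flat.
    """

    def __init__(
        self,
        image_shape: tuple[int, int, int] = (32, 32, 3),
        conv_channels: tuple[int, ...] = (8, 16, 32),
        n_classes: int | None = None,
        epochs: int = 30,
        batch_size: int = 32,
        learning_rate: float = 0.1,
        momentum: float = 0.9,
        lr_schedule: str = "cosine",
        weight_decay: float = 0.0,
        center_inputs: bool = True,
        warm_start: bool = False,
        random_state: int | None = None,
    ):
        self.image_shape = image_shape
        self.conv_channels = conv_channels
        self.n_classes = n_classes
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.lr_schedule = lr_schedule
        self.weight_decay = weight_decay
        self.center_inputs = center_inputs
        self.warm_start = warm_start
        self.random_state = random_state

    def _prepare_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        h, w, c = self.image_shape
        if X.ndim == 2:
            X = X.reshape(len(X), h, w, c)
        if X.shape[1:] != (h, w, c):
            raise ValueError(f"expected images of shape {(h, w, c)}, got {X.shape[1:]}")
        return X - 0.5 if self.center_inputs else X

    def _params(self) -> list[np.ndarray]:
        out = []
        for W, b in zip(self.conv_W_, self.conv_b_):
            out += [W, b]
        out += [self.out_W_, self.out_b_]
        return out

    def _adopt_params(self, params) -> None:
        n_conv = (len(params) - 2) // 2
        self.conv_W_ = [params[2 * i] for i in range(n_conv)]
        self.conv_b_ = [params[2 * i + 1] for i in range(n_conv)]
        self.out_W_, self.out_b_ = params[-2], params[-1]

    def _init_params(self, input_shape, n_out: int) -> None:
        rng = np.random.default_rng(self.random_state)
        self.conv_W_, self.conv_b_ = [], []
        c_in = self.image_shape[2]
        for c_out in self.conv_channels:
            self.conv_W_.append(
                rng.normal(0, np.sqrt(2.0 / (9 * c_in)), size=(9 * c_in, c_out))
            )
            self.conv_b_.append(np.zeros(c_out))
            c_in = c_out
        self.out_W_ = rng.normal(0, np.sqrt(2.0 / c_in), size=(c_in, n_out))
        self.out_b_ = np.zeros(n_out)
        self._velocity = [np.zeros_like(p) for p in self._params()]
        self._epoch_rng = np.random.default_rng(
            None if self.random_state is None else self.random_state + 1
        )
        self.loss_curve_ = []

    def _conv_stack(self, X):
        cols_list, act_list = [], []
        a = X
        for W, b in zip(self.conv_W_, self.conv_b_):
            cols = _im2col(a, stride=2)
            a = np.maximum(cols @ W + b, 0.0)
            cols_list.append(cols)
            act_list.append(a)
        return cols_list, act_list

    def _forward_cached(self, X):
        cols_list, act_list = self._conv_stack(X)
        gap = act_list[-1].mean(axis=(1, 2))
        logits = gap @ self.out_W_ + self.out_b_
        return (X, cols_list, act_list, gap), logits

    def _backward(self, cache, g_logits):
        X, cols_list, act_list, gap = cache
        g_out_W = gap.T @ g_logits
        g_out_b = g_logits.sum(axis=0)
        g_gap = g_logits @ self.out_W_.T
        last = act_list[-1]
        n_cells = last.shape[1] * last.shape[2]
        g_a = (g_gap[:, None, None, :] / n_cells) * (last > 0)
        conv_grads: list[np.ndarray] = []
        for i in range(len(self.conv_W_) - 1, -1, -1):
            cols, a = cols_list[i], act_list[i]
            g_W = cols.reshape(-1, cols.shape[-1]).T @ g_a.reshape(-1, a.shape[-1])
            g_b = g_a.sum(axis=(0, 1, 2))
            conv_grads[:0] = [g_W, g_b]
            if i > 0:
                g_cols = g_a @ self.conv_W_[i].T
                prev = act_list[i - 1]
                g_a = _col2im(g_cols, prev.shape, stride=2) * (prev > 0)
        return conv_grads + [g_out_W, g_out_b]

    def _penultimate(self, X):
        _, act_list = self._conv_stack(X)
        return act_list[-1].mean(axis=(1, 2))

    def layer_embedding(self, X, layer: int = -1) -> np.ndarray:
        """Globally averaged activation of one conv layer.

        ``layer`` indexes the conv stack (0 = first/lowest).  Lower layers
        give generic appearance embeddings (colour, texture); the last layer
        equals ``transform``.
        """
        check_is_fitted(self, "loss_curve_")
        _, act_list = self._conv_stack(self._prepare_X(X))
        return act_list[layer].mean(axis=(1, 2))

    def _infer_n_features(self) -> int:
        return int(np.prod(self.image_shape))


def load_backbone(path, **params):
    """Load a saved backbone, dispatching on the architecture it recorded."""
    data = np.load(path)
    arch = str(data["arch"]) if "arch" in data.files else "SmallImageClassifier"
    if arch == "CompactConvClassifier":
        shape = tuple(int(v) for v in data["image_shape"])
        params.setdefault("image_shape", shape)
        return CompactConvClassifier.load(path, **params)
    return SmallImageClassifier.load(path, **params)
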
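"""Two-phase training for long-tailed image classification.

Phase I trains the backbone on every training image with plain cross-entropy;
the result serves three roles downstream: feature extractor, cosine-retrieval
index, and frozen distillation teacher.  Phase II re-trains on a class-
balanced set — every class at ``floor(m)`` effective samples, where
``m = D / n`` is the mean class size — built from herding-selected head
samples, original tail samples, and CutMix composites whose donors come from
the removed-head pool.  A temperature-scaled distillation term on the
selected head samples retains what phase I learned from the removed ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .cutmix import (
    MixRecipe,
    compose_recipe,
    oversample_tail,
    read_recipe_log,
    write_recipe_log,
)
from .distill import DistillConfig
from .features import FeatureMatrix, extract_features
from .herding import HeadPartition, undersample_heads
from .network import CompactConvClassifier, SmallImageClassifier


def make_backbone(
    architecture: str,
    image_shape: tuple[int, int, int],
    n_classes: int,
    epochs: int,
    **sgd,
):
    """Construct a backbone estimator: compact convnet (default) or MLP."""
    if architecture == "conv":
        return CompactConvClassifier(
            image_shape=image_shape, n_classes=n_classes, epochs=epochs, **sgd
        )
    if architecture == "mlp":
        return SmallImageClassifier(n_classes=n_classes, epochs=epochs, **sgd)
    raise ValueError(f"unknown architecture: {architecture!r}")

__all__ = ["TwoPhaseClassifier", "BalancedPlan", "train_baseline", "BASELINE_STRATEGIES"]


@dataclass
class BalancedPlan:
    """Serializable phase-II training plan: who is kept, who is synthesized."""

    m: float
    target: int                      # floor(m), per-class effective count
    head_classes: list[int]
    tail_classes: list[int]
    partition: HeadPartition         # head classes: kept (Ds) / removed (Dr)
    recipes: list[MixRecipe]         # tail-class composites

    def base_sample_ids(self, labels: np.ndarray) -> np.ndarray:
        """Real (non-synthetic) sample ids in the balanced set: Ds + tails."""
        labels = np.asarray(labels)
        tail_mask = np.isin(labels, self.tail_classes)
        tail_ids = np.flatnonzero(tail_mask)
        return np.concatenate([self.partition.all_selected(), tail_ids]).astype(np.int64)

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.partition.to_csv(d / "head_partition.csv")
        write_recipe_log(self.recipes, d / "recipes.jsonl")
        (d / "plan.json").write_text(
            json.dumps(
                {
                    "m": self.m,
                    "target": self.target,
                    "head_classes": self.head_classes,
                    "tail_classes": self.tail_classes,
                }
            )
        )

    @classmethod
    def load(cls, directory: str | Path) -> "BalancedPlan":
        d = Path(directory)
        meta = json.loads((d / "plan.json").read_text())
        return cls(
            m=meta["m"],
            target=meta["target"],
            head_classes=list(meta["head_classes"]),
            tail_classes=list(meta["tail_classes"]),
            partition=HeadPartition.from_csv(d / "head_partition.csv"),
            recipes=read_recipe_log(d / "recipes.jsonl"),
        )


class TwoPhaseClassifier(ClassifierMixin, BaseEstimator):
    """Head-undersampling + tail-oversampling classifier with distillation.

    Fits the full two-phase framework on images ``X`` of shape
    ``(n, H, W, C)`` (or flat ``(n, H*W*C)`` with ``image_shape`` set) and
    integer labels ``y``.  Head classes (count > m) are cut to ``floor(m)``
    samples by herding; tail classes (count <= m) are lifted to ``floor(m)``
    with visual-similarity-aware CutMix; a KD term (teacher = phase-I model,
    default temperature 0.5) is applied to the selected head samples.

    Parameters mirror the study conditions: 50 + 100 epochs, SGD with
    momentum 0.9, initial learning rate 0.1 under one cosine decay spanning
    both phases, k = 1 donor per composite drawn from a batch-sized sample
    of the removed pool, composites carrying the tail label.  Scale
    ``epochs_phase1``/``epochs_phase2`` down for desk-size experiments.

    Attributes (after fit)
    ----------------------
    teacher_ : phase-I backbone (frozen).
    student_ : phase-II backbone used for prediction.
    plan_ : BalancedPlan with the head partition and last-epoch recipes.
    head_classes_, tail_classes_ : the m-threshold split.
    m_ : mean samples per class (real-valued).
    features_ : phase-I feature matrix of the training set.
    recipe_log_ : recipes of every phase-II epoch (list per epoch).
    """

    def __init__(
        self,
        architecture: str = "conv",
        hidden_units: int = 128,
        epochs_phase1: int = 50,
        epochs_phase2: int = 100,
        batch_size: int = 32,
        learning_rate: float = 0.1,
        momentum: float = 0.9,
        weight_decay: float = 0.0,
        kd_temperature: float = 0.5,
        kd_weight: float = 1.0,
        kd_scope: str = "selected-head-only",
        kd_t_squared: bool = False,
        head_selection: str = "herding",
        herding_method: str = "nearest-mean",
        herding_layer: int | None = 0,
        normalize_features: bool = True,
        oversample_policy: str = "visual",
        k: int = 1,
        s_range: tuple[float, float] = (0.0, 1.0),
        label_policy: str = "tail-only",
        br_size: int = 32,
        recipes_per_epoch: bool = True,
        warm_start_phase2: bool = True,
        image_shape: tuple[int, int, int] | None = None,
        teacher: SmallImageClassifier | None = None,
        random_state: int | None = None,
    ):
        self.architecture = architecture
        self.hidden_units = hidden_units
        self.epochs_phase1 = epochs_phase1
        self.epochs_phase2 = epochs_phase2
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.kd_temperature = kd_temperature
        self.kd_weight = kd_weight
        self.kd_scope = kd_scope
        self.kd_t_squared = kd_t_squared
        self.head_selection = head_selection
        self.herding_method = herding_method
        self.herding_layer = herding_layer
        self.normalize_features = normalize_features
        self.oversample_policy = oversample_policy
        self.k = k
        self.s_range = s_range
        self.label_policy = label_policy
        self.br_size = br_size
        self.recipes_per_epoch = recipes_per_epoch
        self.warm_start_phase2 = warm_start_phase2
        self.image_shape = image_shape
        self.teacher = teacher
        self.random_state = random_state

    # ----------------------------------------------------------------- utils

    def _images(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Return (4-D image stack, flat 2-D matrix)."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 4:
            return X, X.reshape(len(X), -1)
        if X.ndim == 2:
            if self.image_shape is None:
                raise ValueError("flat input requires image_shape=(H, W, C)")
            h, w, c = self.image_shape
            return X.reshape(len(X), h, w, c), X
        raise ValueError(f"expected 2-D or 4-D input, got ndim={X.ndim}")

    def _backbone(self, epochs: int, seed_offset: int):
        rs = None if self.random_state is None else self.random_state + seed_offset
        sgd = dict(
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            momentum=self.momentum,
            weight_decay=self.weight_decay,
            lr_schedule="cosine",
            random_state=rs,
        )
        if self.architecture == "mlp":
            sgd["hidden_units"] = self.hidden_units
        return make_backbone(
            self.architecture, self._image_shape_, self.n_classes_, epochs, **sgd
        )

    # ------------------------------------------------------------------- fit

    def fit(self, X, y):
        X4, X2 = self._images(X)
        y = np.asarray(y, dtype=int)
        if len(y) != len(X2):
            raise ValueError("X and y lengths differ")
        self.classes_ = np.unique(y)
        self.n_classes_ = len(self.classes_)
        if not np.array_equal(self.classes_, np.arange(self.n_classes_)):
            raise ValueError("labels must be 0..n_classes-1")
        self.n_features_in_ = X2.shape[1]
        h, w = X4.shape[1], X4.shape[2]
        self._image_shape_ = (h, w, X4.shape[3])
        rng = np.random.default_rng(self.random_state)

        # ---- phase I: standard training on all data (or an injected,
        # already-trained teacher from the same data/seed/architecture)
        if self.teacher is not None:
            check_is_fitted(self.teacher, "loss_curve_")
            self.teacher_ = self.teacher
        else:
            self.teacher_ = self._backbone(self.epochs_phase1, seed_offset=0).fit(X2, y)

        # ---- statistics and head/tail split (count > m vs <= m)
        counts = pd.Series(y).value_counts().sort_index()
        self.m_ = float(counts.sum() / len(counts))
        target = int(np.floor(self.m_))
        self.head_classes_ = [int(c) for c in counts.index[counts > self.m_]]
        self.tail_classes_ = [int(c) for c in counts.index[counts <= self.m_]]

        # ---- phase-I features: cosine donor retrieval uses the penultimate
        # embedding; herding ranks in a lower-layer (generic appearance)
        # space so selection reflects typicality, not classifier margin
        self.features_ = extract_features(
            self.teacher_, X2, normalize=self.normalize_features
        )

        # ---- head partition
        if self.head_selection == "herding":
            herding_feats = (
                self.features_
                if self.herding_layer is None
                else extract_features(
                    self.teacher_, X2,
                    normalize=self.normalize_features,
                    layer=self.herding_layer,
                )
            )
            partition = undersample_heads(
                y, herding_feats, self.head_classes_, self.m_,
                method=self.herding_method,
            )
        elif self.head_selection == "random":
            selected, removed = {}, {}
            for c in self.head_classes_:
                ids = self.features_.sample_ids[y == c]
                perm = rng.permutation(ids)
                selected[c] = np.sort(perm[:target]).astype(np.int64)
                removed[c] = np.sort(perm[target:]).astype(np.int64)
            partition = HeadPartition(selected=selected, removed=removed)
        else:
            raise ValueError(f"unknown head_selection: {self.head_selection!r}")

        plan = BalancedPlan(
            m=self.m_,
            target=target,
            head_classes=self.head_classes_,
            tail_classes=self.tail_classes_,
            partition=partition,
            recipes=[],
        )

        # ---- phase II
        base_ids = plan.base_sample_ids(y)
        X_base, y_base = X2[base_ids], y[base_ids]
        teacher_logits_base = self.teacher_.decision_function(X_base)
        onehot = np.zeros((len(y_base), self.n_classes_))
        onehot[np.arange(len(y_base)), y_base] = 1.0

        selected_set = set(int(s) for s in partition.all_selected())
        in_ds = np.array([int(i) in selected_set for i in base_ids])

        student = self._backbone(self.epochs_phase2, seed_offset=1)
        if self.warm_start_phase2:
            student.copy_weights_from(self.teacher_)
        else:
            student._init_params(X4.shape[1:], self.n_classes_)
            student.classes_ = np.arange(self.n_classes_)
            student.n_features_in_ = X2.shape[1]

        kd = DistillConfig(
            temperature=self.kd_temperature,
            weight=self.kd_weight,
            scope=self.kd_scope,
            t_squared=self.kd_t_squared,
        )
        donor_pool = partition.all_removed()
        oversampling = self.oversample_policy != "none" and len(self.tail_classes_) > 0

        self.recipe_log_ = []
        recipes: list[MixRecipe] = []
        for epoch in range(self.epochs_phase2):
            if oversampling and (self.recipes_per_epoch or epoch == 0):
                recipes = oversample_tail(
                    labels=y,
                    tail_ids=self.tail_classes_,
                    donor_pool=donor_pool,
                    features=self.features_,
                    m=self.m_,
                    image_size=(w, h),
                    k=self.k,
                    br_size=self.br_size,
                    s_range=self.s_range,
                    policy=self.oversample_policy,
                    label_policy=self.label_policy,
                    n_classes=self.n_classes_,
                    rng=rng,
                )
                self.recipe_log_.append(recipes)
            if recipes:
                composites = np.stack(
                    [compose_recipe(r, X4).reshape(-1) for r in recipes]
                )
                labels_syn = np.stack([r.label for r in recipes])
                X_epoch = np.concatenate([X_base, composites])
                Y_epoch = np.concatenate([onehot, labels_syn])
                t_logits = np.concatenate(
                    [teacher_logits_base, self.teacher_.decision_function(composites)]
                )
                if kd.scope == "all-samples":
                    mask = np.ones(len(X_epoch), dtype=bool)
                else:
                    mask = np.concatenate(
                        [in_ds, np.zeros(len(composites), dtype=bool)]
                    )
            else:
                X_epoch, Y_epoch, t_logits = X_base, onehot, teacher_logits_base
                mask = (
                    np.ones(len(X_base), dtype=bool)
                    if kd.scope == "all-samples"
                    else in_ds
                )
            # one cosine schedule spans both phases (total = e1 + e2 epochs),
            # so phase II continues the decay where phase I left off instead
            # of restarting at the full step size and scrambling the
            # warm-started weights
            total = self.epochs_phase1 + self.epochs_phase2
            lr = student._epoch_lr(self.epochs_phase1 + epoch, total)
            student.partial_train(
                X_epoch,
                Y_epoch,
                epochs=1,
                learning_rate=lr,
                teacher_logits=t_logits,
                kd_mask=mask if kd.weight > 0 else None,
                kd=kd,
            )

        plan.recipes = recipes
        self.plan_ = plan
        self.student_ = student
        return self

    def build_balanced_set(self, X, y) -> BalancedPlan:
        """The phase-II plan implied by the fitted teacher (no training)."""
        check_is_fitted(self, "plan_")
        return self.plan_

    # ------------------------------------------------------------ prediction

    @staticmethod
    def _flat(X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        return X.reshape(len(X), -1) if X.ndim > 2 else X

    def predict(self, X):
        check_is_fitted(self, "student_")
        return self.student_.predict(self._flat(X))

    def predict_proba(self, X):
        check_is_fitted(self, "student_")
        return self.student_.predict_proba(self._flat(X))

    def transform(self, X):
        """Phase-I feature embedding of new images."""
        check_is_fitted(self, "teacher_")
        return self.teacher_.transform(self._flat(X))


BASELINE_STRATEGIES = (
    "baseline-ce",
    "ros",
    "rus",
    "hus",
    "hus-kd",
    "cutmix-random",
    "ours",
)


def train_baseline(
    X,
    y,
    strategy: str,
    teacher: SmallImageClassifier | None = None,
    **params,
):
    """Train one method of the comparison suite and return the fitted model.

    Strategies
    ----------
    baseline-ce : plain cross-entropy on the long-tailed data for the full
        epoch budget (phase-1 + phase-2 epochs).
    ros : tail classes duplicated uniformly at random up to ``floor(m)``,
        then plain training.
    rus : heads randomly cut to ``floor(m)``, then plain training.
    hus : heads cut to ``floor(m)`` by herding in the feature space of a
        separately trained extractor, then plain training — isolating the
        selection method as the only difference from rus.
    hus-kd : the two-phase framework with oversampling disabled (herding
        undersampling plus the distillation term).
    cutmix-random : the full pipeline with donors drawn uniformly from the
        removed pool (context-rich oversampling without visual retrieval).
    ours : the full visual-similarity-aware framework.

    ``teacher`` optionally injects an already-trained phase-I model so the
    ablation arms share the identical starting point (it must come from the
    same data, seed and architecture).
    """
    if strategy not in BASELINE_STRATEGIES:
        raise ValueError(
            f"unknown strategy {strategy!r}; choose from {BASELINE_STRATEGIES}"
        )
    p = dict(params)
    e1 = p.get("epochs_phase1", 50)
    e2 = p.get("epochs_phase2", 100)
    seed = p.get("random_state")

    if strategy in ("baseline-ce", "ros", "rus", "hus"):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 4:
            image_shape = X.shape[1:]
        elif p.get("image_shape") is not None:
            image_shape = tuple(p["image_shape"])
        else:
            raise ValueError("flat input requires image_shape=(H, W, C)")
        X2 = X.reshape(len(X), -1)
        y = np.asarray(y, dtype=int)
        n_classes = int(np.max(y)) + 1
        arch = p.get("architecture", "conv")
        sgd = dict(
            batch_size=p.get("batch_size", 32),
            learning_rate=p.get("learning_rate", 0.1),
            momentum=p.get("momentum", 0.9),
            weight_decay=p.get("weight_decay", 0.0),
            random_state=seed,
        )
        if arch == "mlp":
            sgd["hidden_units"] = p.get("hidden_units", 128)

        rng = np.random.default_rng(seed)
        counts = pd.Series(y).value_counts().sort_index()
        m = counts.sum() / len(counts)
        target = int(np.floor(m))

        if strategy == "ros":
            extra_X, extra_y = [], []
            for c in counts.index[counts <= m]:
                ids = np.flatnonzero(y == c)
                need = target - len(ids)
                if need > 0:
                    pick = rng.choice(ids, size=need, replace=True)
                    extra_X.append(X2[pick])
                    extra_y.append(np.full(need, c))
            if extra_X:
                X2 = np.concatenate([X2] + extra_X)
                y = np.concatenate([y] + extra_y)
        elif strategy in ("rus", "hus"):
            head_ids = [int(c) for c in counts.index[counts > m]]
            if strategy == "rus":
                keep = np.ones(len(y), dtype=bool)
                for c in head_ids:
                    ids = np.flatnonzero(y == c)
                    drop = rng.choice(ids, size=len(ids) - target, replace=False)
                    keep[drop] = False
            else:
                extractor = teacher
                if extractor is None:
                    extractor = make_backbone(
                        arch, image_shape, n_classes, e1, **sgd
                    ).fit(X2, y)
                feats = extract_features(
                    extractor, X2,
                    normalize=p.get("normalize_features", True),
                    layer=p.get("herding_layer", 0),
                )
                partition = undersample_heads(
                    y, feats, head_ids, m,
                    method=p.get("herding_method", "nearest-mean"),
                )
                keep = np.ones(len(y), dtype=bool)
                keep[partition.all_removed()] = False
            X2, y = X2[keep], y[keep]

        model = make_backbone(arch, image_shape, n_classes, e1 + e2, **sgd)
        return model.fit(X2, y)

    overrides = {
        "hus-kd": dict(head_selection="herding", oversample_policy="none"),
        "cutmix-random": dict(oversample_policy="random"),
        "ours": {},
    }[strategy]
    est = TwoPhaseClassifier(teacher=teacher, **{**p, **overrides})
    return est.fit(X, y)
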
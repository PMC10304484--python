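"""The desk-scale synthetic long-tail benchmark and its ablation suite.

Study conditions: 10 classes on a geometric profile from 600 down to 6
training images (imbalance ratio 100, ~1.5K 32x32 images), 25 balanced test
images per class, three similarity groups mixing head and tail classes, a
compact backbone trained 10 phase-I + 20 phase-II epochs.  These sizes make a
full method-vs-baseline comparison run in minutes on one CPU while still
exhibiting the head/tail accuracy trade-offs the framework targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import EvalReport, evaluate
from .pipeline import train_baseline
from .profiles import make_rank_profile
from .synthetic import JitterSpec, SyntheticSpec, render_images

__all__ = ["benchmark_spec", "run_benchmark", "BenchmarkData", "make_benchmark_data"]

BENCHMARK_EPOCHS = (10, 20)  # phase I, phase II


def benchmark_spec(seed: int = 0) -> SyntheticSpec:
    """The default synthetic long-tail benchmark specification."""
    profile = make_rank_profile(n_classes=10, n_max=600, n_min=6, shape="geometric")
    return SyntheticSpec(
        profile=profile,
        image_size=(32, 32),
        test_per_class=25,
        jitter=JitterSpec(),
        seed=seed,
    )


@dataclass
class BenchmarkData:
    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    spec: SyntheticSpec


def make_benchmark_data(seed: int = 0) -> BenchmarkData:
    spec = benchmark_spec(seed)
    X_train, y_train, X_test, y_test, _ = render_images(spec)
    return BenchmarkData(X_train, y_train, X_test, y_test, spec)


def run_benchmark(
    seed: int = 0,
    strategies: tuple[str, ...] = ("baseline-ce", "rus", "hus", "cutmix-random", "ours"),
    epochs: tuple[int, int] = BENCHMARK_EPOCHS,
    data: BenchmarkData | None = None,
    **overrides,
) -> dict[str, EvalReport]:
    """Train every requested strategy on one seeded benchmark instance.

    Phase-I training is identical across the two-phase strategies (same data,
    seed and architecture), so a single teacher is trained once and shared.
    Returns a method-name -> EvalReport mapping.
    """
    if data is None:
        data = make_benchmark_data(seed)
    e1, e2 = epochs
    config = dict(
        epochs_phase1=e1,
        epochs_phase2=e2,
        random_state=seed,
        **overrides,
    )

    head, tail = _head_tail_split(data.y_train)

    teacher = None
    reports: dict[str, EvalReport] = {}
    for strategy in strategies:
        model = train_baseline(
            data.X_train, data.y_train, strategy, teacher=teacher, **config
        )
        if hasattr(model, "teacher_") and teacher is None:
            teacher = model.teacher_
        reports[strategy] = evaluate(
            model,
            data.X_test,
            data.y_test,
            head,
            tail,
            metadata={"method": strategy, "seed": seed},
        )
    return reports


def _head_tail_split(y: np.ndarray) -> tuple[list[int], list[int]]:
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    m = counts.sum() / len(classes)
    head = [int(c) for c, n in zip(classes, counts) if n > m]
    tail = [int(c) for c, n in zip(classes, counts) if n <= m]
    return head, tail
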
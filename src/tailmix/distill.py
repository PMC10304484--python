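"""Temperature-scaled knowledge distillation.

The second training phase sees only a herding-selected subset of each head
class.  To keep what the first-phase model learned from the removed samples,
the student is additionally trained to match the frozen teacher's
temperature-softened output distribution via cross-entropy.  A temperature
below 1 sharpens the teacher's distribution (efficient transfer of the
dominant prediction); above 1 it flattens it (exposes dark knowledge).
The framework default is T = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_softmax

__all__ = ["DistillConfig", "softened_distribution", "kd_loss"]


@dataclass(frozen=True)
class DistillConfig:
    """Knowledge-distillation hyper-parameters.

    temperature : softening divisor T > 0 applied to logits (default 0.5).
    weight : multiplier lambda on the KD term in the phase-II loss (>= 0).
    scope : which samples receive the KD term — the herding-selected head
        samples only (default) or every sample in the balanced set.
    t_squared : multiply the KD term by T**2 (gradient-scale convention used
        by some distillation implementations; off by default).
    """

    temperature: float = 0.5
    weight: float = 1.0
    scope: str = "selected-head-only"
    t_squared: bool = False

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.weight < 0:
            raise ValueError("kd weight must be >= 0")
        if self.scope not in ("selected-head-only", "all-samples"):
            raise ValueError(f"unknown kd scope: {self.scope!r}")


def _check_logits(logits: np.ndarray, temperature: float) -> np.ndarray:
    logits = np.asarray(logits, dtype=np.float64)
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError("logits must be finite")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    return logits


def softened_distribution(logits: np.ndarray, temperature: float = 0.5) -> np.ndarray:
    """Softmax of ``logits / T`` computed with a numerically stable shift.

    Works on a single logit vector or a batch (last axis = classes).
    Components are strictly positive and sum to 1 along the last axis.
    """
    logits = _check_logits(logits, temperature)
    return np.exp(log_softmax(logits / temperature, axis=-1))


def kd_loss(
    teacher_logits: np.ndarray,
    student_logits: np.ndarray,
    temperature: float = 0.5,
) -> float:
    """Cross-entropy of the softened student under the softened teacher.

    ``- sum_i p_T(i) log q_T(i)`` where ``p_T``/``q_T`` are the
    temperature-softened teacher/student distributions.  By Gibbs' inequality
    this is at least the softened teacher's entropy, with equality exactly
    when the softened distributions coincide.  Natural logarithm; batches are
    averaged over the leading axes.
    """
    t = _check_logits(teacher_logits, temperature)
    s = _check_logits(student_logits, temperature)
    if t.shape != s.shape:
        raise ValueError(
            f"teacher/student logit shapes differ: {t.shape} vs {s.shape}"
        )
    p = softened_distribution(t, temperature)
    log_q = log_softmax(s / temperature, axis=-1)
    per_sample = -(p * log_q).sum(axis=-1)
    return float(per_sample.mean())
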
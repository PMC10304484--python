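"""Long-tailed class-size profiles.

A profile is the ordered list of per-class training counts that defines how
imbalanced a benchmark is.  The default generator is a deterministic geometric
(log-linear in class rank) profile pinned to exact endpoint sizes; a stochastic
Pareto-sampled variant and a verbatim file-based variant are also provided for
fidelity experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ClassSizeProfile",
    "make_rank_profile",
    "food101_lt_profile",
]


class InvalidProfileError(ValueError):
    """Raised when requested profile endpoints are degenerate."""


@dataclass(frozen=True)
class ClassSizeProfile:
    """Ordered per-class training counts defining a long tail.

    Attributes
    ----------
    sizes : tuple of int
        Per-class training counts in non-increasing rank order.
    alpha : float
        Power parameter of the generating distribution (only meaningful for
        the Pareto-sampled shape; recorded for provenance otherwise).
    """

    sizes: tuple[int, ...]
    alpha: float = 6.0

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.sizes)
        object.__setattr__(self, "sizes", sizes)
        if len(sizes) < 1:
            raise InvalidProfileError("profile needs at least one class")
        if any(s < 1 for s in sizes):
            raise InvalidProfileError("all class sizes must be >= 1")
        if any(a < b for a, b in zip(sizes, sizes[1:])):
            raise InvalidProfileError("sizes must be non-increasing in rank")

    @property
    def n_classes(self) -> int:
        return len(self.sizes)

    @property
    def n_max(self) -> int:
        return self.sizes[0]

    @property
    def n_min(self) -> int:
        return self.sizes[-1]

    @property
    def imbalance_ratio(self) -> float:
        """Largest class size over smallest class size."""
        return self.n_max / self.n_min

    @property
    def total(self) -> int:
        return int(sum(self.sizes))

    def to_file(self, path: str | Path) -> None:
        """Write one integer per line in rank order."""
        Path(path).write_text("\n".join(str(s) for s in self.sizes) + "\n")

    @classmethod
    def from_file(cls, path: str | Path, alpha: float = 6.0) -> "ClassSizeProfile":
        sizes = [int(line) for line in Path(path).read_text().split() if line.strip()]
        return cls(sizes=tuple(sizes), alpha=alpha)


def make_rank_profile(
    n_classes: int,
    n_max: int,
    n_min: int,
    shape: str = "geometric",
    alpha: float = 6.0,
    seed: int | None = None,
    sizes: Sequence[int] | None = None,
) -> ClassSizeProfile:
    """Build a long-tailed class-size profile.

    Parameters
    ----------
    n_classes : int
        Number of classes (>= 2).
    n_max, n_min : int
        Largest and smallest per-class training counts; ``n_max > n_min >= 1``.
    shape : {"geometric", "pareto-sample", "file"}
        ``geometric`` (default): size at rank ``i`` is ``round(n_max * rho**i)``
        with ``rho = (n_min / n_max) ** (1 / (n_classes - 1))`` — deterministic,
        exact at both endpoints.  ``pareto-sample``: draw sizes from a Pareto
        law with power ``alpha``, sort descending and affinely rescale to the
        ``[n_min, n_max]`` endpoints (seeded).  ``file``: take ``sizes``
        verbatim.
    alpha : float
        Pareto power parameter (used by ``pareto-sample`` only).
    seed : int, optional
        RNG seed for the stochastic shape.
    sizes : sequence of int, optional
        Explicit sizes for ``shape="file"``.

    Returns
    -------
    ClassSizeProfile
    """
    if shape == "file":
        if sizes is None:
            raise ValueError('shape="file" requires explicit sizes')
        return ClassSizeProfile(sizes=tuple(int(s) for s in sizes), alpha=alpha)

    if n_classes < 2:
        raise InvalidProfileError("n_classes must be >= 2")
    if not (n_max > n_min >= 1):
        raise InvalidProfileError(
            f"require n_max > n_min >= 1, got n_max={n_max}, n_min={n_min}"
        )

    if shape == "geometric":
        rho = (n_min / n_max) ** (1.0 / (n_classes - 1))
        ranks = np.arange(n_classes)
        raw = n_max * rho**ranks
        out = np.rint(raw).astype(int)
        # rounding cannot break the endpoints: rho**0 == 1, rho**(C-1) exact
        out[0], out[-1] = n_max, n_min
    elif shape == "pareto-sample":
        rng = np.random.default_rng(seed)
        draws = np.sort(rng.pareto(alpha, size=n_classes))[::-1]
        lo, hi = draws[-1], draws[0]
        scaled = n_min + (draws - lo) * (n_max - n_min) / (hi - lo)
        out = np.rint(scaled).astype(int)
        out[0], out[-1] = n_max, n_min
        out = np.maximum.accumulate(out[::-1])[::-1]  # enforce monotone after rounding
    else:
        raise ValueError(f"unknown profile shape: {shape!r}")

    return ClassSizeProfile(sizes=tuple(int(s) for s in out), alpha=alpha)


def food101_lt_profile() -> ClassSizeProfile:
    """Default 101-class long-tail profile: 750 down to 5 images per class.

    Endpoints give an imbalance ratio of exactly 150 and the geometric decay
    yields well over 11,000 training images in total.
    """
    return make_rank_profile(n_classes=101, n_max=750, n_min=5, shape="geometric")
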
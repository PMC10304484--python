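"""Consumption-frequency-driven class sizing.

Real-world food intake is heavily skewed: a handful of food types (breads,
cookies, tomatoes, ...) dominate what U.S. adults report eating, while foods
like grilled salmon are rarely reported.  The packaged table maps 74 common
food types to an 8-digit FNDDS food code and a consumption frequency from
NHANES dietary recalls (2009-2016, 17,796 adults aged 20-65).  Scaling each
class's image count by its frequency relative to the most-consumed food turns
a balanced image dataset into a realistic long-tailed benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FrequencyTable",
    "SamplingPlan",
    "load_frequency_table",
    "frequency_plan",
]

_PACKAGED_TABLE = "vfn_consumption_frequency.tsv"


class MatchingError(KeyError):
    """A dataset class could not be matched to a frequency-table row."""


@dataclass(frozen=True)
class FrequencyTable:
    """Food types with FNDDS food codes and consumption frequencies."""

    rows: pd.DataFrame  # columns: index, food_type, food_code, consumption_frequency

    def __post_init__(self) -> None:
        freqs = self.rows["consumption_frequency"]
        if (freqs <= 0).any():
            raise ValueError("all consumption frequencies must be positive")
        if self.rows["food_code"].duplicated().any():
            raise ValueError("food codes must be unique")

    @property
    def f_max(self) -> int:
        return int(self.rows["consumption_frequency"].max())

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def frequency_of(self, food_type: str) -> int:
        hit = self.rows[self.rows["food_type"] == food_type]
        if hit.empty:
            raise MatchingError(food_type)
        return int(hit["consumption_frequency"].iloc[0])

    def to_tsv(self, path: str | Path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def load_frequency_table(path: str | Path | None = None) -> FrequencyTable:
    """Load the packaged 74-row table (or a user-provided TSV)."""
    if path is None:
        source = resources.files("tailmix.data").joinpath(_PACKAGED_TABLE)
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return FrequencyTable(rows=df)


@dataclass(frozen=True)
class SamplingPlan:
    """Per-class (source count n_i, selected count s_i) pairs."""

    sources: dict[int, int]
    targets: dict[int, int]

    def __post_init__(self) -> None:
        for c, s in self.targets.items():
            n = self.sources[c]
            if not (1 <= s <= n):
                raise ValueError(f"class {c}: target {s} outside [1, {n}]")


def _round_half_away(x: float) -> int:
    """Round half away from zero (positive arguments only here)."""
    return int(np.floor(x + 0.5))


def frequency_plan(
    table: FrequencyTable,
    source_counts: Mapping[int, int],
    matching: Mapping[int, str],
) -> SamplingPlan:
    """Scale per-class counts by consumption frequency.

    For class ``i`` with ``n_i`` source images matched to frequency ``f_i``,
    the selected count is ``s_i = max(1, round(n_i * f_i / f_max))`` — the
    most-consumed food keeps all of its images and every class keeps at least
    one, so even the rarest foods stay represented.

    Raises
    ------
    MatchingError
        Listing every class name that has no table row.
    """
    f_max = table.f_max
    known = set(table.rows["food_type"])
    unmatched = sorted(
        str(matching.get(c, f"<class {c}>"))
        for c in source_counts
        if matching.get(c) not in known
    )
    if unmatched:
        raise MatchingError(f"classes with no frequency-table match: {unmatched}")

    sources = {int(c): int(n) for c, n in source_counts.items()}
    targets = {}
    for c, n in sources.items():
        if n <= 0:
            raise ValueError(f"class {c} has non-positive source count {n}")
        f = table.frequency_of(matching[c])
        targets[c] = max(1, _round_half_away(n * f / f_max))
    return SamplingPlan(sources=sources, targets=targets)
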
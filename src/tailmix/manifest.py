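"""Dataset manifests: tabular (image path, class, split) records plus the
statistics and head/tail partition that drive resampling.

A manifest is a thin wrapper around a pandas DataFrame with columns
``image_path, class_id, class_name, split`` (split in {"train", "test"}).
Paths are stored relative to a declared image root.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .profiles import ClassSizeProfile

__all__ = [
    "DatasetManifest",
    "DatasetStats",
    "subsample_manifest",
    "dataset_stats",
    "split_head_tail",
]

MANIFEST_COLUMNS = ["image_path", "class_id", "class_name", "split"]


class CapacityError(ValueError):
    """A requested per-class count exceeds what the source provides."""


class EmptyManifestError(ValueError):
    """Operation requires a non-empty training split."""


@dataclass
class DatasetManifest:
    """Records of (image path, class id, class name, split)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        bad = set(self.records["split"]) - {"train", "test"}
        if bad:
            raise ValueError(f"unknown split tags: {sorted(bad)}")
        for split, grp in self.records.groupby("split"):
            if grp["image_path"].duplicated().any():
                raise ValueError(f"duplicate image paths within split {split!r}")
        self.records = self.records.reset_index(drop=True)

    def split(self, tag: str) -> pd.DataFrame:
        return self.records[self.records["split"] == tag]

    @property
    def train(self) -> pd.DataFrame:
        return self.split("train")

    @property
    def test(self) -> pd.DataFrame:
        return self.split("test")

    @property
    def class_ids(self) -> list[int]:
        return sorted(self.records["class_id"].unique())

    def class_counts(self, split: str = "train") -> dict[int, int]:
        """Per-class record counts in one split, keyed by class id."""
        counts = self.split(split)["class_id"].value_counts().to_dict()
        return {int(c): int(n) for c, n in sorted(counts.items())}

    def class_index(self, split: str = "train") -> dict[int, np.ndarray]:
        """Class id -> row positions (into ``records``) for one split."""
        sub = self.split(split)
        return {
            int(c): grp.index.to_numpy()
            for c, grp in sub.groupby("class_id")
        }

    def to_csv(self, path: str | Path) -> None:
        self.records[MANIFEST_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DatasetManifest":
        df = pd.read_csv(path)
        return cls(records=df)


@dataclass(frozen=True)
class DatasetStats:
    """Aggregate statistics of a manifest's training split."""

    total: int
    per_class: dict[int, int]
    imbalance_ratio: float
    mean_per_class: float  # m = D / n, real-valued

    @property
    def n_classes(self) -> int:
        return len(self.per_class)


def dataset_stats(manifest: DatasetManifest) -> DatasetStats:
    """Total images, per-class counts, imbalance ratio and mean m = D/n."""
    counts = manifest.class_counts("train")
    if not counts:
        raise EmptyManifestError("manifest has an empty training split")
    values = list(counts.values())
    return DatasetStats(
        total=int(sum(values)),
        per_class=counts,
        imbalance_ratio=max(values) / min(values),
        mean_per_class=sum(values) / len(values),
    )


def split_head_tail(
    stats: DatasetStats, manifest: DatasetManifest
) -> tuple[list[int], list[int]]:
    """Partition classes into head (count > m) and tail (count <= m).

    Classes sitting exactly at the mean are treated as tail; they need no
    resampling either way, so the tie rule only affects bookkeeping.
    """
    m = stats.mean_per_class
    head = [c for c, n in stats.per_class.items() if n > m]
    tail = [c for c, n in stats.per_class.items() if n <= m]
    return sorted(head), sorted(tail)


def _target_counts(
    source_counts: Mapping[int, int],
    plan_or_profile,
) -> dict[int, int]:
    """Normalize a SamplingPlan / ClassSizeProfile / mapping into targets."""
    if isinstance(plan_or_profile, ClassSizeProfile):
        sizes = plan_or_profile.sizes
        classes = sorted(source_counts)
        if len(sizes) != len(classes):
            raise ValueError(
                f"profile has {len(sizes)} classes, manifest has {len(classes)}"
            )
        # rank 0 (largest target) is assigned to the first class id, matching
        # how the synthetic generator and the builders order classes
        return {c: int(s) for c, s in zip(classes, sizes)}
    if hasattr(plan_or_profile, "targets"):  # SamplingPlan
        return {int(c): int(s) for c, s in plan_or_profile.targets.items()}
    return {int(c): int(s) for c, s in dict(plan_or_profile).items()}


def subsample_manifest(
    source: DatasetManifest,
    plan_or_profile,
    seed: int = 0,
) -> DatasetManifest:
    """Cut the training split down to per-class target counts.

    Selection within each class is uniform without replacement and fully
    determined by ``seed``; the test split passes through unchanged.
    """
    source_counts = source.class_counts("train")
    targets = _target_counts(source_counts, plan_or_profile)

    for c, t in targets.items():
        have = source_counts.get(c, 0)
        if t > have:
            raise CapacityError(
                f"class {c}: requested {t} training images but source has {have}"
            )

    rng = np.random.default_rng(seed)
    keep_rows: list[np.ndarray] = []
    index = source.class_index("train")
    for c in sorted(index):
        rows = index[c]
        t = targets.get(c, len(rows))
        chosen = rng.choice(rows, size=t, replace=False)
        keep_rows.append(np.sort(chosen))
    kept = np.concatenate(keep_rows) if keep_rows else np.array([], dtype=int)

    out = pd.concat(
        [source.records.loc[kept], source.test], ignore_index=True
    )
    return DatasetManifest(records=out)
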
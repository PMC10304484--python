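"""Representative head-class undersampling.

Head classes carry redundant training samples; cutting them at random throws
away information.  Herding instead keeps the samples that best represent the
class in feature space.  Two variants are provided:

``nearest-mean`` (default)
    Rank samples by Euclidean distance to the class mean feature vector and
    keep the closest ones.
``greedy-herding``
    The classic exemplar-selection loop: iteratively add the sample that
    moves the running mean of the picked set closest to the class mean.

Both break ties by sample id, making selection order-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureMatrix

__all__ = ["HeadPartition", "herding_select", "undersample_heads"]


class CapacityError(ValueError):
    """Asked to select more samples than the class has."""


@dataclass
class HeadPartition:
    """Per head class: selected (kept) and removed sample-id sets."""

    selected: dict[int, np.ndarray]   # class id -> sample ids, selection order
    removed: dict[int, np.ndarray]

    def all_selected(self) -> np.ndarray:
        parts = [self.selected[c] for c in sorted(self.selected)]
        return np.concatenate(parts) if parts else np.array([], dtype=np.int64)

    def all_removed(self) -> np.ndarray:
        parts = [self.removed[c] for c in sorted(self.removed)]
        return np.concatenate(parts) if parts else np.array([], dtype=np.int64)

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for c in sorted(self.selected):
            rows += [(c, int(s), "selected") for s in self.selected[c]]
            rows += [(c, int(s), "removed") for s in self.removed[c]]
        pd.DataFrame(rows, columns=["class_id", "sample_id", "status"]).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "HeadPartition":
        df = pd.read_csv(path)
        selected: dict[int, np.ndarray] = {}
        removed: dict[int, np.ndarray] = {}
        for c, grp in df.groupby("class_id"):
            selected[int(c)] = grp.loc[
                grp["status"] == "selected", "sample_id"
            ].to_numpy(dtype=np.int64)
            removed[int(c)] = grp.loc[
                grp["status"] == "removed", "sample_id"
            ].to_numpy(dtype=np.int64)
        return cls(selected=selected, removed=removed)


def herding_select(
    features: FeatureMatrix,
    n_select: int,
    method: str = "nearest-mean",
) -> np.ndarray:
    """Pick the ``n_select`` most representative samples of one class.

    Parameters
    ----------
    features : FeatureMatrix
        Feature vectors of every sample in the class.
    n_select : int
        How many to keep (1 <= n_select <= class size).
    method : {"nearest-mean", "greedy-herding"}

    Returns
    -------
    ndarray of sample ids in selection order.
    """
    n = len(features.sample_ids)
    if not (1 <= n_select <= n):
        raise CapacityError(f"n_select={n_select} outside [1, {n}]")

    vecs = features.vectors
    ids = features.sample_ids
    mean = vecs.mean(axis=0)

    if method == "nearest-mean":
        dist = np.linalg.norm(vecs - mean, axis=1)
        order = np.lexsort((ids, dist))  # distance first, sample id breaks ties
        return ids[order[:n_select]]

    if method == "greedy-herding":
        chosen: list[int] = []
        chosen_sum = np.zeros_like(mean)
        remaining = list(range(n))
        for t in range(n_select):
            cand = np.array(remaining)
            # distance between class mean and running mean if candidate added
            trial_means = (chosen_sum + vecs[cand]) / (t + 1)
            d = np.linalg.norm(trial_means - mean, axis=1)
            order = np.lexsort((ids[cand], d))
            pick = cand[order[0]]
            chosen.append(pick)
            chosen_sum += vecs[pick]
            remaining.remove(pick)
        return ids[np.array(chosen)]

    raise ValueError(f"unknown herding method: {method!r}")


def undersample_heads(
    labels: np.ndarray,
    features: FeatureMatrix,
    head_ids: list[int],
    m: float,
    method: str = "nearest-mean",
) -> HeadPartition:
    """Cut every head class down to ``floor(m)`` representative samples.

    ``labels`` aligns with ``features.sample_ids``.  The per-class integer
    target is ``floor(m)`` since the mean m = D/n is real-valued.
    """
    labels = np.asarray(labels)
    target = int(np.floor(m))
    selected: dict[int, np.ndarray] = {}
    removed: dict[int, np.ndarray] = {}
    for c in head_ids:
        mask = labels == c
        class_ids = features.sample_ids[mask]
        if len(class_ids) <= target:
            raise ValueError(
                f"class {c} has {len(class_ids)} samples, not more than m={m}; "
                "it is not a head class"
            )
        class_feats = FeatureMatrix(
            vectors=features.vectors[mask],
            sample_ids=class_ids,
            normalized=features.normalized,
        )
        keep = herding_select(class_feats, target, method=method)
        keep_set = set(int(k) for k in keep)
        drop = np.array([int(i) for i in class_ids if int(i) not in keep_set],
                        dtype=np.int64)
        selected[c] = keep.astype(np.int64)
        removed[c] = drop
    return HeadPartition(selected=selected, removed=removed)
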
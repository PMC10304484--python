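"""Visual-similarity-aware multi-image CutMix oversampling of tail classes.

Each synthetic tail sample starts from a real tail image and sequentially
mixes in rectangular regions of up to k head-class donor images.  Donors are
drawn from the pool of head samples *removed* by undersampling (so no pixel
budget is wasted) and, under the visual policy, are the k nearest neighbours
of the tail image by cosine similarity in the phase-I feature space — mixing
with look-alike images preserves the semantics of the tail class.  Binary
mask value 1 keeps the (running) tail composite, value 0 pastes the donor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import FeatureMatrix

__all__ = [
    "MixMask",
    "MixRecipe",
    "sample_mask",
    "topk_similar_heads",
    "compose",
    "ownership_from_masks",
    "make_label",
    "oversample_tail",
]


class DonorPoolError(ValueError):
    """The donor pool is empty or smaller than k."""


@dataclass(frozen=True)
class MixMask:
    """Rectangular binary mask over a W x H image.

    ``rect = (x0, y0, w, h)`` with ``w = floor(s * W)``, ``h = floor(s * H)``;
    the grid holds 1 inside the rectangle (tail-owned region under the
    composition convention) and 0 outside.
    """

    width: int
    height: int
    s: float
    rect: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        x0, y0, w, h = self.rect
        if w < 1 or h < 1:
            raise ValueError("mask rectangle must cover at least one pixel")
        if x0 < 0 or y0 < 0 or x0 + w > self.width or y0 + h > self.height:
            raise ValueError("mask rectangle must lie inside the image")

    @property
    def grid(self) -> np.ndarray:
        """(H, W) float array, 1 inside the rectangle."""
        g = np.zeros((self.height, self.width))
        x0, y0, w, h = self.rect
        g[y0 : y0 + h, x0 : x0 + w] = 1.0
        return g

    @property
    def ones_count(self) -> int:
        _, _, w, h = self.rect
        return w * h


def sample_mask(
    width: int,
    height: int,
    s_range: tuple[float, float] = (0.0, 1.0),
    rng: np.random.Generator | None = None,
) -> MixMask:
    """Draw a mask with mixing ratio s uniform on ``s_range``.

    s is redrawn until the rectangle ``floor(s*W) x floor(s*H)`` covers at
    least one pixel; its location is uniform over valid placements.
    """
    if width < 2 or height < 2:
        raise ValueError("image must be at least 2x2 to place a mask")
    low, high = s_range
    if not (0.0 <= low < high <= 1.0):
        raise ValueError(f"invalid s_range: {s_range}")
    rng = rng if rng is not None else np.random.default_rng()
    while True:
        s = float(rng.uniform(low, high))
        w, h = int(np.floor(s * width)), int(np.floor(s * height))
        if w >= 1 and h >= 1:
            break
    x0 = int(rng.integers(0, width - w + 1))
    y0 = int(rng.integers(0, height - h + 1))
    return MixMask(width=width, height=height, s=s, rect=(x0, y0, w, h))


def topk_similar_heads(
    tail_feature: np.ndarray,
    head_batch: FeatureMatrix,
    k: int,
) -> np.ndarray:
    """Ids of the k donors most cosine-similar to the tail feature.

    Descending similarity; exact ties broken by ascending sample id.
    """
    if k > len(head_batch.sample_ids):
        raise DonorPoolError(f"k={k} exceeds donor batch size {len(head_batch.sample_ids)}")
    t = np.asarray(tail_feature, dtype=np.float64)
    tn = np.linalg.norm(t)
    vn = np.linalg.norm(head_batch.vectors, axis=1)
    if tn == 0 or np.any(vn == 0):
        raise FloatingPointError("cosine similarity undefined for zero vectors")
    sims = head_batch.vectors @ t / (vn * tn)
    order = np.lexsort((head_batch.sample_ids, -sims))
    return head_batch.sample_ids[order[:k]]


def compose(
    tail_image: np.ndarray,
    donors: list[np.ndarray],
    masks: list[MixMask],
) -> tuple[np.ndarray, np.ndarray]:
    """Sequentially mix donors into the tail image.

    Step i replaces the region *outside* mask i with donor i:
    ``running = (1 - M_i) * donor_i + M_i * running``.  Returns the composite
    and an ownership map of owner indices (0 = tail, i = i-th donor).
    """
    if len(donors) != len(masks):
        raise ValueError("donors and masks must have equal length")
    running = np.asarray(tail_image, dtype=np.float64)
    h, w = running.shape[:2]
    ownership = np.zeros((h, w), dtype=np.int64)
    for i, (donor, mask) in enumerate(zip(donors, masks), start=1):
        donor = np.asarray(donor, dtype=np.float64)
        if donor.shape != running.shape:
            raise ValueError(
                f"donor {i} shape {donor.shape} != tail shape {running.shape}"
            )
        if (mask.height, mask.width) != (h, w):
            raise ValueError("mask dimensions must match the image")
        g = mask.grid
        running = (1.0 - g)[..., None] * donor + g[..., None] * running
        ownership = np.where(g == 0, i, ownership)
    return running, ownership


def ownership_from_masks(masks: list[MixMask]) -> np.ndarray:
    """Ownership map implied by a mask sequence alone (no pixels needed)."""
    if not masks:
        raise ValueError("need at least one mask")
    h, w = masks[0].height, masks[0].width
    ownership = np.zeros((h, w), dtype=np.int64)
    for i, mask in enumerate(masks, start=1):
        ownership = np.where(mask.grid == 0, i, ownership)
    return ownership


def make_label(
    ownership: np.ndarray,
    owner_classes: list[int],
    n_classes: int,
    policy: str = "area-mix",
) -> np.ndarray:
    """Per-class label weights for a composite.

    ``owner_classes[i]`` is the class of owner index i (0 = tail class).
    ``area-mix`` weights each class by its pixel fraction (the CutMix
    convention); ``tail-only`` puts weight 1 on the tail class.
    """
    weights = np.zeros(n_classes)
    if policy == "tail-only":
        weights[owner_classes[0]] = 1.0
        return weights
    if policy != "area-mix":
        raise ValueError(f"unknown label policy: {policy!r}")
    total = ownership.size
    for owner, cls in enumerate(owner_classes):
        frac = np.count_nonzero(ownership == owner) / total
        weights[cls] += frac
    return weights


@dataclass
class MixRecipe:
    """Everything needed to reproduce one augmented tail sample."""

    tail_id: int
    tail_class: int
    donor_ids: list[int]
    donor_classes: list[int]
    masks: list[MixMask]
    label: np.ndarray

    @property
    def tail_fraction(self) -> float:
        """Fraction of pixels still owned by the original tail image."""
        own = ownership_from_masks(self.masks)
        return float(np.count_nonzero(own == 0) / own.size)

    def to_dict(self) -> dict:
        return {
            "tail_id": int(self.tail_id),
            "tail_class": int(self.tail_class),
            "donor_ids": [int(d) for d in self.donor_ids],
            "donor_classes": [int(c) for c in self.donor_classes],
            "masks": [
                {"s": m.s, "rect": list(m.rect), "width": m.width, "height": m.height}
                for m in self.masks
            ],
            "label": [float(x) for x in self.label],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixRecipe":
        return cls(
            tail_id=d["tail_id"],
            tail_class=d["tail_class"],
            donor_ids=list(d["donor_ids"]),
            donor_classes=list(d["donor_classes"]),
            masks=[
                MixMask(
                    width=m["width"], height=m["height"], s=m["s"],
                    rect=tuple(m["rect"]),
                )
                for m in d["masks"]
            ],
            label=np.array(d["label"]),
        )


def write_recipe_log(recipes: list[MixRecipe], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in recipes:
            fh.write(json.dumps(r.to_dict()) + "\n")


def read_recipe_log(path: str | Path) -> list[MixRecipe]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                out.append(MixRecipe.from_dict(json.loads(line)))
    return out


def oversample_tail(
    labels: np.ndarray,
    tail_ids: list[int],
    donor_pool: np.ndarray,
    features: FeatureMatrix,
    m: float,
    image_size: tuple[int, int],
    k: int = 1,
    br_size: int = 64,
    s_range: tuple[float, float] = (0.0, 1.0),
    policy: str = "visual",
    label_policy: str = "area-mix",
    n_classes: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[MixRecipe]:
    """Generate mix recipes lifting every tail class to ``floor(m)`` samples.

    For each needed synthetic sample: cycle over the class's originals, draw a
    fresh donor batch Br from the removed-head pool, retrieve k donors (top-k
    cosine under ``policy="visual"``, uniform under ``policy="random"``),
    sample k fresh masks and record the composition plus its label weights.
    Fully reproducible from ``rng``.
    """
    labels = np.asarray(labels)
    donor_pool = np.asarray(donor_pool, dtype=np.int64)
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    if n_classes is None:
        n_classes = int(labels.max()) + 1
    w, h = image_size

    id_to_class = {int(s): int(c) for s, c in zip(features.sample_ids, labels)}
    id_to_pos = {int(s): i for i, s in enumerate(features.sample_ids)}
    target = int(np.floor(m))

    recipes: list[MixRecipe] = []
    for c in sorted(tail_ids):
        originals = features.sample_ids[labels == c]
        if len(originals) == 0:
            raise ValueError(f"tail class {c} has no images")
        need = target - len(originals)
        if need > 0 and len(donor_pool) == 0:
            raise DonorPoolError(
                "empty donor pool; enable the all-heads fallback or skip oversampling"
            )
        for j in range(max(0, need)):
            tail_id = int(originals[j % len(originals)])
            br_n = min(br_size, len(donor_pool))
            if k > br_n:
                raise DonorPoolError(f"k={k} exceeds donor batch size {br_n}")
            br_ids = rng.choice(donor_pool, size=br_n, replace=False)
            if policy == "visual":
                batch = features.subset(br_ids)
                donor_ids = topk_similar_heads(
                    features.vectors[id_to_pos[tail_id]], batch, k
                )
            elif policy == "random":
                donor_ids = rng.choice(br_ids, size=k, replace=False)
            else:
                raise ValueError(f"unknown donor policy: {policy!r}")
            masks = [sample_mask(w, h, s_range, rng) for _ in range(k)]
            owner_classes = [c] + [id_to_class[int(d)] for d in donor_ids]
            label = make_label(
                ownership_from_masks(masks), owner_classes, n_classes, label_policy
            )
            recipes.append(
                MixRecipe(
                    tail_id=tail_id,
                    tail_class=c,
                    donor_ids=[int(d) for d in donor_ids],
                    donor_classes=owner_classes[1:],
                    masks=masks,
                    label=label,
                )
            )
    return recipes


def compose_recipe(recipe: MixRecipe, images_by_id) -> np.ndarray:
    """Materialize a recipe's composite from an id-indexable image source."""
    tail_img = images_by_id[recipe.tail_id]
    donors = [images_by_id[d] for d in recipe.donor_ids]
    composite, _ = compose(tail_img, donors, recipe.masks)
    return composite
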
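"""Procedural synthetic image datasets with a controllable long tail.

Every class renders as a background hue band plus a filled polygon foreground
and a sinusoidal grating texture; classes in the same *similarity group* share
the hue band (so they look alike to a feature extractor), while shape vertex
count and texture frequency separate classes within a group.  Per-image jitter
(hue, position, scale, rotation, pixel noise) provides intra-class diversity.
Everything is deterministic given the spec's seed.

This emulates the two properties that make food recognition hard — inter-class
visual similarity and intra-class diversity — without shipping or downloading
any image corpus.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image, ImageDraw

from .manifest import DatasetManifest, MANIFEST_COLUMNS
from .profiles import ClassSizeProfile

import pandas as pd

__all__ = [
    "JitterSpec",
    "SyntheticSpec",
    "default_similarity_groups",
    "render_images",
    "generate_dataset",
    "load_images",
]


@dataclass(frozen=True)
class JitterSpec:
    """Per-image appearance noise (all dimensionless fractions).

    ``outlier_fraction`` emulates the noise endemic to the uncleaned
    training splits of web-scraped food datasets: with this probability a
    *training* image keeps its class label but is rendered as an outlier.
    Three styles are provided — ``corrupt`` (default: the class render
    survives but the palette rotates to an arbitrary hue and random blobs
    occlude it, emulating the "intense colors" / filter-heavy failure
    mode), ``junk`` (off-distribution clutter carrying no class structure
    at all) and ``mislabel`` (the appearance of a uniformly chosen
    different class, a wrong-label failure).

    ``test_jitter_scale`` emulates the curated test splits of those same
    benchmarks (test labels and images are manually reviewed while training
    data is left noisy): test images are always correctly labelled and
    their appearance spreads are scaled by this factor.
    """

    hue_spread: float = 0.03      # std of hue offset, hue-circle units
    pos_spread: float = 0.15      # std of polygon centre offset, fraction of W
    scale_spread: float = 0.15    # relative std of polygon radius
    noise: float = 0.02           # std of additive pixel noise in [0,1] units
    outlier_fraction: float = 0.10  # share of outlier training images
    outlier_style: str = "corrupt"  # "corrupt", "junk" or "mislabel"
    test_jitter_scale: float = 0.5  # appearance-spread factor for test images

    def scaled(self, factor: float) -> "JitterSpec":
        return JitterSpec(
            hue_spread=self.hue_spread * factor,
            pos_spread=self.pos_spread * factor,
            scale_spread=self.scale_spread * factor,
            noise=self.noise,
            outlier_fraction=self.outlier_fraction,
            outlier_style=self.outlier_style,
            test_jitter_scale=self.test_jitter_scale,
        )


def default_similarity_groups(n_classes: int, n_groups: int = 3) -> list[list[int]]:
    """Round-robin partition so each group mixes large and small classes."""
    groups: list[list[int]] = [[] for _ in range(n_groups)]
    for c in range(n_classes):
        groups[c % n_groups].append(c)
    return [g for g in groups if g]


@dataclass(frozen=True)
class SyntheticSpec:
    """Full recipe for one synthetic dataset."""

    profile: ClassSizeProfile
    image_size: tuple[int, int] = (32, 32)
    test_per_class: int = 10
    similarity_groups: list[list[int]] | None = None
    jitter: JitterSpec = field(default_factory=JitterSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.image_size
        if w < 16 or h < 16:
            raise ValueError("image_size must be at least 16x16")
        if self.similarity_groups is None:
            object.__setattr__(
                self,
                "similarity_groups",
                default_similarity_groups(self.profile.n_classes),
            )
        seen = sorted(c for g in self.similarity_groups for c in g)
        if seen != list(range(self.profile.n_classes)):
            raise ValueError("similarity_groups must partition the classes")

    @property
    def n_classes(self) -> int:
        return self.profile.n_classes

    def group_of(self, class_id: int) -> int:
        for gi, g in enumerate(self.similarity_groups):
            if class_id in g:
                return gi
        raise KeyError(class_id)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "profile_sizes": list(self.profile.sizes),
            "alpha": self.profile.alpha,
            "image_size": list(self.image_size),
            "test_per_class": self.test_per_class,
            "similarity_groups": [list(g) for g in self.similarity_groups],
            "jitter": {
                "hue_spread": self.jitter.hue_spread,
                "pos_spread": self.jitter.pos_spread,
                "scale_spread": self.jitter.scale_spread,
                "noise": self.jitter.noise,
                "outlier_fraction": self.jitter.outlier_fraction,
                "outlier_style": self.jitter.outlier_style,
                "test_jitter_scale": self.jitter.test_jitter_scale,
            },
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            profile=ClassSizeProfile(
                sizes=tuple(payload["profile_sizes"]), alpha=payload.get("alpha", 6.0)
            ),
            image_size=tuple(payload["image_size"]),
            test_per_class=payload["test_per_class"],
            similarity_groups=[list(g) for g in payload["similarity_groups"]],
            jitter=JitterSpec(**payload["jitter"]),
            seed=payload["seed"],
        )


def _hsv_to_rgb(h: np.ndarray, s: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Vectorized HSV -> RGB, all components in [0, 1]."""
    h = np.mod(h, 1.0) * 6.0
    i = np.floor(h).astype(int) % 6
    f = h - np.floor(h)
    p = v * (1 - s)
    q = v * (1 - s * f)
    t = v * (1 - s * (1 - f))
    table = np.stack(
        [
            np.stack([v, t, p], axis=-1),
            np.stack([q, v, p], axis=-1),
            np.stack([p, v, t], axis=-1),
            np.stack([p, q, v], axis=-1),
            np.stack([t, p, v], axis=-1),
            np.stack([v, p, q], axis=-1),
        ],
        axis=0,
    )
    return np.take_along_axis(table, i[None, ..., None], axis=0)[0]


def _image_rng(seed: int, class_id: int, split_flag: int, idx: int) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, class_id, split_flag, idx])


def _render_junk(w: int, h: int, rng: np.random.Generator) -> np.ndarray:
    """Off-distribution clutter: random hue field plus scattered fragments."""
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    val = rng.uniform(0.2, 1.0) + 0.2 * np.sin(
        2 * np.pi * rng.uniform(1, 8) * xx / w + rng.uniform(0, 2 * np.pi)
    )
    img = _hsv_to_rgb(
        np.full((h, w), rng.uniform()),
        np.full((h, w), rng.uniform(0.1, 1.0)),
        np.clip(val, 0, 1),
    )
    canvas = Image.fromarray(np.clip(np.rint(img * 255), 0, 255).astype(np.uint8))
    draw = ImageDraw.Draw(canvas)
    for _ in range(int(rng.integers(3, 8))):
        x0, y0 = rng.uniform(0, w), rng.uniform(0, h)
        r = rng.uniform(1, w / 4)
        color = tuple(int(v) for v in rng.integers(0, 256, size=3))
        draw.ellipse([x0 - r, y0 - r, x0 + r, y0 + r], fill=color)
    img = np.asarray(canvas, dtype=np.float64) / 255.0
    img = img + rng.normal(0.0, 0.15, size=img.shape)
    img8 = np.clip(np.rint(img * 255), 0, 255).astype(np.uint8)
    return img8.astype(np.float32) / 255.0


def _render_one(
    spec: SyntheticSpec, class_id: int, split_flag: int, idx: int
) -> np.ndarray:
    """Render one image as float32 (H, W, 3) in [0, 1], uint8-quantized."""
    w, h = spec.image_size
    jit = spec.jitter if split_flag == 0 else spec.jitter.scaled(
        spec.jitter.test_jitter_scale
    )
    rng = _image_rng(spec.seed, class_id, split_flag, idx)

    corrupt = False
    if split_flag == 0 and rng.uniform() < jit.outlier_fraction:
        if jit.outlier_style == "junk":
            return _render_junk(w, h, rng)
        if jit.outlier_style == "corrupt":
            corrupt = True
        else:
            # mislabel style: appearance of another class, label unchanged
            others = [c for c in range(spec.n_classes) if c != class_id]
            class_id = int(others[rng.integers(0, len(others))])

    group = spec.group_of(class_id)
    n_groups = len(spec.similarity_groups)
    rank_in_group = spec.similarity_groups[group].index(class_id)

    # the background hue band is shared by the whole similarity group (what
    # makes its members look alike); the foreground hue separates classes
    # within a group, so look-alike classes stay clearly discriminable
    base_hue = group / n_groups
    hue = base_hue + rng.normal(0.0, jit.hue_spread)
    if corrupt:
        # color-cast corruption: the class structure survives but the whole
        # palette rotates to an arbitrary hue, as in badly white-balanced or
        # filter-heavy photographs
        hue = rng.uniform()

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    val = 0.55 + 0.25 * yy / max(h - 1, 1)

    # class-specific grating texture
    freq = 2.0 + (class_id % 4)
    theta = (class_id * 0.7) % np.pi
    phase = rng.uniform(0, 2 * np.pi)
    val = val + 0.06 * np.sin(
        2 * np.pi * freq * (xx * np.cos(theta) + yy * np.sin(theta)) / w + phase
    )
    sat = np.full((h, w), 0.55)
    img = _hsv_to_rgb(np.full((h, w), hue), sat, np.clip(val, 0, 1))

    # foreground: regular polygon filling most of the frame (as the food
    # fills most of a food photograph); vertex count keyed to the class
    n_vertices = 3 + (class_id % 5)
    cx = w / 2 + rng.normal(0.0, jit.pos_spread * w)
    cy = h / 2 + rng.normal(0.0, jit.pos_spread * h)
    radius = (w / 2.2) * np.exp(rng.normal(0.0, jit.scale_spread))
    radius = float(np.clip(radius, 2.0, 0.7 * w))
    rot = rng.uniform(0, 2 * np.pi)
    angles = rot + 2 * np.pi * np.arange(n_vertices) / n_vertices
    pts = [(cx + radius * np.cos(a), cy + radius * np.sin(a)) for a in angles]

    mask_img = Image.new("L", (w, h), 0)
    ImageDraw.Draw(mask_img).polygon(pts, fill=255)
    fg_mask = np.asarray(mask_img, dtype=np.float64)[..., None] / 255.0

    fg_hue = hue + 0.5 + 0.04 * rank_in_group
    fg = _hsv_to_rgb(
        np.full((h, w), fg_hue), np.full((h, w), 0.85), np.full((h, w), 0.9)
    )
    img = (1 - fg_mask) * img + fg_mask * fg

    if corrupt:
        # partial occlusion by random blobs plus heavier sensor noise
        canvas = Image.fromarray(np.clip(np.rint(img * 255), 0, 255).astype(np.uint8))
        draw = ImageDraw.Draw(canvas)
        for _ in range(int(rng.integers(2, 5))):
            x0, y0 = rng.uniform(0, w), rng.uniform(0, h)
            r = rng.uniform(2, w / 4)
            color = tuple(int(v) for v in rng.integers(0, 256, size=3))
            draw.ellipse([x0 - r, y0 - r, x0 + r, y0 + r], fill=color)
        img = np.asarray(canvas, dtype=np.float64) / 255.0
        img = img + rng.normal(0.0, 0.08, size=img.shape)

    img = img + rng.normal(0.0, jit.noise, size=img.shape)
    img8 = np.clip(np.rint(img * 255), 0, 255).astype(np.uint8)
    return img8.astype(np.float32) / 255.0


def render_images(
    spec: SyntheticSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, DatasetManifest]:
    """Render the full dataset in memory.

    Returns
    -------
    X_train, y_train, X_test, y_test, manifest
        Images as float32 arrays (N, H, W, 3) in [0, 1]; the manifest row
        order matches the concatenation train-then-test.
    """
    rows = []
    train_imgs, train_lbls, test_imgs, test_lbls = [], [], [], []
    for c in range(spec.n_classes):
        n_train = spec.profile.sizes[c]
        for i in range(n_train):
            train_imgs.append(_render_one(spec, c, 0, i))
            train_lbls.append(c)
            rows.append(
                (f"train/class_{c:02d}/img_{i:05d}.png", c, f"class_{c:02d}", "train")
            )
    for c in range(spec.n_classes):
        for i in range(spec.test_per_class):
            test_imgs.append(_render_one(spec, c, 1, i))
            test_lbls.append(c)
            rows.append(
                (f"test/class_{c:02d}/img_{i:05d}.png", c, f"class_{c:02d}", "test")
            )
    manifest = DatasetManifest(
        records=pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    )
    return (
        np.stack(train_imgs),
        np.array(train_lbls),
        np.stack(test_imgs) if test_imgs else np.empty((0,)),
        np.array(test_lbls),
        manifest,
    )


def generate_dataset(spec: SyntheticSpec, output_root: str | Path) -> DatasetManifest:
    """Write PNG images plus ``manifest.csv`` and ``spec.yaml`` under a root."""
    root = Path(output_root)
    root.mkdir(parents=True, exist_ok=True)
    X_train, _, X_test, _, manifest = render_images(spec)
    images = np.concatenate([X_train, X_test]) if len(X_test) else X_train
    for img, path in zip(images, manifest.records["image_path"]):
        target = root / path
        target.parent.mkdir(parents=True, exist_ok=True)
        Image.fromarray(np.clip(np.rint(img * 255), 0, 255).astype(np.uint8)).save(
            target
        )
    manifest.to_csv(root / "manifest.csv")
    spec.to_yaml(root / "spec.yaml")
    return manifest


def load_images(manifest: DatasetManifest, root: str | Path) -> np.ndarray:
    """Load all manifest images as float32 (N, H, W, 3) in [0, 1]."""
    root = Path(root)
    out = []
    for path in manifest.records["image_path"]:
        full = root / path
        if not full.exists():
            raise FileNotFoundError(f"missing image file: {full}")
        out.append(np.asarray(Image.open(full), dtype=np.float32) / 255.0)
    return np.stack(out)


def dataset_checksum(images: np.ndarray) -> str:
    """Stable checksum of a rendered image stack (uint8-quantized)."""
    q = np.clip(np.rint(images * 255), 0, 255).astype(np.uint8)
    return hashlib.sha256(q.tobytes()).hexdigest()
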
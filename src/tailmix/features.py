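"""Feature embeddings from a trained backbone's penultimate layer."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FeatureMatrix", "extract_features"]


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-sample feature vectors aligned to manifest record ids."""

    vectors: np.ndarray        # (n_samples, dim) float64
    sample_ids: np.ndarray     # (n_samples,) int
    normalized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=np.float64)
        ids = np.asarray(self.sample_ids, dtype=np.int64)
        if v.ndim != 2:
            raise ValueError("feature vectors must form a 2-D matrix")
        if len(ids) != len(v):
            raise ValueError("sample_ids must align with vectors")
        if self.normalized:
            norms = np.linalg.norm(v, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("normalized flag set but vectors are not unit-norm")
        object.__setattr__(self, "vectors", v)
        object.__setattr__(self, "sample_ids", ids)

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def subset(self, ids: np.ndarray) -> "FeatureMatrix":
        """Restrict to a set of sample ids (kept in the given order)."""
        pos = {int(s): i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[int(i)] for i in ids], dtype=int)
        return FeatureMatrix(
            vectors=self.vectors[idx],
            sample_ids=self.sample_ids[idx],
            normalized=self.normalized,
        )


def extract_features(
    model,
    images: np.ndarray,
    sample_ids: np.ndarray | None = None,
    batch_size: int = 512,
    normalize: bool = True,
    layer: int | None = None,
) -> FeatureMatrix:
    """Run images through the backbone's penultimate representation.

    ``model`` must expose ``transform(X)`` mapping a (n, features) pixel
    matrix to fixed-length real vectors (the sklearn transformer contract);
    images of shape (n, H, W, C) are flattened automatically.  ``layer``
    selects a lower conv layer instead of the penultimate embedding for
    backbones that expose ``layer_embedding`` (lower layers give generic
    appearance features rather than class-collapsed ones).  With
    ``normalize`` each vector is scaled to unit Euclidean norm, which both
    stabilizes class means for herding and turns dot products into cosine
    similarities for donor retrieval.
    """
    X = np.asarray(images, dtype=np.float64)
    if X.ndim > 2:
        X = X.reshape(len(X), -1)
    if sample_ids is None:
        sample_ids = np.arange(len(X))
    if layer is not None and hasattr(model, "layer_embedding"):
        def embed(batch):
            return model.layer_embedding(batch, layer=layer)
    else:
        embed = model.transform
    chunks = [embed(X[i : i + batch_size]) for i in range(0, len(X), batch_size)]
    vecs = np.concatenate(chunks, axis=0).astype(np.float64)
    if normalize:
        norms = np.linalg.norm(vecs, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise FloatingPointError("zero feature vector cannot be normalized")
        vecs = vecs / norms
    return FeatureMatrix(vectors=vecs, sample_ids=np.asarray(sample_ids), normalized=normalize)
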
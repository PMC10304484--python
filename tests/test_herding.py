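import numpy as np
import pytest

from tailmix.features import FeatureMatrix, extract_features
from tailmix.herding import CapacityError, HeadPartition, herding_select, undersample_heads


def fm(vectors, ids=None, normalized=False):
    vectors = np.asarray(vectors, dtype=float)
    if ids is None:
        ids = np.arange(len(vectors))
    return FeatureMatrix(vectors=vectors, sample_ids=np.asarray(ids), normalized=normalized)


def nearest_mean_oracle(vectors, ids, n):
    """Independent ranking oracle: plain sort by distance, then id."""
    mean = vectors.mean(axis=0)
    d = np.linalg.norm(vectors - mean, axis=1)
    order = sorted(range(len(ids)), key=lambda i: (d[i], ids[i]))
    return [ids[i] for i in order[:n]]


def greedy_oracle(vectors, ids, n):
    """Independent step-by-step search over all candidates per step."""
    mean = vectors.mean(axis=0)
    chosen, total = [], np.zeros_like(mean)
    remaining = list(range(len(ids)))
    for t in range(n):
        best = min(
            remaining,
            key=lambda i: (np.linalg.norm((total + vectors[i]) / (t + 1) - mean), ids[i]),
        )
        chosen.append(best)
        total = total + vectors[best]
        remaining.remove(best)
    return [ids[i] for i in chosen]


class TestHerdingSelect:
    def test_single_sample_class(self):
        out = herding_select(fm([[1.0, 2.0]], ids=[7]), 1)
        assert list(out) == [7]

    def test_sample_at_mean_ranked_first(self):
        vecs = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0], [0.0, 0.0]])
        for method in ("nearest-mean", "greedy-herding"):
            out = herding_select(fm(vecs), 1, method=method)
            assert out[0] == 4

    @pytest.mark.parametrize("method,oracle", [
        ("nearest-mean", nearest_mean_oracle),
        ("greedy-herding", greedy_oracle),
    ])
    def test_matches_independent_oracle(self, method, oracle, rng):
        for _ in range(25):
            n = int(rng.integers(3, 15))
            vecs = rng.normal(size=(n, 2))
            k = int(rng.integers(1, n + 1))
            got = list(herding_select(fm(vecs), k, method=method))
            assert got == oracle(vecs, np.arange(n), k)

    def test_permutation_invariant(self, rng):
        vecs = rng.normal(size=(12, 4))
        ids = np.arange(12)
        perm = rng.permutation(12)
        a = set(herding_select(fm(vecs, ids), 5))
        b = set(herding_select(fm(vecs[perm], ids[perm]), 5))
        assert a == b

    def test_capacity_error(self):
        with pytest.raises(CapacityError):
            herding_select(fm(np.eye(3)), 4)

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="method"):
            herding_select(fm(np.eye(3)), 2, method="kmeans")


class TestUndersampleHeads:
    def make_features(self, counts, rng, dim=3):
        labels = np.concatenate([np.full(n, c) for c, n in enumerate(counts)])
        vecs = rng.normal(size=(len(labels), dim)) + labels[:, None] * 3
        return labels, fm(vecs)

    def test_exact_floor_m_selected_and_partition_valid(self, rng):
        labels, feats = self.make_features([20, 15, 4], rng)
        part = undersample_heads(labels, feats, [0, 1], m=13.0)
        for c in (0, 1):
            sel, rem = set(part.selected[c]), set(part.removed[c])
            assert len(sel) == 13
            assert not sel & rem
            assert sel | rem == set(feats.sample_ids[labels == c])

    def test_one_over_m_removes_exactly_one(self, rng):
        labels, feats = self.make_features([8], rng)
        part = undersample_heads(labels, feats, [0], m=7.0)
        assert len(part.removed[0]) == 1

    def test_non_head_class_rejected(self, rng):
        labels, feats = self.make_features([5], rng)
        with pytest.raises(ValueError, match="not a head class"):
            undersample_heads(labels, feats, [0], m=6.0)

    def test_selected_mean_approximates_class_mean(self, rng):
        """Herding-selected subsets track the class mean at least as well as
        equally sized random subsets, on average over repetitions."""
        herd_err, rand_err = [], []
        for _ in range(20):
            vecs = rng.normal(size=(40, 3))
            mean = vecs.mean(axis=0)
            keep = herding_select(fm(vecs), 10, method="greedy-herding")
            herd_err.append(np.linalg.norm(vecs[keep].mean(axis=0) - mean))
            pick = rng.choice(40, size=10, replace=False)
            rand_err.append(np.linalg.norm(vecs[pick].mean(axis=0) - mean))
        assert np.mean(herd_err) <= np.mean(rand_err)

    def test_partition_csv_roundtrip(self, rng, tmp_path):
        labels, feats = self.make_features([10, 9], rng)
        part = undersample_heads(labels, feats, [0, 1], m=6.0)
        part.to_csv(tmp_path / "part.csv")
        again = HeadPartition.from_csv(tmp_path / "part.csv")
        for c in (0, 1):
            assert sorted(again.selected[c]) == sorted(part.selected[c])
            assert sorted(again.removed[c]) == sorted(part.removed[c])


class TestExtractFeatures:
    class DoublingModel:
        def transform(self, X):
            return np.asarray(X) * 2.0

    def test_duplicate_images_identical_vectors(self):
        X = np.stack([np.full((4, 4, 3), 0.3)] * 2)
        out = extract_features(self.DoublingModel(), X, normalize=False)
        np.testing.assert_array_equal(out.vectors[0], out.vectors[1])

    def test_normalized_vectors_unit_norm(self, rng):
        X = rng.uniform(0.1, 1.0, size=(6, 4, 4, 3))
        out = extract_features(self.DoublingModel(), X, normalize=True)
        np.testing.assert_allclose(np.linalg.norm(out.vectors, axis=1), 1.0)
        assert out.normalized

    def test_batching_matches_single_pass(self, rng):
        X = rng.uniform(size=(10, 5))
        a = extract_features(self.DoublingModel(), X, batch_size=3, normalize=False)
        b = extract_features(self.DoublingModel(), X, batch_size=100, normalize=False)
        np.testing.assert_array_equal(a.vectors, b.vectors)
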
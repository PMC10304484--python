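import numpy as np
import pytest

from tailmix.cutmix import (
    DonorPoolError,
    MixMask,
    MixRecipe,
    compose,
    compose_recipe,
    make_label,
    oversample_tail,
    ownership_from_masks,
    read_recipe_log,
    sample_mask,
    topk_similar_heads,
    write_recipe_log,
)
from tailmix.features import FeatureMatrix


def fm(vectors, ids=None):
    vectors = np.asarray(vectors, dtype=float)
    if ids is None:
        ids = np.arange(len(vectors))
    return FeatureMatrix(vectors=vectors, sample_ids=np.asarray(ids))


class TestMask:
    def test_half_ratio_covers_quarter_area(self):
        m = MixMask(width=32, height=32, s=0.5, rect=(4, 4, 16, 16))
        assert m.ones_count == 256
        assert m.grid.sum() == 256

    def test_rect_must_fit(self):
        with pytest.raises(ValueError):
            MixMask(width=8, height=8, s=0.9, rect=(4, 4, 7, 7))
        with pytest.raises(ValueError):
            MixMask(width=8, height=8, s=0.1, rect=(0, 0, 0, 1))

    def test_sampled_mask_always_at_least_one_pixel(self, rng):
        for _ in range(200):
            m = sample_mask(8, 8, (0.0, 1.0), rng)
            assert m.ones_count >= 1
            x0, y0, w, h = m.rect
            assert 0 <= x0 <= 8 - w and 0 <= y0 <= 8 - h

    def test_s_range_validation(self, rng):
        with pytest.raises(ValueError):
            sample_mask(8, 8, (0.5, 0.2), rng)
        with pytest.raises(ValueError):
            sample_mask(1, 1, (0.0, 1.0), rng)


class TestTopK:
    def test_identical_donor_first_with_unit_similarity(self):
        t = np.array([1.0, 0.0])
        batch = fm([[0.0, 1.0], [1.0, 0.0], [0.7, 0.7]])
        out = topk_similar_heads(t, batch, 2)
        assert out[0] == 1

    def test_orthogonal_ties_break_by_id(self):
        t = np.array([1.0, 0.0, 0.0])
        batch = fm([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0]], ids=[9, 4])
        out = topk_similar_heads(t, batch, 2)
        assert list(out) == [4, 9]

    def test_matches_exhaustive_cosine_sort(self, rng):
        for _ in range(30):
            vecs = rng.normal(size=(20, 6))
            t = rng.normal(size=6)
            got = list(topk_similar_heads(t, fm(vecs), 5))
            sims = vecs @ t / (np.linalg.norm(vecs, axis=1) * np.linalg.norm(t))
            want = sorted(range(20), key=lambda i: (-sims[i], i))[:5]
            assert got == want

    def test_zero_vector_rejected(self):
        with pytest.raises(FloatingPointError):
            topk_similar_heads(np.zeros(3), fm(np.eye(3)), 1)

    def test_k_larger_than_batch_rejected(self):
        with pytest.raises(DonorPoolError):
            topk_similar_heads(np.ones(3), fm(np.eye(3)), 4)


class TestCompose:
    def test_full_mask_keeps_tail(self):
        tail = np.full((4, 4, 3), 0.5)
        donor = np.full((4, 4, 3), 0.9)
        mask = MixMask(width=4, height=4, s=1.0, rect=(0, 0, 4, 4))
        out, own = compose(tail, [donor], [mask])
        np.testing.assert_array_equal(out, tail)
        assert (own == 0).all()

    def test_one_pixel_mask_is_nearly_all_donor(self):
        tail = np.full((4, 4, 3), 0.5)
        donor = np.full((4, 4, 3), 0.9)
        mask = MixMask(width=4, height=4, s=0.25, rect=(0, 0, 1, 1))
        out, own = compose(tail, [donor], [mask])
        assert out[0, 0, 0] == 0.5
        assert (own == 1).sum() == 15

    def test_two_step_hand_composite(self):
        """4x4 constant-colour images with hand-placed rectangles."""
        tail = np.full((4, 4, 3), 0.5)
        d1 = np.full((4, 4, 3), 0.2)
        d2 = np.full((4, 4, 3), 0.8)
        m1 = MixMask(width=4, height=4, s=0.5, rect=(0, 0, 2, 2))
        m2 = MixMask(width=4, height=4, s=0.5, rect=(1, 1, 2, 2))
        out, own = compose(tail, [d1, d2], [m1, m2])
        # hand enumeration: inside both rects -> tail; inside m2 only -> d1;
        # outside m2 -> d2
        expected_own = np.full((4, 4), 2)
        expected_own[1, 1] = 0
        expected_own[1, 2] = expected_own[2, 1] = expected_own[2, 2] = 1
        np.testing.assert_array_equal(own, expected_own)
        expected_vals = np.where(
            expected_own == 0, 0.5, np.where(expected_own == 1, 0.2, 0.8)
        )
        np.testing.assert_allclose(out[..., 0], expected_vals)

    def test_shape_mismatch_rejected(self):
        tail = np.zeros((4, 4, 3))
        with pytest.raises(ValueError):
            compose(tail, [np.zeros((5, 5, 3))],
                    [MixMask(width=4, height=4, s=0.5, rect=(0, 0, 2, 2))])

    def test_deterministic_given_inputs(self, rng):
        tail = rng.uniform(size=(6, 6, 3))
        donors = [rng.uniform(size=(6, 6, 3)) for _ in range(2)]
        masks = [sample_mask(6, 6, (0.2, 0.9), rng) for _ in range(2)]
        a, _ = compose(tail, donors, masks)
        b, _ = compose(tail, donors, masks)
        np.testing.assert_array_equal(a, b)


class TestLabels:
    def test_pure_tail_one_hot_under_both_policies(self):
        own = np.zeros((4, 4), dtype=int)
        for policy in ("area-mix", "tail-only"):
            lab = make_label(own, [2], 5, policy)
            assert lab[2] == 1.0 and lab.sum() == 1.0

    def test_quarter_donor_area_mix(self):
        own = np.zeros((4, 4), dtype=int)
        own[:2, :2] = 1
        lab = make_label(own, [0, 1], 2, "area-mix")
        np.testing.assert_allclose(lab, [0.75, 0.25])

    def test_hand_composite_label_matches_pixel_fractions(self):
        m1 = MixMask(width=4, height=4, s=0.5, rect=(0, 0, 2, 2))
        m2 = MixMask(width=4, height=4, s=0.5, rect=(1, 1, 2, 2))
        own = ownership_from_masks([m1, m2])
        lab = make_label(own, [0, 1, 2], 3, "area-mix")
        np.testing.assert_allclose(lab, [1 / 16, 3 / 16, 12 / 16])

    def test_tail_only_ignores_donors(self):
        own = np.ones((2, 2), dtype=int)
        lab = make_label(own, [3, 1], 4, "tail-only")
        assert lab[3] == 1.0


class TestOversampleTail:
    def setup_problem(self, rng, tail_sizes=(1, 5, 10), head_size=20):
        sizes = [head_size] + list(tail_sizes)
        labels = np.concatenate([np.full(n, c) for c, n in enumerate(sizes)])
        vecs = rng.normal(size=(len(labels), 4)) + labels[:, None]
        feats = fm(vecs)
        donor_pool = feats.sample_ids[labels == 0]
        return labels, feats, donor_pool

    def test_recipe_counts_reach_target(self, rng):
        labels, feats, pool = self.setup_problem(rng)
        recipes = oversample_tail(
            labels, [1, 2, 3], pool, feats, m=10.0, image_size=(8, 8), rng=rng
        )
        per_class = {c: sum(r.tail_class == c for r in recipes) for c in (1, 2, 3)}
        assert per_class == {1: 9, 2: 5, 3: 0}

    def test_class_already_at_target_gets_no_recipes(self, rng):
        labels, feats, pool = self.setup_problem(rng, tail_sizes=(10,))
        recipes = oversample_tail(
            labels, [1], pool, feats, m=10.0, image_size=(8, 8), rng=rng
        )
        assert recipes == []

    def test_empty_pool_rejected_when_needed(self, rng):
        labels, feats, _ = self.setup_problem(rng)
        with pytest.raises(DonorPoolError):
            oversample_tail(
                labels, [1], np.array([]), feats, m=10.0, image_size=(8, 8), rng=rng
            )

    def test_reproducible_from_seed(self):
        rng1, rng2 = np.random.default_rng(5), np.random.default_rng(5)
        base = np.random.default_rng(0)
        labels, feats, pool = self.setup_problem(base)
        a = oversample_tail(labels, [1, 2], pool, feats, m=10.0,
                            image_size=(8, 8), rng=rng1)
        b = oversample_tail(labels, [1, 2], pool, feats, m=10.0,
                            image_size=(8, 8), rng=rng2)
        assert [r.to_dict() for r in a] == [r.to_dict() for r in b]

    def test_random_policy_changes_only_donor_choice(self, rng):
        labels, feats, pool = self.setup_problem(rng)
        recipes = oversample_tail(labels, [1], pool, feats, m=5.0,
                                  image_size=(8, 8), policy="random", rng=rng)
        assert all(r.donor_ids[0] in set(pool) for r in recipes)

    def test_recipe_log_roundtrip(self, rng, tmp_path):
        labels, feats, pool = self.setup_problem(rng)
        recipes = oversample_tail(labels, [1, 2], pool, feats, m=8.0,
                                  image_size=(8, 8), rng=rng)
        path = tmp_path / "recipes.jsonl"
        write_recipe_log(recipes, path)
        again = read_recipe_log(path)
        assert [r.to_dict() for r in again] == [r.to_dict() for r in recipes]

    def test_compose_recipe_materializes(self, rng):
        labels, feats, pool = self.setup_problem(rng)
        recipes = oversample_tail(labels, [1], pool, feats, m=3.0,
                                  image_size=(8, 8), rng=rng)
        images = rng.uniform(size=(len(labels), 8, 8, 3))
        out = compose_recipe(recipes[0], images)
        assert out.shape == (8, 8, 3)
        assert out.min() >= 0.0 and out.max() <= 1.0


def test_tail_ownership_shrinks_with_more_donors(rng):
    """Mean tail-owned area decreases as composites stack more donor images."""
    means = []
    for k in (1, 3, 5, 10):
        fracs = []
        for _ in range(200):
            masks = [sample_mask(16, 16, (0.0, 1.0), rng) for _ in range(k)]
            own = ownership_from_masks(masks)
            fracs.append((own == 0).mean())
        means.append(np.mean(fracs))
    assert all(a > b for a, b in zip(means, means[1:]))
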
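"""Baseline clustering schemes, evaluation metrics, consensus and ranking."""

from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bayesahc import (
    Partition,
    adjusted_rand_index,
    ahc_infomut,
    ahc_linkage,
    consensus_cluster,
    contingency_table,
    cut_hierarchy,
    proportion_correct,
    rand_index,
    random_ahc,
    rank_methods,
)


def brute_force_rand(a, b):
    la, lb = list(a.labels), list(b.labels)
    n = len(la)
    conc = tot = 0
    for i in range(n):
        for j in range(i + 1, n):
            tot += 1
            if (la[i] == la[j]) == (lb[i] == lb[j]):
                conc += 1
    return conc / tot


def brute_force_ari(a, b):
    """Chance-corrected pair counting straight from the contingency table."""
    t = contingency_table(a, b)
    n = t.sum()

    def c2(x):
        return x * (x - 1) / 2.0

    sum_ij = c2(t).sum()
    sum_a = c2(t.sum(axis=1)).sum()
    sum_b = c2(t.sum(axis=0)).sum()
    exp = sum_a * sum_b / c2(n)
    mx = 0.5 * (sum_a + sum_b)
    if mx == exp:
        return 1.0
    return (sum_ij - exp) / (mx - exp)


def brute_force_accuracy(truth, est):
    """Exhaustive search over injective label maps (small partitions only)."""
    lt, le = np.asarray(truth.labels), np.asarray(est.labels)
    kt, ke = lt.max() + 1, le.max() + 1
    big = max(kt, ke)
    best = 0
    for perm in permutations(range(big), int(ke)):
        mapped = np.array([perm[l] for l in le])
        best = max(best, int(np.sum(mapped == lt)))
    return best / len(lt)


class TestInfomutAHC:
    def test_toy_merge_order(self, toy):
        h = ahc_infomut(toy.sample_covariance())
        assert [m.members for m in h.merges] == [
            (2, 4),
            (0, 1),
            (2, 4, 5),
            (0, 1, 2, 4, 5),
            (0, 1, 2, 3, 4, 5),
        ]

    def test_rejects_auto_stop(self, toy):
        with pytest.raises(ValueError):
            ahc_infomut(toy.sample_covariance(), stop="auto")

    def test_invariant_to_diagonal_rescaling(self, rng):
        a = rng.standard_normal((30, 5))
        s_hat = np.cov(a, rowvar=False)
        c = np.diag([5.0, 0.1, 1.0, 2.0, 0.5])
        h1 = ahc_infomut(s_hat, rng=np.random.default_rng(3))
        h2 = ahc_infomut(c @ s_hat @ c, rng=np.random.default_rng(3))
        assert [m.members for m in h1.merges] == [m.members for m in h2.merges]

    def test_normalized_variant_runs(self, toy):
        h = ahc_infomut(toy.sample_covariance(), normalized=True)
        assert len(h.merges) == 5


class TestLinkageAHC:
    def test_toy_first_two_merges(self, toy):
        h = ahc_linkage(toy.sample_covariance(), "average", use_abs=True)
        assert h.merges[0].members == (2, 4)
        assert h.merges[1].members == (0, 1)

    def test_zero_distance_pair_merges_first(self):
        r = np.eye(4)
        r[0, 3] = r[3, 0] = 1.0  # |r| = 1 -> distance 0
        r[1, 2] = r[2, 1] = 0.5
        h = ahc_linkage(r, "single", use_abs=True)
        assert h.merges[0].members == (0, 3)

    def test_matches_brute_force_average_linkage(self, rng):
        # exhaustive small-instance oracle for the recursive update
        a = rng.standard_normal((40, 4))
        s_hat = np.cov(a, rowvar=False)
        d = np.sqrt(np.diag(s_hat))
        dist = 1.0 - np.abs(s_hat / np.outer(d, d))
        np.fill_diagonal(dist, 0.0)

        clusters = {i: (i,) for i in range(4)}
        order = []
        nid = 4
        while len(clusters) > 1:
            pairs = [(a_, b_) for a_ in clusters for b_ in clusters if a_ < b_]
            best = min(
                pairs,
                key=lambda p: np.mean(
                    [dist[x, y] for x in clusters[p[0]] for y in clusters[p[1]]]
                ),
            )
            merged = tuple(sorted(clusters[best[0]] + clusters[best[1]]))
            order.append(merged)
            del clusters[best[0]], clusters[best[1]]
            clusters[nid] = merged
            nid += 1

        h = ahc_linkage(s_hat, "average", use_abs=True)
        assert [m.members for m in h.merges] == order

    def test_rejects_unknown_criterion(self, toy):
        with pytest.raises(ValueError):
            ahc_linkage(toy.sample_covariance(), "median")


class TestRandomAHC:
    def test_two_variables(self):
        h = random_ahc(2, rng=np.random.default_rng(0))
        assert [m.members for m in h.merges] == [(0, 1)]

    def test_first_pair_uniform(self):
        counts = {}
        for seed in range(10_000):
            h = random_ahc(3, rng=np.random.default_rng(seed))
            counts[h.merges[0].members] = counts.get(h.merges[0].members, 0) + 1
        freqs = np.array(list(counts.values())) / 10_000
        assert len(counts) == 3
        assert np.all(np.abs(freqs - 1 / 3) < 0.02)

    def test_chance_level_ari(self):
        truth = Partition(labels=(0, 0, 0, 1, 1, 2, 2, 2))
        aris = [
            adjusted_rand_index(truth, cut_hierarchy(random_ahc(8, np.random.default_rng(s)), 3))
            for s in range(2000)
        ]
        assert abs(float(np.mean(aris))) < 0.03


class TestRandIndices:
    def test_identical_partitions(self):
        p = Partition(labels=(0, 0, 1, 2))
        assert rand_index(p, p) == 1.0
        assert adjusted_rand_index(p, p) == 1.0

    def test_crossed_pairs(self):
        a = Partition(labels=(0, 0, 1, 1))
        b = Partition(labels=(0, 1, 0, 1))
        assert rand_index(a, b) == pytest.approx(2 / 6)
        assert adjusted_rand_index(a, b) == pytest.approx(-0.5)
        assert adjusted_rand_index(a, b) == pytest.approx(brute_force_ari(a, b))

    def test_singletons_vs_one_cluster(self):
        a = Partition(labels=(0, 1, 2, 3))
        b = Partition(labels=(0, 0, 0, 0))
        assert rand_index(a, b) == 0.0

    def test_degenerate_identical_cases(self):
        ones = Partition(labels=(0, 0, 0))
        singles = Partition(labels=(0, 1, 2))
        assert adjusted_rand_index(ones, ones) == 1.0
        assert adjusted_rand_index(singles, singles) == 1.0

    def test_matches_brute_force_on_random_partitions(self, rng):
        for _ in range(100):
            d = int(rng.integers(2, 7))
            a = Partition(labels=tuple(rng.integers(0, 3, size=d)))
            b = Partition(labels=tuple(rng.integers(0, 3, size=d)))
            assert rand_index(a, b) == pytest.approx(brute_force_rand(a, b))
            assert adjusted_rand_index(a, b) == pytest.approx(brute_force_ari(a, b))

    @given(st.lists(st.integers(0, 3), min_size=2, max_size=8), st.permutations(range(4)))
    @settings(max_examples=50, deadline=None)
    def test_invariant_to_label_permutation(self, labels, perm):
        a = Partition(labels=tuple(labels))
        b = Partition(labels=tuple(perm[l] for l in labels))
        assert adjusted_rand_index(a, b) == pytest.approx(1.0)
        assert rand_index(a, b) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        a = Partition(labels=tuple(rng.integers(0, 3, size=6)))
        b = Partition(labels=tuple(rng.integers(0, 3, size=6)))
        assert rand_index(a, b) == rand_index(b, a)
        assert adjusted_rand_index(a, b) == adjusted_rand_index(b, a)


class TestProportionCorrect:
    def test_relabelled_truth_scores_one(self):
        truth = Partition(labels=(0, 0, 1, 1, 2))
        est = Partition(labels=(2, 2, 0, 0, 1))
        assert proportion_correct(truth, est) == 1.0

    def test_split_cluster(self):
        truth = Partition(labels=(0, 0, 0, 1, 1, 1))
        est = Partition(labels=(0, 0, 0, 1, 1, 2))
        assert proportion_correct(truth, est) == pytest.approx(5 / 6)

    def test_single_cluster_estimate(self):
        truth = Partition(labels=(0, 0, 1, 1, 2, 2))
        est = Partition(labels=(0,) * 6)
        assert proportion_correct(truth, est) == pytest.approx(1 / 3)

    def test_matches_exhaustive_label_map(self, rng):
        for _ in range(50):
            d = int(rng.integers(2, 7))
            truth = Partition(labels=tuple(rng.integers(0, 3, size=d)))
            est = Partition(labels=tuple(rng.integers(0, 3, size=d)))
            assert proportion_correct(truth, est) == pytest.approx(
                brute_force_accuracy(truth, est)
            )


class TestConsensus:
    def test_identical_inputs(self):
        p = Partition(labels=(0, 0, 1, 1))
        stability, consensus = consensus_cluster([p] * 5, k=2)
        assert consensus == p
        assert set(np.unique(stability)) <= {0.0, 1.0}
        np.testing.assert_array_equal(np.diag(stability), 1.0)

    def test_stability_bounds_and_symmetry(self, rng):
        parts = [
            Partition(labels=tuple(rng.integers(0, 3, size=6))) for _ in range(10)
        ]
        stability, _ = consensus_cluster(parts, k=3)
        assert np.all((stability >= 0) & (stability <= 1))
        np.testing.assert_allclose(stability, stability.T)

    def test_recovers_majority_structure(self, rng):
        halves = Partition(labels=(0, 0, 0, 0, 1, 1, 1, 1))
        ensemble = []
        for i in range(50):
            if i % 10 == 0:  # 10% disagreeing partitions
                ensemble.append(Partition(labels=tuple(rng.integers(0, 2, size=8))))
            else:
                ensemble.append(halves)
        _, consensus = consensus_cluster(ensemble, k=2)
        assert consensus == halves

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            consensus_cluster([], k=2)


class TestRankMethods:
    def test_single_method(self):
        assert rank_methods({"m": {"ari": [0.5], "accuracy": [0.5]}}) == ["m"]

    def test_median_tie_broken_by_quartile(self):
        results = {
            "a": {"ari": [0.0, 0.5, 1.0], "accuracy": [0.5] * 3},
            "b": {"ari": [0.4, 0.5, 0.6], "accuracy": [0.5] * 3},
        }
        assert rank_methods(results) == ["b", "a"]

    def test_known_lexicographic_order(self):
        results = {
            "worst": {"ari": [0.1, 0.1, 0.1], "accuracy": [0.2] * 3},
            "best": {"ari": [0.9, 0.9, 0.9], "accuracy": [0.9] * 3},
            "mid": {"ari": [0.1, 0.5, 0.9], "accuracy": [0.5] * 3},
        }
        assert rank_methods(results) == ["best", "mid", "worst"]
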
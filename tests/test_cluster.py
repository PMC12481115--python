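"""Pooling, Ward clustering, gap statistic, matching, temporal comparison."""

import itertools

import numpy as np
import pytest

from emgsynergy import (
    SynergyDecomposition,
    compare_temporal,
    gap_statistic,
    make_templates,
    match_groups,
    pool_group,
    subject_invariant,
    ward_cluster,
)
from emgsynergy.cluster import ClusterSolution, brute_force_match, cluster_group
from emgsynergy.exceptions import (
    EmptySetError,
    InsufficientSampleError,
    LabelError,
    OrderError,
)


def _dec(W, labels=None):
    W = np.asarray(W, dtype=float)
    return SynergyDecomposition(
        W=W, C=np.zeros((W.shape[1], 1)), n=W.shape[1],
        vaf_curve=np.full(W.shape[0], np.nan), vaf_selected=np.nan,
        residual_norm=0.0, restarts=1, seed=0,
        muscle_labels=labels or [f"m{i}" for i in range(W.shape[0])])


class TestPoolGroup:
    def test_counts_all_columns(self, rng):
        d1 = _dec(rng.random((16, 3)))
        d2 = _dec(rng.random((16, 4)))
        pooled = pool_group([d1, d2], ["s1", "s2"])
        assert len(pooled) == 7
        assert pooled.subject_ids == ["s1"] * 3 + ["s2"] * 4

    def test_vectors_unit_norm(self, rng):
        pooled = pool_group([_dec(rng.random((8, 5)) * 7)])
        np.testing.assert_allclose(
            np.linalg.norm(pooled.vectors, axis=1), 1.0, atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(EmptySetError):
            pool_group([])

    def test_label_mismatch_rejected(self, rng):
        d1 = _dec(rng.random((3, 2)), labels=["a", "b", "c"])
        d2 = _dec(rng.random((3, 2)), labels=["a", "b", "X"])
        with pytest.raises(LabelError):
            pool_group([d1, d2])


class TestWardCluster:
    def test_two_blobs_separate(self, rng):
        blob1 = rng.normal(0.0, 0.05, (10, 4))
        blob2 = rng.normal(5.0, 0.05, (10, 4))
        labels = ward_cluster(np.vstack([blob1, blob2]), 2)
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]

    def test_full_cut_gives_singletons(self, rng):
        X = rng.random((7, 3))
        assert len(set(ward_cluster(X, 7))) == 7

    def test_matches_reference_agglomeration(self, rng):
        sk = pytest.importorskip("sklearn.cluster")
        X = rng.random((10, 5))
        ours = ward_cluster(X, 3)
        ref = sk.AgglomerativeClustering(n_clusters=3, linkage="ward").fit(X)
        # same partition up to label permutation
        pairs = {(i, j) for i, j in itertools.combinations(range(10), 2)
                 if ours[i] == ours[j]}
        ref_pairs = {(i, j) for i, j in itertools.combinations(range(10), 2)
                     if ref.labels_[i] == ref.labels_[j]}
        assert pairs == ref_pairs

    def test_invalid_h_rejected(self, rng):
        with pytest.raises(OrderError):
            ward_cluster(rng.random((5, 2)), 0)
        with pytest.raises(OrderError):
            ward_cluster(rng.random((5, 2)), 6)


class TestGapStatistic:
    def test_three_blobs_recovered(self, rng):
        centers = np.eye(3)
        X = np.vstack([c + rng.normal(0, 0.01, (10, 3)) for c in centers])
        _, h, found = gap_statistic(X, h_range=(2, 8), B=100, seed=0)
        assert found and h == 3

    def test_template_blobs_recovered_across_k(self):
        for k in (3, 6, 8):
            t = make_templates(k, seed=k)
            rng = np.random.default_rng(5)
            X = np.vstack([c + rng.normal(0, 0.05, (10, 16)) for c in t])
            X /= np.linalg.norm(X, axis=1, keepdims=True)
            _, h, found = gap_statistic(X, (2, 20), B=100, seed=3)
            assert found and h == k

    def test_minimum_b_warns(self, rng):
        X = rng.random((25, 4))
        with pytest.warns(UserWarning, match="reference datasets"):
            gap_statistic(X, h_range=(2, 5), B=2, seed=0)

    def test_structureless_data_prefers_smallest_h(self):
        votes = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.random((30, 6))
            _, h, _ = gap_statistic(X, h_range=(2, 10), B=50, seed=seed)
            votes.append(h)
        assert (np.array(votes) == 2).mean() >= 0.75

    def test_too_few_vectors_rejected(self, rng):
        with pytest.raises(OrderError):
            gap_statistic(rng.random((5, 3)), h_range=(2, 10), B=10)


class TestSubjectInvariant:
    def _solution(self, support):
        support = np.asarray(support)
        h = len(support)
        m = 4
        cents = np.eye(h, m)
        return ClusterSolution(
            pooled=None, linkage=None, h=h, gap_curve=np.empty((0, 3)),
            gap_found=True, assignments=np.arange(h) + 1,
            centroids_raw=cents, centroids=cents, support=support)

    def test_thirteen_subjects_threshold_rounds_up(self):
        sol = self._solution([5, 4, 13])
        kept, _ = subject_invariant(sol, group_size=13, fraction=1 / 3)
        assert kept.tolist() == [1, 3]  # need ceil(13/3) = 5

    def test_small_support_dropped(self):
        sol = self._solution([2, 8])
        kept, _ = subject_invariant(sol, group_size=8, fraction=1 / 3)
        assert kept.tolist() == [2]  # need 3

    def test_zero_fraction_keeps_all(self):
        sol = self._solution([1, 1, 1])
        kept, _ = subject_invariant(sol, group_size=10, fraction=0.0)
        assert kept.tolist() == [1, 2, 3]


class TestMatchGroups:
    def test_identical_sets_pair_perfectly(self, rng):
        A = rng.random((4, 8))
        A /= np.linalg.norm(A, axis=1, keepdims=True)
        res = match_groups(A, A)
        assert len(res.pairs) == 4
        assert all(s == pytest.approx(1.0) for _, _, s in res.pairs)
        assert all(a == b for a, b, _ in res.pairs)

    def test_orthogonal_sets_all_unmatched(self):
        A = np.eye(3, 6)
        B = np.eye(3, 6, k=3)
        res = match_groups(A, B)
        assert res.pairs == []
        assert res.unmatched_A == [0, 1, 2] and res.unmatched_B == [0, 1, 2]

    def test_empty_input_gives_empty_match(self):
        res = match_groups(np.empty((0, 4)), np.eye(2, 4))
        assert res.pairs == [] and res.unmatched_B == [0, 1]

    @pytest.mark.parametrize("na,nb", [(3, 4), (4, 4), (5, 3)])
    def test_total_sp_matches_exhaustive_optimum(self, rng, na, nb):
        A = rng.random((na, 6))
        A /= np.linalg.norm(A, axis=1, keepdims=True)
        B = rng.random((nb, 6))
        B /= np.linalg.norm(B, axis=1, keepdims=True)
        res = match_groups(A, B, sp_threshold=-1.0)  # keep all pairs
        total = sum(s for _, _, s in res.pairs)
        assert total == pytest.approx(brute_force_match(A, B), abs=1e-10)


class TestCompareTemporal:
    def test_identical_groups_show_nothing(self, rng):
        base = np.abs(np.sin(np.linspace(0, 3, 200)))
        A = base + rng.normal(0, 0.05, (8, 200))
        B = base + rng.normal(0, 0.05, (8, 200))
        res = compare_temporal(A, B, n_perm=199, seed=0)
        assert res.clusters == []

    def test_localized_offset_detected(self, rng):
        base = np.abs(np.sin(np.linspace(0, 3, 200)))
        A = base + rng.normal(0, 0.02, (8, 200))
        B = base + rng.normal(0, 0.02, (8, 200))
        B[:, 50:101] += 1.0
        res = compare_temporal(A, B, n_perm=199, seed=0)
        assert res.clusters, "offset window not detected"
        covered = set()
        for s, e in res.clusters:
            covered.update(range(s, e + 1))
        overlap = len(covered & set(range(50, 101))) / 51
        assert overlap > 0.8

    def test_null_false_positive_rate_controlled(self):
        hits = 0
        n_sim = 200
        for sim in range(n_sim):
            rng = np.random.default_rng(sim)
            A = rng.normal(0, 1, (6, 50))
            B = rng.normal(0, 1, (6, 50))
            res = compare_temporal(A, B, n_perm=99, seed=sim, alpha=0.05)
            hits += bool(res.clusters)
        assert hits / n_sim <= 0.05 + 0.033  # binomial 95% slack on alpha

    def test_single_subject_rejected(self, rng):
        with pytest.raises(InsufficientSampleError):
            compare_temporal(rng.random((1, 50)), rng.random((5, 50)))


def test_cluster_centroids_invariant_to_vector_order(rng):
    W = rng.random((16, 12))
    pooled = pool_group([_dec(W)], ["s"])
    sol = cluster_group(pooled, h=3)
    perm = rng.permutation(12)
    pooled2 = pool_group([_dec(W[:, perm])], ["s"])
    sol2 = cluster_group(pooled2, h=3)
    got = {tuple(np.round(c, 10)) for c in sol.centroids}
    got2 = {tuple(np.round(c, 10)) for c in sol2.centroids}
    assert got == got2
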
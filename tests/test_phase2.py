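"""Repeat profiles, the weighted cluster graph, MCL and granularity tuning."""

import numpy as np
import pytest

import metasep as ms
from metasep.phase2 import ClusterGraphF, _mcluster_weights

from conftest import make_reads


def graph_of(W: np.ndarray) -> ClusterGraphF:
    W = np.asarray(W, dtype=float).copy()
    np.fill_diagonal(W, 0.0)
    np.fill_diagonal(W, W.sum(axis=1))
    return ClusterGraphF(W=W)


class TestRepeatProfile:
    def _setup(self):
        # pair 0: mate 1 corresponds to cluster 0 and contains a repeat;
        # mate 2 is fully unclustered
        rng = np.random.default_rng(1)
        m1 = "".join(rng.choice(list("ACGT"), 40))
        m2 = "".join(rng.choice(list("ACGT"), 40))
        reads = make_reads([m1], [m2])
        l = 12
        mat, _ = reads.mate_window_matrix(l)
        m1_codes = np.sort(np.unique(mat[0]))
        m2_codes = np.sort(np.unique(mat[1]))
        return reads, l, mat, m1_codes, m2_codes

    def test_own_repeats_and_unclustered_mate_lmers_attributed(self):
        reads, l, mat, m1_codes, m2_codes = self._setup()
        repeat_code = mat[0, 5]
        cluster = np.sort(m1_codes[m1_codes != repeat_code])
        clusters = ms.Phase1Clusters(
            clusters=[cluster], read_map=np.array([0, -1]), frozen=[False]
        )
        partition = ms.LmerPartition(
            l=l,
            U=cluster,
            R=np.array([repeat_code]),
            discarded=np.empty(0, dtype=np.int64),
            K_err=1,
            K_repeat=10,
            lam_hat=20.0,
        )
        profile = ms.build_repeat_profile(clusters, reads, partition)
        assert repeat_code in profile.R[0]
        # every l-mer of the unclustered mate lands in R_0 too
        assert set(m2_codes[~np.isin(m2_codes, cluster)]) <= set(profile.R[0])

    def test_mate_inside_cluster_contributes_nothing(self):
        reads, l, mat, m1_codes, m2_codes = self._setup()
        both = np.sort(np.unique(np.concatenate([m1_codes, m2_codes])))
        clusters = ms.Phase1Clusters(
            clusters=[both], read_map=np.array([0, 0]), frozen=[False]
        )
        partition = ms.LmerPartition(
            l=l, U=both, R=np.empty(0, dtype=np.int64),
            discarded=np.empty(0, dtype=np.int64),
            K_err=1, K_repeat=10, lam_hat=20.0,
        )
        profile = ms.build_repeat_profile(clusters, reads, partition)
        assert profile.R[0].size == 0

    def test_planted_common_repeat_links_genome_clusters(self):
        # a repeat shared by two genomes must appear in repeat sets of
        # clusters on both sides
        spec = ms.CommunitySpec(
            genome_lengths=[20_000, 20_000], common_repeat_fraction=0.02,
            coverage=20, seed=17,
        )
        truth, reads, origin = ms.simulate(spec)
        counts = ms.count_lmers(reads, 20)
        part = ms.classify_lmers(counts)
        g = ms.build_graph(reads, part)
        g, part = ms.prune_high_degree(g, reads.L, 20, part)
        T = ms.select_T(reads.N, reads.L, 20, 40_000).T
        clusters = ms.expand_clusters(g, reads, T=T, l=20, rng_seed=17)
        clusters = ms.consolidate_paired(clusters, reads, min_links=3, l=20)
        profile = ms.build_repeat_profile(clusters, reads, part)
        common = set(truth.codes_of_class(2).tolist())
        holders = [
            i for i, r in enumerate(profile.R)
            if clusters.clusters[i].size > 500 and common & set(r.tolist())
        ]
        # clusters from both genomes hold common repeats
        g0 = truth.copy_counts[0]
        sides = set()
        for i in holders:
            sample = clusters.clusters[i][:: max(1, clusters.clusters[i].size // 50)]
            cls0 = truth.class_of(sample)
            pos = np.searchsorted(truth.lmer_codes, sample)
            in0 = g0[np.clip(pos, 0, g0.size - 1)] > 0
            sides.add(bool(np.mean(in0) > 0.5))
        assert sides == {True, False}


class TestClusterGraph:
    def test_intersection_weights(self):
        profile = ms.RepeatProfile(
            R=[np.array([1, 2, 3]), np.array([2, 3, 4]), np.array([9])]
        )
        F = ms.build_cluster_graph(profile)
        assert F.W[0, 1] == 2 and F.W[1, 0] == 2
        assert F.W[0, 2] == 0 and F.W[1, 2] == 0
        # diagonal: total incident weight
        assert F.W[0, 0] == 2 and F.W[2, 2] == 0

    def test_disjoint_sets_give_edgeless_graph(self):
        profile = ms.RepeatProfile(R=[np.array([1]), np.array([2])])
        F = ms.build_cluster_graph(profile)
        assert F.off_diagonal().sum() == 0

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            ms.build_cluster_graph(ms.RepeatProfile(R=[]))


class TestMCL:
    def test_two_cliques_split(self):
        W = np.zeros((6, 6))
        for blk in ([0, 1, 2], [3, 4, 5]):
            for a in blk:
                for b in blk:
                    if a != b:
                        W[a, b] = 10
        W[2, 3] = W[3, 2] = 1
        # oracle: connected components after deleting the weak bridge
        assert ms.mcl(W, r=2.0) == [[0, 1, 2], [3, 4, 5]]

    def test_edgeless_graph_gives_singletons(self):
        assert ms.mcl(np.zeros((4, 4)), r=2.0) == [[0], [1], [2], [3]]

    def test_single_clique_gives_one_cluster(self):
        W = np.full((5, 5), 7.0)
        np.fill_diagonal(W, 0)
        assert ms.mcl(W, r=2.0) == [[0, 1, 2, 3, 4]]

    def test_output_is_partition(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = int(rng.integers(2, 12))
            W = rng.random((n, n)) * (rng.random((n, n)) < 0.4)
            W = (W + W.T) / 2
            np.fill_diagonal(W, 0)
            part = ms.mcl(W, r=2.0)
            flat = sorted(i for grp in part for i in grp)
            assert flat == list(range(n))

    def test_idempotent_on_quotient_graph(self):
        # rerunning on the block-quotient of its own output reproduces it
        W = np.zeros((6, 6))
        for blk in ([0, 1, 2], [3, 4, 5]):
            for a in blk:
                for b in blk:
                    if a != b:
                        W[a, b] = 10
        W[2, 3] = W[3, 2] = 1
        part = ms.mcl(W, r=2.0)
        # quotient: inter weights off-diagonal, intra weights as self-loops
        Q = np.zeros((2, 2))
        for i, gi in enumerate(part):
            for j, gj in enumerate(part):
                if i != j:
                    Q[i, j] = W[np.ix_(gi, gj)].sum()
                else:
                    Q[i, i] = W[np.ix_(gi, gi)].sum() / 2
        assert ms.mcl(Q, r=2.0, keep_self_loops=True) == [[0], [1]]

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ms.mcl(np.zeros((2, 2)), r=1.0)
        with pytest.raises(ValueError):
            ms.mcl(np.zeros((2, 2)), r=2.0, expansion=1)


class TestValidity:
    def test_normalized_ratio_above_eps_fails(self):
        # W_ij=50, W_ii=1e4, W_jj=2.5e3: 50/sqrt(2.5e7)=0.01 > 1e-3
        intra = np.array([1e4, 2.5e3])
        inter = np.array([[0, 50.0], [50.0, 0]])
        assert not ms.is_valid(0, {0, 1}, intra, inter, eps=1e-3)
        assert ms.is_valid(0, {0, 1}, intra, inter, eps=0.02)

    def test_zero_inter_weight_is_separated(self):
        intra = np.array([0.0, 0.0])
        inter = np.zeros((2, 2))
        assert ms.is_valid(0, {0, 1}, intra, inter)

    def test_zero_intra_with_positive_inter_is_invalid(self):
        intra = np.array([0.0, 10.0])
        inter = np.array([[0, 5.0], [5.0, 0]])
        assert not ms.is_valid(0, {0, 1}, intra, inter)

    def test_product_normalization_alternative(self):
        intra = np.array([100.0, 100.0])
        inter = np.array([[0, 5.0], [5.0, 0]])
        # geometric: 5/100 = 0.05 > eps; product: 5/10^4 = 5e-4 <= 1e-3
        assert not ms.is_valid(0, {0, 1}, intra, inter, normalization="geometric")
        assert ms.is_valid(0, {0, 1}, intra, inter, normalization="product")


class TestTuneGranularity:
    def test_separated_blocks_accepted_at_first_r(self):
        W = np.zeros((6, 6))
        for blk in ([0, 1, 2], [3, 4, 5]):
            for a in blk:
                for b in blk:
                    if a != b:
                        W[a, b] = 10
        F = graph_of(W)
        sizes = np.full(6, 100)
        res = ms.tune_granularity(F, sizes, min_big_size=150)
        assert res.r == ms.phase2.DEFAULT_R_SCHEDULE[0]
        assert res.accepted
        assert sorted(map(sorted, res.m_clusters)) == [[0, 1, 2], [3, 4, 5]]
        assert res.valid == res.big

    def test_strong_inter_links_force_lower_granularity(self):
        # blocks joined by substantial weight: high r over-fragments and
        # fails validity, a lower r merges them
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 10
        W[2, 3] = W[3, 2] = 10
        W[1, 2] = W[2, 1] = 8
        F = graph_of(W)
        sizes = np.full(4, 100)
        res = ms.tune_granularity(F, sizes, min_big_size=150)
        if len(res.m_clusters) == 1:
            assert res.r < ms.phase2.DEFAULT_R_SCHEDULE[0]
        else:
            # if never valid, the last scheduled r is kept with a warning
            assert not res.accepted

    def test_single_node_trivially_accepted(self):
        F = graph_of(np.zeros((1, 1)))
        res = ms.tune_granularity(F, np.array([1000]), min_big_size=100)
        assert res.m_clusters == [[0]]
        assert res.accepted

    def test_bad_schedule_rejected(self):
        F = graph_of(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            ms.tune_granularity(F, np.array([1, 1]), 1, r_schedule=(2.0, 3.0))


class TestMergeClusters:
    def test_union_and_identity(self):
        spec = ms.CommunitySpec(genome_lengths=[5000], coverage=15, seed=19)
        _, reads, _ = ms.simulate(spec)
        counts = ms.count_lmers(reads, 20)
        part = ms.classify_lmers(counts)
        g = ms.build_graph(reads, part)
        clusters = ms.expand_clusters(g, reads, T=5, l=20, rng_seed=19)
        k = clusters.n_clusters
        if k < 2:
            pytest.skip("need >= 2 phase-1 clusters for a merge")
        m = ms.MClusterResult(
            m_clusters=[[0, 1]] + [[i] for i in range(2, k)], r=2.0
        )
        merged = ms.merge_clusters(clusters, m, reads, l=20)
        assert merged.n_clusters == k - 1
        expect = np.union1d(clusters.clusters[0], clusters.clusters[1])
        assert np.array_equal(merged.clusters[0], expect)

    def test_non_partition_rejected(self):
        clusters = ms.Phase1Clusters(
            clusters=[np.array([1]), np.array([2])],
            read_map=np.array([-1, -1]),
            frozen=[False, False],
        )
        reads = make_reads(["ACGTACGTACGTACGTACGTACGT"])
        m = ms.MClusterResult(m_clusters=[[0]], r=2.0)
        with pytest.raises(ValueError):
            ms.merge_clusters(clusters, m, reads, l=12)
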
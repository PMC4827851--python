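"""Partition-similarity and module-quality measures.

Closed-form cases are asserted exactly; where an established library
implements the same quantity (scikit-learn, igraph, edlib) it serves as an
independent oracle on random instances.
"""
import edlib
import igraph as ig
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score, mutual_info_score
from sklearn.metrics.cluster import pair_confusion_matrix

from lsgc import metrics as m


def random_labels(rng, D, k):
    return rng.integers(0, k, size=D)


class TestPairCounts:
    def test_identical_partitions_have_no_disagreement(self, rng):
        lab = random_labels(rng, 30, 4)
        pc = m.pair_counts(lab, lab)
        assert pc.N01 == pc.N10 == 0
        assert pc.total == 30 * 29 // 2

    def test_three_vertex_enumeration(self):
        # A = {a,b}{c}, B = {a}{b,c}
        pc = m.pair_counts([0, 0, 1], [0, 1, 1])
        assert (pc.N11, pc.N00, pc.N01, pc.N10) == (0, 1, 1, 1)

    def test_all_singletons(self):
        pc = m.pair_counts(np.arange(10), np.arange(10)[::-1])
        assert pc.N00 == 45 and pc.N11 == 0

    def test_matches_sklearn_pair_confusion(self, rng):
        a, b = random_labels(rng, 40, 5), random_labels(rng, 40, 3)
        pc = m.pair_counts(a, b)
        C = pair_confusion_matrix(a, b)  # ordered pairs: twice our counts
        assert C[1, 1] == 2 * pc.N11 and C[0, 0] == 2 * pc.N00
        assert C[0, 1] == 2 * pc.N01 and C[1, 0] == 2 * pc.N10


class TestRandFamily:
    def test_identical_gives_one(self, rng):
        lab = random_labels(rng, 20, 3)
        assert m.rand_index(lab, lab) == 1.0
        assert m.adjusted_rand(lab, lab) == 1.0

    def test_three_vertex_rand_is_one_third(self):
        assert m.rand_index([0, 0, 1], [0, 1, 1]) == pytest.approx(1 / 3)

    def test_symmetry(self, rng):
        a, b = random_labels(rng, 25, 4), random_labels(rng, 25, 4)
        assert m.rand_index(a, b) == m.rand_index(b, a)
        assert m.adjusted_rand(a, b) == pytest.approx(m.adjusted_rand(b, a))

    def test_adjusted_rand_matches_sklearn(self, rng):
        for _ in range(10):
            a, b = random_labels(rng, 30, 4), random_labels(rng, 30, 5)
            assert m.adjusted_rand(a, b) == pytest.approx(adjusted_rand_score(a, b))

    def test_adjusted_rand_near_zero_for_independent_partitions(self, rng):
        vals = [
            m.adjusted_rand(random_labels(rng, 60, 4), random_labels(rng, 60, 4))
            for _ in range(200)
        ]
        assert abs(np.mean(vals)) < 0.01

    def test_contingency_closed_form_on_six_vertices(self):
        # A = {0,1,2}{3,4,5}, B = {0,1}{2,3}{4,5}: pair counts by hand
        a = [0, 0, 0, 1, 1, 1]
        b = [0, 0, 1, 1, 2, 2]
        pc = m.pair_counts(a, b)
        assert (pc.N11, pc.N10, pc.N01, pc.N00) == (2, 4, 1, 8)
        expected = 2 * (2 * 8 - 4 * 1) / ((2 + 4) * (4 + 8) + (2 + 1) * (1 + 8))
        assert m.adjusted_rand(a, b) == pytest.approx(expected)


class TestInformationMeasures:
    def test_identical_partition_mi_equals_entropy_and_vi_zero(self, rng):
        lab = random_labels(rng, 40, 5)
        _, counts = np.unique(lab, return_counts=True)
        p = counts / counts.sum()
        h = -(p * np.log(p)).sum()
        assert m.mutual_information(lab, lab) == pytest.approx(h)
        assert m.variation_of_information(lab, lab) == pytest.approx(0.0, abs=1e-12)

    def test_single_module_partition_has_zero_mi(self, rng):
        lab = random_labels(rng, 30, 4)
        assert m.mutual_information(lab, np.zeros(30, int)) == pytest.approx(0.0)

    def test_mi_matches_sklearn(self, rng):
        a, b = random_labels(rng, 50, 4), random_labels(rng, 50, 6)
        assert m.mutual_information(a, b) == pytest.approx(mutual_info_score(a, b))

    def test_vi_triangle_inequality_on_sampled_triples(self, rng):
        for _ in range(50):
            a, b, c = (random_labels(rng, 20, 4) for _ in range(3))
            ab = m.variation_of_information(a, b)
            bc = m.variation_of_information(b, c)
            ac = m.variation_of_information(a, c)
            assert ac <= ab + bc + 1e-10


class TestSplitJoin:
    def test_identical_is_zero(self, rng):
        lab = random_labels(rng, 30, 4)
        assert m.split_join_distance(lab, lab) == 0

    def test_single_split_module_by_overlap_table(self):
        # one 10-vertex module split 5/5; distance = 5 (one direction only)
        a = np.zeros(10, int)
        b = np.array([0] * 5 + [1] * 5)
        assert m.split_join_distance(a, b) == 5

    def test_matches_igraph_oracle(self, rng):
        for _ in range(10):
            a, b = random_labels(rng, 40, 5), random_labels(rng, 40, 4)
            oracle = ig.compare_communities(list(a), list(b), method="split-join")
            assert m.split_join_distance(a, b) == oracle

    def test_upper_bound_two_d(self, rng):
        a, b = random_labels(rng, 50, 7), random_labels(rng, 50, 7)
        assert m.split_join_distance(a, b) <= 2 * 50


class TestMatchingAndCorrectRatio:
    def test_identity_matching(self, rng):
        lab = random_labels(rng, 30, 4)
        match = m.match_modules(lab, lab)
        assert all(k == v for k, v in match.mapping.items())
        assert m.correct_ratio(lab, lab) == 1.0

    def test_split_module_leaves_half_unmatched(self):
        # D=100: ten 10-vertex modules; module 0 split 5/5 in the second
        a = np.repeat(np.arange(10), 10)
        b = a.copy()
        b[:5] = 99  # new surplus module
        assert m.correct_ratio(a, b) == pytest.approx(0.95)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_label_permutation_invariance(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.integers(0, 4, 40), r.integers(0, 5, 40)
        perm = r.permutation(10)
        assert m.correct_ratio(a, b) == m.correct_ratio(perm[a], b)
        assert m.rand_index(a, b) == m.rand_index(perm[a], perm[b])


class TestTopologyAwareMeasures:
    def test_coverage_closed_forms(self, truth_net_100):
        assert m.coverage(truth_net_100, truth_net_100.labels) < 1.0
        assert m.coverage(truth_net_100, np.zeros(100, int)) == 1.0
        # 10 directed edges, 7 intra
        adj = np.zeros((6, 6), int)
        lab = np.array([0, 0, 0, 1, 1, 1])
        intra = [(1, 0), (2, 0), (0, 1), (2, 1), (4, 3), (5, 3), (3, 4)]
        inter = [(3, 0), (4, 1), (0, 5)]
        for t, s in intra + inter:
            adj[t, s] = 1
        assert m.coverage(adj, lab) == pytest.approx(0.7)

    def test_performance_closed_forms(self, rng):
        adj, _ = _cliques_adj()
        lab = np.array([0] * 5 + [1] * 5)
        assert m.performance(adj, lab) == 1.0
        # single-module partition on a sparse net -> symmetric edge density
        r = (rng.random((8, 8)) < 0.2).astype(int)
        np.fill_diagonal(r, 0)
        sym = r | r.T
        density = sym[np.triu_indices(8, 1)].mean()
        assert m.performance(r, np.zeros(8, int)) == pytest.approx(density)

    def test_performance_matches_pair_audit_on_five_vertices(self, rng):
        adj = (rng.random((5, 5)) < 0.4).astype(int)
        np.fill_diagonal(adj, 0)
        lab = np.array([0, 0, 1, 1, 1])
        good = 0
        for i in range(5):
            for j in range(i + 1, 5):
                linked = bool(adj[i, j] or adj[j, i])
                good += (lab[i] == lab[j]) == linked
        assert m.performance(adj, lab) == pytest.approx(good / 10)

    def test_modularity_closed_forms(self):
        adj, lab = _cliques_adj()
        assert m.modularity(adj, np.zeros(10, int), directed=True) == pytest.approx(0.0)
        assert m.modularity(adj, lab, directed=False) == pytest.approx(0.5)
        # directed formula on a symmetric network equals the undirected one
        assert m.modularity(adj, lab, directed=True) == pytest.approx(
            m.modularity(adj, lab, directed=False)
        )

    def test_undirected_modularity_matches_igraph(self, rng):
        adj = (rng.random((20, 20)) < 0.15).astype(int)
        np.fill_diagonal(adj, 0)
        sym = (adj | adj.T).astype(int)
        lab = random_labels(rng, 20, 3)
        g = ig.Graph.Adjacency(sym.tolist(), mode="undirected")
        assert m.modularity(adj, lab, directed=False) == pytest.approx(
            g.modularity(list(lab))
        )


class TestEditDistance:
    def test_levenshtein_matches_edlib(self, rng):
        for _ in range(10):
            a = "".join(rng.choice(list("01"), size=rng.integers(5, 60)))
            b = "".join(rng.choice(list("01"), size=rng.integers(5, 60)))
            assert m.levenshtein(a, b) == edlib.align(a, b)["editDistance"]

    def test_identical_networks_give_zero(self, rng):
        adj = (rng.random((12, 12)) < 0.3).astype(int)
        np.fill_diagonal(adj, 0)
        lab = np.repeat([0, 1, 2], 4)
        assert m.partition_edit_distance(adj, adj, lab, lab) == 0

    def test_single_flipped_intra_edge_costs_one(self, rng):
        adj = (rng.random((9, 9)) < 0.4).astype(int)
        np.fill_diagonal(adj, 0)
        lab = np.repeat([0, 1, 2], 3)
        other = adj.copy()
        other[1, 0] ^= 1  # flip one intra-module entry of module 0
        assert m.partition_edit_distance(adj, other, lab, lab) == 1

    def test_three_vertex_module_matches_dp_oracle(self, rng):
        adjA = (rng.random((3, 3)) < 0.5).astype(int)
        adjB = (rng.random((3, 3)) < 0.5).astype(int)
        np.fill_diagonal(adjA, 0)
        np.fill_diagonal(adjB, 0)
        lab = np.zeros(3, int)
        sa = "".join(map(str, adjA.ravel()))
        sb = "".join(map(str, adjB.ravel()))
        oracle = edlib.align(sa, sb)["editDistance"]
        assert m.partition_edit_distance(adjA, adjB, lab, lab) == oracle


def _cliques_adj():
    adj = np.zeros((10, 10), int)
    adj[:5, :5] = 1
    adj[5:, 5:] = 1
    np.fill_diagonal(adj, 0)
    return adj, np.array([0] * 5 + [1] * 5)
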
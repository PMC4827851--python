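"""Module-structure quality and partition-similarity measures.

Two families of measures are provided.  Pure partition comparisons
(pair counts, Rand and adjusted Rand indices, mutual information,
variation of information, split-join distance, Jaccard-cost module
matching with the correctly-classified-vertex ratio) depend only on the
two label vectors.  Topology-aware measures (coverage, performance,
modularity, partition edit distance) additionally use network adjacency.
Natural logarithms are used throughout the information measures.

Label vectors may use arbitrary hashable module ids; every measure is
invariant under relabeling.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "PairCounts",
    "ModuleMatching",
    "contingency_table",
    "pair_counts",
    "rand_index",
    "adjusted_rand",
    "mutual_information",
    "variation_of_information",
    "split_join_distance",
    "match_modules",
    "correct_ratio",
    "coverage",
    "performance",
    "modularity",
    "partition_edit_distance",
    "levenshtein",
]


def _labels(P) -> np.ndarray:
    """Accept a Partition-like object (``.labels``) or a label sequence."""
    lab = getattr(P, "labels", P)
    return np.asarray(lab)


def _adjacency(net) -> np.ndarray:
    adj = getattr(net, "adjacency", net)
    return np.asarray(adj)


@dataclass
class PairCounts:
    """Classification of all unordered vertex pairs by two partitions.

    N11: together in both; N00: separated in both; N01: separated in the
    first but together in the second; N10: the opposite.
    """

    N11: int
    N00: int
    N01: int
    N10: int

    @property
    def total(self) -> int:
        return self.N11 + self.N00 + self.N01 + self.N10


@dataclass
class ModuleMatching:
    """Injective map from modules of the first partition to the second,
    minimizing total Jaccard distance over vertex sets."""

    mapping: dict
    cost: float


def contingency_table(Pa, Pb) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Label contingency table and the distinct module ids of each side."""
    a, b = _labels(Pa), _labels(Pb)
    if a.shape != b.shape:
        raise ValueError("partitions must cover the same vertex set")
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    table = np.zeros((ua.size, ub.size), dtype=np.int64)
    np.add.at(table, (ia, ib), 1)
    return table, ua, ub


def pair_counts(Pa, Pb) -> PairCounts:
    """Exhaustive unordered-pair classification of two partitions."""
    table, _, _ = contingency_table(Pa, Pb)
    n = int(table.sum())
    total = n * (n - 1) // 2
    same_both = int((table * (table - 1) // 2).sum())
    a_sizes = table.sum(axis=1)
    b_sizes = table.sum(axis=0)
    same_a = int((a_sizes * (a_sizes - 1) // 2).sum())
    same_b = int((b_sizes * (b_sizes - 1) // 2).sum())
    n10 = same_a - same_both  # together in A only
    n01 = same_b - same_both  # together in B only
    n00 = total - same_both - n10 - n01
    return PairCounts(N11=same_both, N00=n00, N01=n01, N10=n10)


def rand_index(Pa, Pb) -> float:
    """Fraction of vertex pairs classified concordantly, (N11+N00)/all."""
    pc = pair_counts(Pa, Pb)
    return (pc.N11 + pc.N00) / pc.total


def adjusted_rand(Pa, Pb) -> float:
    """Hubert-Arabie chance-corrected Rand index."""
    pc = pair_counts(Pa, Pb)
    num = 2.0 * (pc.N11 * pc.N00 - pc.N10 * pc.N01)
    den = (pc.N11 + pc.N10) * (pc.N10 + pc.N00) + (pc.N11 + pc.N01) * (
        pc.N01 + pc.N00
    )
    if den == 0:  # both partitions trivial (all-same or all-singletons)
        return 1.0
    return num / den


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def mutual_information(Pa, Pb) -> float:
    """Mutual information of the two label assignments (natural log)."""
    table, _, _ = contingency_table(Pa, Pb)
    n = table.sum()
    a = table.sum(axis=1)
    b = table.sum(axis=0)
    nz = table > 0
    pij = table[nz] / n
    outer = np.outer(a, b)[nz] / (n * n)
    return float((pij * np.log(pij / outer)).sum())


def variation_of_information(Pa, Pb) -> float:
    """VI = H(Pa) + H(Pb) - 2 MI; a metric on partitions."""
    table, _, _ = contingency_table(Pa, Pb)
    ha = _entropy(table.sum(axis=1))
    hb = _entropy(table.sum(axis=0))
    vi = ha + hb - 2.0 * mutual_information(Pa, Pb)
    return max(vi, 0.0)  # clip the negative epsilon from rounding


def split_join_distance(Pa, Pb) -> int:
    """van Dongen split-join distance via best-overlap sums both ways."""
    table, _, _ = contingency_table(Pa, Pb)
    n = int(table.sum())
    return int(2 * n - table.max(axis=1).sum() - table.max(axis=0).sum())


def match_modules(Pa, Pb) -> ModuleMatching:
    """Optimal injective module matching under Jaccard-distance cost.

    The cost of pairing module A_k with module B_l is 1 - |A_k ∩ B_l| /
    |A_k ∪ B_l|; the (possibly rectangular) assignment problem is solved
    exactly, leaving surplus modules of the larger partition unmatched.
    """
    table, ua, ub = contingency_table(Pa, Pb)
    a_sizes = table.sum(axis=1, keepdims=True)
    b_sizes = table.sum(axis=0, keepdims=True)
    union = a_sizes + b_sizes - table
    cost = 1.0 - table / union
    rows, cols = linear_sum_assignment(cost)
    mapping = {ua[r]: ub[c] for r, c in zip(rows, cols)}
    return ModuleMatching(mapping=mapping, cost=float(cost[rows, cols].sum()))


def correct_ratio(Pa, Pb, matching: ModuleMatching | None = None) -> float:
    """Fraction of vertices whose module in Pb is matched to their module
    in Pa.  Vertices of unmatched surplus modules count as misclassified."""
    a, b = _labels(Pa), _labels(Pb)
    if a.shape != b.shape:
        raise ValueError("partitions must cover the same vertex set")
    if matching is None:
        matching = match_modules(Pa, Pb)
    mapped = np.array([matching.mapping.get(la, None) == lb for la, lb in zip(a, b)])
    return float(mapped.mean())


def coverage(net, P) -> float:
    """Intra-module directed-edge fraction, |intra edges| / |edges|."""
    adj = _adjacency(net)
    lab = _labels(P)
    same = lab[:, None] == lab[None, :]
    total = adj.sum()
    if total == 0:
        raise ValueError("coverage undefined for an edgeless network")
    return float((adj * same).sum() / total)


def performance(net, P) -> float:
    """Fraction of correctly 'interpreted' unordered vertex pairs.

    A pair counts as correct if it is intra-module and linked by at least
    one arc, or inter-module and not linked in either direction.
    """
    adj = _adjacency(net)
    lab = _labels(P)
    D = adj.shape[0]
    sym = (adj | adj.T).astype(bool)
    same = lab[:, None] == lab[None, :]
    iu = np.triu_indices(D, k=1)
    good = (same[iu] & sym[iu]) | (~same[iu] & ~sym[iu])
    return float(good.mean())


def modularity(net, P, directed: bool = True) -> float:
    """Newman-Girvan (undirected) or Leicht-Newman (directed) modularity.

    Directed: Q = (1/m) sum_{u,v same module} [A_uv - kout_u kin_v / m]
    over the standard source-row orientation; the package's target-row
    adjacency is transposed internally.  Undirected: the network is
    symmetrized first and the degree-based null model is used.
    """
    adj = _adjacency(net)
    lab = _labels(P)
    same = lab[:, None] == lab[None, :]
    if directed:
        A = adj.T.astype(float)  # A[u, v] = 1 iff u -> v
        m = A.sum()
        if m == 0:
            raise ValueError("modularity undefined for an edgeless network")
        kout = A.sum(axis=1)
        kin = A.sum(axis=0)
        return float(((A - np.outer(kout, kin) / m) * same).sum() / m)
    A = (adj | adj.T).astype(float)
    np.fill_diagonal(A, 0)
    two_m = A.sum()
    if two_m == 0:
        raise ValueError("modularity undefined for an edgeless network")
    k = A.sum(axis=1)
    return float(((A - np.outer(k, k) / two_m) * same).sum() / two_m)


def levenshtein(a: str, b: str) -> int:
    """Classic dynamic-programming Levenshtein edit distance."""
    if len(a) < len(b):
        a, b = b, a
    prev = np.arange(len(b) + 1)
    for i, ca in enumerate(a, start=1):
        cur = np.empty(len(b) + 1, dtype=np.int64)
        cur[0] = i
        sub = prev[:-1] + np.fromiter((ca != cb for cb in b), dtype=np.int64, count=len(b))
        np.minimum(sub, prev[1:] + 1, out=cur[1:])
        for j in range(1, len(b) + 1):  # insertion needs the running value
            if cur[j - 1] + 1 < cur[j]:
                cur[j] = cur[j - 1] + 1
        prev = cur
    return int(prev[-1])


def partition_edit_distance(netA, netB, Pa, Pb, matching: ModuleMatching | None = None) -> int:
    """Sum of Levenshtein distances between matched modules' internal
    edge patterns.

    For each matched module pair, the two internal adjacency submatrices
    are aligned on the union of the two vertex sets (vertices absent from
    one module contribute zero rows/columns there), vectorized row-major
    to binary strings, and compared by edit distance.
    """
    A = _adjacency(netA)
    B = _adjacency(netB)
    a, b = _labels(Pa), _labels(Pb)
    if matching is None:
        matching = match_modules(Pa, Pb)
    total = 0
    for la, lb in matching.mapping.items():
        va = np.flatnonzero(a == la)
        vb = np.flatnonzero(b == lb)
        union = np.union1d(va, vb)
        in_a = np.isin(union, va)
        in_b = np.isin(union, vb)
        subA = A[np.ix_(union, union)] * np.outer(in_a, in_a)
        subB = B[np.ix_(union, union)] * np.outer(in_b, in_b)
        sa = "".join(map(str, subA.ravel().astype(int)))
        sb = "".join(map(str, subB.ravel().astype(int)))
        total += levenshtein(sa, sb)
    return total
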
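"""Boolean implication analysis between gene pairs from tri-state calls.

For a gene pair (A, B) every sample with both calls in {low, high} falls into
one of four scatter-plot quadrants:

    a00 = A low  & B low      a01 = A low  & B high
    a10 = A high & B low      a11 = A high & B high

Under independence the expected occupancy of a quadrant is
n̂ = (A-marginal / total) · (B-marginal / total) · total.  A quadrant is sparse
when the BooleanNet statistic S = (n̂ − a)/√n̂ exceeds ``sthr`` and the error
rate p = ½·(a / A-marginal + a / B-marginal) is below ``pthr``.  Two sparse
diagonal quadrants give a symmetric relation (equivalent: a01 & a10 sparse;
opposite: a00 & a11 sparse); exactly one sparse quadrant gives one of the four
asymmetric implications:

    a00 sparse → A low ⇒ B high        a01 sparse → A low ⇒ B low
    a10 sparse → A high ⇒ B high       a11 sparse → A high ⇒ B low

Genes linked by equivalent relations form the clusters (connected components,
singletons pruned) that become the nodes of the Boolean network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .stepminer import HIGH, LOW, TriStateMatrix

log = logging.getLogger("macpolar")

RELATION_TYPES = ("equivalent", "opposite", "low_low", "low_high",
                  "high_high", "high_low", "none")

#: relation type of (B, A) given the type of (A, B)
SWAP_TYPE = {
    "equivalent": "equivalent",
    "opposite": "opposite",
    "low_low": "high_high",
    "high_high": "low_low",
    "low_high": "low_high",
    "high_low": "high_low",
    "none": "none",
}

QUADRANTS = ("00", "01", "10", "11")

#: sparse quadrant → asymmetric relation type
_ASYMMETRIC = {"00": "low_high", "01": "low_low", "10": "high_high", "11": "high_low"}

DEFAULT_STHR = 3.0
DEFAULT_PTHR = 0.1


@dataclass
class QuadrantCounts:
    """Sample counts per scatter-plot quadrant (intermediate/missing excluded)."""

    a00: int
    a01: int
    a10: int
    a11: int

    @property
    def total(self) -> int:
        return self.a00 + self.a01 + self.a10 + self.a11

    @property
    def n_a_low(self) -> int:
        return self.a00 + self.a01

    @property
    def n_a_high(self) -> int:
        return self.a10 + self.a11

    @property
    def n_b_low(self) -> int:
        return self.a00 + self.a10

    @property
    def n_b_high(self) -> int:
        return self.a01 + self.a11

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a00, self.a01, self.a10, self.a11)


@dataclass
class RelationStats:
    """Expected occupancy, sparsity statistic S and error rate p per quadrant."""

    counts: QuadrantCounts
    expected: dict[str, float]
    s: dict[str, float]
    p: dict[str, float]


@dataclass
class BooleanRelation:
    """Classified pairwise relation between two genes/rows."""

    gene_a: str
    gene_b: str
    type: str
    stats: RelationStats | None = None


@dataclass
class BooleanNetwork:
    """Equivalence clusters as nodes, majority-vote relations as edges."""

    clusters: list[list[str]]
    edges: list[dict]   # keys: cluster_a, cluster_b, type, support, n_pairs


# ---------------------------------------------------------------------------
# Pairwise statistics
# ---------------------------------------------------------------------------


def quadrant_counts(calls_a: Sequence[float], calls_b: Sequence[float]) -> QuadrantCounts:
    """Count samples per quadrant, disregarding intermediate and missing calls."""
    a = np.asarray(calls_a, dtype=float)
    b = np.asarray(calls_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"call vectors differ in length: {a.shape} vs {b.shape}")
    use = np.isin(a, (LOW, HIGH)) & np.isin(b, (LOW, HIGH))
    a, b = a[use], b[use]
    return QuadrantCounts(
        a00=int(np.sum((a == LOW) & (b == LOW))),
        a01=int(np.sum((a == LOW) & (b == HIGH))),
        a10=int(np.sum((a == HIGH) & (b == LOW))),
        a11=int(np.sum((a == HIGH) & (b == HIGH))),
    )


def _marginals(counts: QuadrantCounts, quadrant: str) -> tuple[int, int]:
    i, j = quadrant
    a_marg = counts.n_a_low if i == "0" else counts.n_a_high
    b_marg = counts.n_b_low if j == "0" else counts.n_b_high
    return a_marg, b_marg


def sparsity_stats(counts: QuadrantCounts) -> RelationStats:
    """BooleanNet statistics (expected n̂, S, p) for all four quadrants."""
    total = counts.total
    if total == 0:
        raise ValueError("sparsity_stats requires at least one sample in a quadrant")
    observed = dict(zip(QUADRANTS, counts.as_tuple()))
    expected: dict[str, float] = {}
    s: dict[str, float] = {}
    p: dict[str, float] = {}
    for q in QUADRANTS:
        a_marg, b_marg = _marginals(counts, q)
        n_hat = (a_marg / total) * (b_marg / total) * total
        expected[q] = n_hat
        obs = observed[q]
        s[q] = (n_hat - obs) / np.sqrt(n_hat) if n_hat > 0 else 0.0
        term_a = obs / a_marg if a_marg > 0 else 0.0
        term_b = obs / b_marg if b_marg > 0 else 0.0
        p[q] = 0.5 * (term_a + term_b)
    return RelationStats(counts=counts, expected=expected, s=s, p=p)


def classify_relation(stats: RelationStats, sthr: float = DEFAULT_STHR,
                      pthr: float = DEFAULT_PTHR) -> str:
    """Relation type from quadrant statistics.

    Symmetric types are checked first; an asymmetric type requires exactly
    one sparse quadrant; anything else is ``"none"``.
    """
    sparse = {q: (stats.s[q] > sthr and stats.p[q] < pthr) for q in QUADRANTS}
    if sparse["01"] and sparse["10"]:
        return "equivalent"
    if sparse["00"] and sparse["11"]:
        return "opposite"
    hits = [q for q in QUADRANTS if sparse[q]]
    if len(hits) == 1:
        return _ASYMMETRIC[hits[0]]
    return "none"


def relation_between(calls_a, calls_b, gene_a: str = "A", gene_b: str = "B",
                     sthr: float = DEFAULT_STHR, pthr: float = DEFAULT_PTHR
                     ) -> BooleanRelation:
    """Classify one gene pair from tri-state call vectors."""
    counts = quadrant_counts(calls_a, calls_b)
    if counts.total == 0:
        return BooleanRelation(gene_a, gene_b, "none", None)
    stats = sparsity_stats(counts)
    return BooleanRelation(gene_a, gene_b, classify_relation(stats, sthr, pthr), stats)


# ---------------------------------------------------------------------------
# All-pairs relations (vectorized)
# ---------------------------------------------------------------------------


def all_pairs_relations(tri: TriStateMatrix, sthr: float = DEFAULT_STHR,
                        pthr: float = DEFAULT_PTHR, include_none: bool = False,
                        with_stats: bool = False) -> list[BooleanRelation]:
    """Classify every unordered pair of non-excluded rows.

    Relations are reported once per pair, oriented (row i, row j) with i < j
    in matrix order; the (j, i) orientation follows from :data:`SWAP_TYPE`.
    Degenerate/excluded rows are skipped.
    """
    rows = tri.included
    if len(rows) < 2:
        raise ValueError("all_pairs_relations requires >= 2 non-degenerate rows")
    calls = tri.calls.loc[rows].to_numpy(dtype=float)
    low = (calls == LOW).astype(np.float64)
    high = (calls == HIGH).astype(np.float64)

    a00 = low @ low.T
    a01 = low @ high.T
    a10 = high @ low.T
    a11 = high @ high.T
    total = a00 + a01 + a10 + a11

    n_a_low, n_a_high = a00 + a01, a10 + a11
    n_b_low, n_b_high = a00 + a10, a01 + a11

    def sparse_mask(obs, a_marg, b_marg):
        with np.errstate(divide="ignore", invalid="ignore"):
            n_hat = np.where(total > 0, a_marg * b_marg / np.where(total > 0, total, 1), 0.0)
            s = np.where(n_hat > 0, (n_hat - obs) / np.sqrt(np.where(n_hat > 0, n_hat, 1)), 0.0)
            p = 0.5 * (np.where(a_marg > 0, obs / np.where(a_marg > 0, a_marg, 1), 0.0)
                       + np.where(b_marg > 0, obs / np.where(b_marg > 0, b_marg, 1), 0.0))
        return (s > sthr) & (p < pthr)

    sp00 = sparse_mask(a00, n_a_low, n_b_low)
    sp01 = sparse_mask(a01, n_a_low, n_b_high)
    sp10 = sparse_mask(a10, n_a_high, n_b_low)
    sp11 = sparse_mask(a11, n_a_high, n_b_high)

    n_sparse = sp00.astype(int) + sp01.astype(int) + sp10.astype(int) + sp11.astype(int)
    type_idx = np.full(sp00.shape, 6, dtype=np.int8)          # none
    one = n_sparse == 1
    type_idx[one & sp00] = 3                                   # low_high
    type_idx[one & sp01] = 2                                   # low_low
    type_idx[one & sp10] = 4                                   # high_high
    type_idx[one & sp11] = 5                                   # high_low
    type_idx[sp00 & sp11] = 1                                  # opposite
    type_idx[sp01 & sp10] = 0                                  # equivalent
    type_idx[total == 0] = 6

    relations: list[BooleanRelation] = []
    row_list = list(rows)
    iu, ju = np.triu_indices(len(row_list), k=1)
    for i, j in zip(iu, ju):
        t = RELATION_TYPES[type_idx[i, j]]
        if t == "none" and not include_none:
            continue
        stats = None
        if with_stats:
            counts = QuadrantCounts(int(a00[i, j]), int(a01[i, j]),
                                    int(a10[i, j]), int(a11[i, j]))
            stats = sparsity_stats(counts) if counts.total > 0 else None
        relations.append(BooleanRelation(row_list[i], row_list[j], t, stats))
    return relations


# ---------------------------------------------------------------------------
# Clustering and network assembly
# ---------------------------------------------------------------------------


def cluster_equivalent(relations: Iterable[BooleanRelation]) -> list[list[str]]:
    """Connected components over equivalent edges; singleton clusters pruned.

    Clusters are returned sorted (genes within a cluster, clusters by their
    first gene) for reproducibility.
    """
    graph = nx.Graph()
    for rel in relations:
        if rel.type == "equivalent":
            graph.add_edge(rel.gene_a, rel.gene_b)
    clusters = [sorted(component) for component in nx.connected_components(graph)
                if len(component) >= 2]
    return sorted(clusters, key=lambda c: c[0])


def build_network(clusters: list[list[str]],
                  relations: Iterable[BooleanRelation]) -> BooleanNetwork:
    """Induce cluster-level edges by majority vote over inter-cluster gene pairs.

    An edge of a given type exists when more than half of the gene pairs
    between two clusters carry that type (pairs without a computed relation
    count as ``none`` in the denominator); the support fraction is recorded.
    """
    membership: dict[str, int] = {}
    for ci, cluster in enumerate(clusters):
        for gene in cluster:
            membership[gene] = ci
    pair_types: dict[tuple[int, int], dict[str, int]] = {}
    for rel in relations:
        ca, cb = membership.get(rel.gene_a), membership.get(rel.gene_b)
        if ca is None or cb is None or ca == cb:
            continue
        rel_type = rel.type
        if ca > cb:
            ca, cb = cb, ca
            rel_type = SWAP_TYPE[rel_type]
        counter = pair_types.setdefault((ca, cb), {})
        counter[rel_type] = counter.get(rel_type, 0) + 1
    edges = []
    for (ca, cb), counter in sorted(pair_types.items()):
        n_pairs = len(clusters[ca]) * len(clusters[cb])
        candidates = {t: c for t, c in counter.items() if t != "none"}
        if not candidates:
            continue
        best_type = max(sorted(candidates), key=lambda t: candidates[t])
        support = candidates[best_type] / n_pairs
        if support > 0.5:
            edges.append({"cluster_a": ca, "cluster_b": cb, "type": best_type,
                          "support": support, "n_pairs": n_pairs})
    return BooleanNetwork(clusters=clusters, edges=edges)


# ---------------------------------------------------------------------------
# TSV output
# ---------------------------------------------------------------------------


def write_relations(relations: Iterable[BooleanRelation], path: str | Path) -> None:
    rows = []
    for rel in relations:
        row = {"gene_a": rel.gene_a, "gene_b": rel.gene_b, "type": rel.type}
        if rel.stats is not None:
            for q, val in zip(QUADRANTS, rel.stats.counts.as_tuple()):
                row[f"a{q}"] = val
            for q in QUADRANTS:
                row[f"S{q}"] = rel.stats.s[q]
                row[f"p{q}"] = rel.stats.p[q]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_network(network: BooleanNetwork, edges_path: str | Path,
                  clusters_path: str | Path) -> None:
    pd.DataFrame(network.edges).to_csv(edges_path, sep="\t", index=False)
    member_rows = [{"cluster": ci, "gene": gene}
                   for ci, cluster in enumerate(network.clusters) for gene in cluster]
    pd.DataFrame(member_rows).to_csv(clusters_path, sep="\t", index=False)
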
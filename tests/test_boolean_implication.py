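import itertools

import numpy as np
import pandas as pd
import pytest

from macpolar import (binarize, classify_relation, cluster_equivalent,
                      quadrant_counts, relation_between, sparsity_stats)
from macpolar.boolean_implication import (QuadrantCounts, SWAP_TYPE,
                                          all_pairs_relations, build_network,
                                          BooleanRelation)
from macpolar.stepminer import HIGH, INTERMEDIATE, LOW, TriStateMatrix

from conftest import matrix_from_rows

L, I, H = LOW, INTERMEDIATE, HIGH


def tri_from_calls(rows: dict) -> TriStateMatrix:
    calls = pd.DataFrame(rows).T
    calls.columns = [f"s{i}" for i in range(calls.shape[1])]
    fits = pd.DataFrame(index=calls.index)
    return TriStateMatrix(calls=calls.astype(float), margin=0.5, fits=fits)


class TestQuadrantCounts:
    def test_one_sample_per_quadrant(self):
        counts = quadrant_counts([L, L, H, H], [L, H, L, H])
        assert counts.as_tuple() == (1, 1, 1, 1)

    def test_intermediate_and_missing_excluded(self):
        counts = quadrant_counts([L, I, H, np.nan, L], [L, L, I, H, H])
        assert counts.as_tuple() == (1, 0, 0, 0) or counts.total == 2
        assert counts.a00 == 1 and counts.a01 == 1 and counts.total == 2

    def test_all_low(self):
        counts = quadrant_counts([L, L], [L, L])
        assert counts.as_tuple() == (2, 0, 0, 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            quadrant_counts([L, L], [L])


class TestSparsityStats:
    def test_worked_case_low_implies_high(self):
        stats = sparsity_stats(QuadrantCounts(0, 30, 30, 30))
        assert stats.expected["00"] == pytest.approx(10.0)
        assert stats.s["00"] == pytest.approx(10 / np.sqrt(10))
        assert stats.p["00"] == 0.0
        assert classify_relation(stats) == "low_high"

    def test_exact_independence_gives_zero_s(self):
        stats = sparsity_stats(QuadrantCounts(25, 25, 25, 25))
        assert all(stats.s[q] == 0.0 for q in stats.s)
        assert classify_relation(stats) == "none"

    def test_zero_count_zero_p_regardless_of_marginals(self):
        stats = sparsity_stats(QuadrantCounts(0, 7, 13, 40))
        assert stats.p["00"] == 0.0

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            sparsity_stats(QuadrantCounts(0, 0, 0, 0))


def independent_rule_oracle(a00, a01, a10, a11, sthr=3.0, pthr=0.1):
    """Plain re-statement of the sparsity inequality rules, kept separate
    from the library implementation."""
    total = a00 + a01 + a10 + a11
    n_a = {"0": a00 + a01, "1": a10 + a11}
    n_b = {"0": a00 + a10, "1": a01 + a11}
    obs = {"00": a00, "01": a01, "10": a10, "11": a11}
    sparse = {}
    for q in obs:
        expected = n_a[q[0]] * n_b[q[1]] / total
        s = (expected - obs[q]) / np.sqrt(expected) if expected > 0 else 0.0
        pa = obs[q] / n_a[q[0]] if n_a[q[0]] else 0.0
        pb = obs[q] / n_b[q[1]] if n_b[q[1]] else 0.0
        sparse[q] = s > sthr and 0.5 * (pa + pb) < pthr
    if sparse["01"] and sparse["10"]:
        return "equivalent"
    if sparse["00"] and sparse["11"]:
        return "opposite"
    hits = [q for q, flag in sparse.items() if flag]
    if len(hits) == 1:
        return {"00": "low_high", "01": "low_low",
                "10": "high_high", "11": "high_low"}[hits[0]]
    return "none"


class TestClassifyRelation:
    def test_agrees_with_independent_oracle_on_grid(self):
        for combo in itertools.product((0, 5, 10, 30), repeat=4):
            if sum(combo) == 0:
                continue
            stats = sparsity_stats(QuadrantCounts(*combo))
            assert classify_relation(stats) == independent_rule_oracle(*combo), combo

    def test_diagonal_concentration_is_equivalent(self):
        stats = sparsity_stats(QuadrantCounts(30, 0, 0, 30))
        assert stats.s["01"] == stats.s["10"] == pytest.approx(15 / np.sqrt(15))
        assert classify_relation(stats) == "equivalent"

    def test_anti_diagonal_concentration_is_opposite(self):
        assert classify_relation(sparsity_stats(QuadrantCounts(0, 30, 30, 0))) == "opposite"

    def test_thresholds_are_strict(self):
        # S exactly at sThr must not qualify
        stats = sparsity_stats(QuadrantCounts(0, 30, 30, 30))
        assert classify_relation(stats, sthr=stats.s["00"]) == "none"


class TestSwapSymmetry:
    def test_types_map_under_gene_swap(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            a = rng.choice([L, I, H], size=60, p=[0.45, 0.1, 0.45])
            b = np.where(rng.random(60) < 0.85, a, rng.choice([L, H], size=60))
            if rng.random() < 0.5:
                b = 2.0 - b  # anti-correlate
            fwd = relation_between(a, b).type
            rev = relation_between(b, a).type
            assert rev == SWAP_TYPE[fwd]

    def test_asymmetric_example_maps_to_counterpart(self):
        # A low ⇒ B low has sparse a01; swapping genes gives B high ⇒ A high
        a = np.array([L] * 30 + [H] * 60)
        b = np.array([L] * 30 + [L] * 30 + [H] * 30)
        assert relation_between(a, b).type == "low_low"
        assert relation_between(b, a).type == "high_high"


class TestAllPairs:
    def test_identical_rows_equivalent(self):
        m = matrix_from_rows({
            "g1": [1] * 20 + [5] * 20,
            "g2": [1] * 20 + [5] * 20,
        })
        rels = all_pairs_relations(binarize(m))
        assert len(rels) == 1 and rels[0].type == "equivalent"

    def test_independent_random_rows_mostly_none(self):
        rng = np.random.default_rng(7)
        rows = {f"g{i}": np.where(rng.random(100) < 0.5, 1.0, 5.0)
                for i in range(12)}
        rels = all_pairs_relations(binarize(matrix_from_rows(rows)),
                                   include_none=True)
        frac = np.mean([r.type != "none" for r in rels])
        assert frac < 0.05

    def test_false_positive_rate_under_independence(self):
        # Bernoulli(0.5) calls, n=200: < 1% non-none relations across seeds
        n_rel = n_pairs = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            calls = rng.choice([L, H], size=(12, 200))
            tri = tri_from_calls({f"g{i}": calls[i] for i in range(12)})
            rels = all_pairs_relations(tri, include_none=True)
            n_pairs += len(rels)
            n_rel += sum(r.type != "none" for r in rels)
        assert n_rel / n_pairs < 0.01

    def test_matches_pairwise_classification(self):
        rng = np.random.default_rng(9)
        calls = {f"g{i}": rng.choice([L, I, H], size=80, p=[0.4, 0.2, 0.4])
                 for i in range(6)}
        tri = tri_from_calls(calls)
        bulk = {(r.gene_a, r.gene_b): r.type
                for r in all_pairs_relations(tri, include_none=True)}
        for (ga, gb), bulk_type in bulk.items():
            assert relation_between(calls[ga], calls[gb]).type == bulk_type

    def test_requires_two_usable_rows(self):
        m = matrix_from_rows({"flat": [2, 2, 2, 2], "g": [1, 1, 5, 5]})
        with pytest.raises(ValueError, match=">= 2"):
            all_pairs_relations(binarize(m))


class TestClustering:
    def test_transitive_equivalence_one_cluster(self):
        rels = [BooleanRelation("A", "B", "equivalent"),
                BooleanRelation("B", "C", "equivalent")]
        assert cluster_equivalent(rels) == [["A", "B", "C"]]

    def test_no_equivalent_edges_no_clusters(self):
        rels = [BooleanRelation("A", "B", "opposite")]
        assert cluster_equivalent(rels) == []

    def test_disjoint_pairs_two_clusters(self):
        rels = [BooleanRelation("A", "B", "equivalent"),
                BooleanRelation("C", "D", "equivalent")]
        assert cluster_equivalent(rels) == [["A", "B"], ["C", "D"]]


class TestBuildNetwork:
    def test_unanimous_opposite_edge_support_one(self):
        clusters = [["A", "B"], ["C", "D"]]
        rels = [BooleanRelation(a, b, "opposite")
                for a in "AB" for b in "CD"]
        net = build_network(clusters, rels)
        assert len(net.edges) == 1
        edge = net.edges[0]
        assert edge["type"] == "opposite" and edge["support"] == 1.0

    def test_no_cross_relations_no_edge(self):
        net = build_network([["A", "B"], ["C", "D"]], [])
        assert net.edges == []

    def test_majority_vote_with_recorded_support(self):
        clusters = [list("ABCDE"), list("VWXY")]
        pairs = [(a, b) for a in "ABCDE" for b in "VWXY"]
        rels = [BooleanRelation(a, b, "opposite") for a, b in pairs[:12]]
        rels += [BooleanRelation(a, b, "low_low") for a, b in pairs[12:]]
        net = build_network(clusters, rels)
        assert len(net.edges) == 1
        assert net.edges[0]["type"] == "opposite"
        assert net.edges[0]["support"] == pytest.approx(0.6)

    def test_minority_types_produce_no_edge(self):
        clusters = [list("AB"), list("CD")]
        rels = [BooleanRelation("A", "C", "opposite"),
                BooleanRelation("A", "D", "low_low"),
                BooleanRelation("B", "C", "high_low"),
                BooleanRelation("B", "D", "none")]
        assert build_network(clusters, rels).edges == []
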
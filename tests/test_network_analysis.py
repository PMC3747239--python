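"""Network construction, partitioning, module scoring, GO enrichment."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from postgwas.genome_annotation import SnpGeneAnnotation
from postgwas.network_analysis import (
    EmptyNetworkError,
    GoAnnotation,
    build_network,
    edge_weight,
    go_overrepresentation,
    merge_datasets,
    module_score,
    multi_annotation_report,
    partition_network,
    summarize_modules,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def set_partitions(items):
    """All set partitions of a list (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    head, rest = items[0], items[1:]
    for sub in set_partitions(rest):
        for i in range(len(sub)):
            yield sub[:i] + [[head] + sub[i]] + sub[i + 1:]
        yield [[head]] + sub


def exhaustive_best_modularity(g):
    """Max weighted modularity over every partition of the vertex set."""
    best = -np.inf
    for part in set_partitions(list(g.nodes)):
        q = nx.community.modularity(g, [set(p) for p in part], weight="weight")
        best = max(best, q)
    return best


def exact_ranksum_p(xs, ys):
    """Enumerate all rank assignments: P(U_x <= observed) for 'less'."""
    combined = sorted(xs + ys)

    def u_of(sample, other):
        # pairs where the sample value exceeds the other ('less' rejects small U)
        u = 0.0
        for x in sample:
            for y in other:
                u += 1.0 if x > y else (0.5 if x == y else 0.0)
        return u
    obs = u_of(xs, ys)
    n = len(xs)
    count = 0
    total = 0
    for subset in itertools.combinations(range(len(combined)), n):
        sub = [combined[i] for i in subset]
        rest = [combined[i] for i in range(len(combined)) if i not in subset]
        total += 1
        if u_of(sub, rest) <= obs + 1e-12:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# edge weights
# ---------------------------------------------------------------------------

class TestEdgeWeight:
    def test_default_is_product_of_neglog10(self):
        assert edge_weight(0.01, 0.001) == pytest.approx(6.0)

    def test_p_one_gives_zero_weight(self):
        assert edge_weight(1.0, 1e-10) == 0.0

    def test_shared_interactor_contributes_factor_one(self):
        assert edge_weight(None, 0.001) == pytest.approx(3.0)

    def test_custom_function_penalizes_hubs(self):
        fn = lambda p, deg, fixed: (-np.log10(p) if p else 1.0) / max(deg, 1)
        got = edge_weight(0.01, 0.01, degree_a=4, degree_b=2, weight_fn=fn)
        assert got == pytest.approx((2 / 4) * (2 / 2))

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError):
            edge_weight(0.0, 0.5)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

class TestBuildNetwork:
    def test_loops_dropped_duplicates_merged_labels_union(self):
        edges = pd.DataFrame({
            "gene_a": ["A", "A", "A", "A"],
            "gene_b": ["B", "B", "B", "A"],
            "label": ["p1", "p1", "p2", "x"],
        })
        net = build_network(edges, {"A": 0.01, "B": 0.02})
        assert net.number_of_edges() == 1
        assert net["A"]["B"]["labels"] == {"p1", "p2"}

    def test_shared_interactor_needs_two_gwas_links(self):
        edges = pd.DataFrame({"gene_a": ["A", "B", "X"], "gene_b": ["X", "X", "Y"]})
        net = build_network(edges, {"A": 0.01, "B": 0.02}, keep_shared_interactors=True)
        assert set(net.nodes) == {"A", "B", "X"}
        assert net.nodes["X"]["is_shared_interactor"]

    def test_plain_truncation_drops_non_gwas(self):
        edges = pd.DataFrame({"gene_a": ["A", "B", "X"], "gene_b": ["X", "X", "Y"]})
        net = build_network(edges, {"A": 0.01, "B": 0.02}, keep_shared_interactors=False)
        assert set(net.nodes) == {"A", "B"}
        assert net.number_of_edges() == 0

    def test_empty_truncation_raises_with_counts(self):
        edges = pd.DataFrame({"gene_a": ["X"], "gene_b": ["Y"]})
        with pytest.raises(EmptyNetworkError):
            build_network(edges, {"A": 0.01})

    def test_superhub_removed_unless_gwas_annotated(self):
        rows = [("HUB", f"v{i}") for i in range(20)] + [("A", "B"), ("A", "HUB"), ("B", "HUB")]
        edges = pd.DataFrame(rows, columns=["gene_a", "gene_b"])
        net = build_network(edges, {"A": 1e-4, "B": 1e-3},
                            keep_shared_interactors=True,
                            remove_superhubs=True, degree_quantile=0.9)
        assert "HUB" not in net.nodes
        # same input without removal keeps HUB as shared interactor
        net2 = build_network(edges, {"A": 1e-4, "B": 1e-3}, keep_shared_interactors=True)
        assert "HUB" in net2.nodes

    def test_edge_weights_set_from_p(self):
        edges = pd.DataFrame({"gene_a": ["A"], "gene_b": ["B"]})
        net = build_network(edges, {"A": 0.01, "B": 0.001})
        assert net["A"]["B"]["weight"] == pytest.approx(6.0)


# ---------------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------------

def two_triangles():
    g = nx.Graph()
    for a, b in [("A", "B"), ("B", "C"), ("A", "C"), ("D", "E"), ("E", "F"), ("D", "F")]:
        g.add_edge(a, b, weight=10.0)
    g.add_edge("C", "D", weight=0.1)
    return g


class TestPartition:
    def test_two_triangles_split_at_bridge(self):
        part = partition_network(two_triangles(), seed=0)
        assert sorted(map(sorted, part)) == [["A", "B", "C"], ["D", "E", "F"]]

    def test_single_clique_is_one_module(self):
        g = nx.complete_graph(5)
        nx.set_edge_attributes(g, 1.0, "weight")
        part = partition_network(g, seed=0)
        assert len(part) == 1

    def test_deterministic_for_fixed_seed(self):
        g = nx.gnm_random_graph(12, 30, seed=5)
        for a, b in g.edges:
            g[a][b]["weight"] = (a + b) % 5 + 0.5
        assert partition_network(g, seed=3) == partition_network(g, seed=3)

    def test_isolated_vertices_become_singletons(self):
        g = two_triangles()
        g.add_node("LONE")
        part = partition_network(g, seed=0)
        assert {"LONE"} in part

    def test_partition_is_exhaustive_and_disjoint(self):
        g = nx.gnm_random_graph(15, 40, seed=2)
        nx.set_edge_attributes(g, 1.0, "weight")
        part = partition_network(g, seed=0)
        all_vs = [v for p in part for v in p]
        assert len(all_vs) == len(set(all_vs)) == g.number_of_nodes()

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_exhaustive_modularity_on_small_graphs(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(4, 9))
        g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(0, 10**6)))
        if g.number_of_edges() == 0:
            g.add_edge(0, 1)
        for a, b in g.edges:
            g[a][b]["weight"] = float(rng.uniform(0.1, 5.0))
        part = partition_network(g, seed=1)
        got = nx.community.modularity(g, part, weight="weight")
        assert got == pytest.approx(exhaustive_best_modularity(g), abs=1e-9)


# ---------------------------------------------------------------------------
# module score
# ---------------------------------------------------------------------------

class TestModuleScore:
    def test_strong_module_on_five_gene_network(self):
        assert module_score([0.001, 0.002], [0.001, 0.002, 0.5, 0.6, 0.7]) \
            == pytest.approx(1 / math.comb(5, 2))

    def test_weak_module_scores_high(self):
        p = module_score([0.6, 0.7], [0.001, 0.002, 0.003, 0.6, 0.7])
        assert p >= 0.9

    def test_module_equals_network_returns_one(self):
        assert module_score([0.1, 0.2], [0.1, 0.2]) == 1.0

    def test_symmetric_null_never_significant(self):
        vals = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        for pick in itertools.combinations(vals, 3):
            p = module_score(list(pick), vals)
            if set(pick) == {0.1, 0.2, 0.3}:
                continue  # the one genuinely extreme draw
            assert p > 0.04

    @pytest.mark.parametrize("n,m", [(1, 3), (2, 3), (3, 3), (2, 5), (4, 4),
                                     (5, 6), (7, 7), (3, 7)])
    def test_exact_enumeration_agreement(self, n, m):
        rng = np.random.default_rng(n * 31 + m)
        xs = sorted(set(rng.uniform(0, 1, n * 2)))[:n]
        ys = sorted(set(rng.uniform(0, 1, m * 2)))[:m]
        if len(xs) < n or len(ys) < m or set(xs) & set(ys):
            pytest.skip("degenerate draw")
        assert module_score(xs, xs + ys) == pytest.approx(exact_ranksum_p(xs, ys))


# ---------------------------------------------------------------------------
# GO over-representation
# ---------------------------------------------------------------------------

def toy_go():
    """Root R, parent P, child C; child genes are a subset of P's."""
    genes_c = [f"g{i}" for i in range(4)]
    genes_p_extra = ["g4", "g5"]
    others = [f"g{i}" for i in range(6, 10)]
    gene_to_terms = {g: {"C"} for g in genes_c}
    for g in genes_p_extra:
        gene_to_terms[g] = {"P"}
    for g in others:
        gene_to_terms[g] = {"R"}
    return GoAnnotation([("C", "P"), ("P", "R")], gene_to_terms)


class TestGoOverrepresentation:
    def test_hypergeometric_example(self):
        # universe 10, term 4, module 5, overlap 4 -> 6/252
        go = GoAnnotation([], {f"g{i}": {"T"} if i < 4 else {"U"} for i in range(10)})
        res = go_overrepresentation({f"g{i}" for i in [0, 1, 2, 3, 9]}, go,
                                    elim_threshold=0)
        p = res.set_index("term").loc["T", "p"]
        assert p == pytest.approx(6 / 252)

    def test_zero_overlap_gives_p_one(self):
        go = GoAnnotation([], {f"g{i}": {"T"} if i < 4 else {"U"} for i in range(10)})
        res = go_overrepresentation({"g9"}, go, elim_threshold=0)
        assert res.set_index("term").loc["T", "p"] == 1.0

    def test_elim_increases_parent_p(self):
        go = toy_go()
        module = {"g0", "g1", "g2", "g3"}  # exactly the child's genes
        plain = go_overrepresentation(module, go, elim_threshold=0).set_index("term")
        elim = go_overrepresentation(module, go, elim_threshold=0.05).set_index("term")
        assert elim.loc["C", "p"] == plain.loc["C", "p"]
        assert elim.loc["P", "p"] > plain.loc["P", "p"]

    def test_elim_threshold_zero_equals_plain_test(self):
        go = toy_go()
        module = {"g0", "g1", "g4"}
        res = go_overrepresentation(module, go, elim_threshold=0)
        from scipy.stats import hypergeom
        n_univ = len(go.universe)
        for row in res.itertuples(index=False):
            expect = hypergeom.sf(row.x - 1, n_univ, row.K, len(module)) if row.x else 1.0
            assert row.p == pytest.approx(expect)

    def test_results_ranked_ascending(self):
        go = toy_go()
        res = go_overrepresentation({"g0", "g1", "g2"}, go)
        assert list(res["p"]) == sorted(res["p"])

    def test_unannotated_terms_skipped(self):
        go = GoAnnotation([("A", "B")], {"g1": {"A"}})
        res = go_overrepresentation({"g1"}, go)
        assert set(res["term"]) == {"A", "B"}  # B inherits g1; no K=0 rows


# ---------------------------------------------------------------------------
# summaries, merging, multi-annotation
# ---------------------------------------------------------------------------

class TestSummaries:
    def _net(self):
        edges = pd.DataFrame({
            "gene_a": ["g0", "g1", "g0", "g6", "g7", "g6", "g3"],
            "gene_b": ["g1", "g2", "g2", "g7", "g8", "g8", "g6"],
        })
        ps = {"g0": 1e-5, "g1": 2e-5, "g2": 1e-6, "g6": 0.5, "g7": 0.6,
              "g8": 0.7, "g3": 0.4}
        return build_network(edges, ps)

    def test_top_three_terms_listed(self):
        net = self._net()
        part = partition_network(net, seed=0)
        go = toy_go()
        modules = summarize_modules(net, part, go, top_k=3)
        tested_terms = len(go_overrepresentation(modules[0].vertices, go))
        assert len(modules[0].top_go_terms) == min(3, tested_terms)

    def test_module_with_strongest_ps_ranks_first(self):
        net = self._net()
        part = partition_network(net, seed=0)
        modules = summarize_modules(net, part)
        assert "g2" in modules[0].vertices  # the low-p triangle
        assert modules[0].score <= modules[-1].score

    def test_module_without_go_genes_scores_anyway(self):
        net = self._net()
        part = partition_network(net, seed=0)
        go = GoAnnotation([], {"zz": {"T"}})  # annotations disjoint from network
        modules = summarize_modules(net, part, go)
        assert all(m.top_go_terms == [] or m.top_go_terms for m in modules)
        assert all(0 < m.score <= 1 for m in modules)


class TestMergeDatasets:
    def test_min_p_and_overlap_flag(self):
        a = pd.DataFrame({"gene_id": ["G"], "p": [1e-4]})
        b = pd.DataFrame({"gene_id": ["G"], "p": [1e-6]})
        merged = merge_datasets([("a", a), ("b", b)])
        row = merged.set_index("gene_id").loc["G"]
        assert row["p"] == 1e-6 and row["overlap"]

    def test_disjoint_sets_concatenate(self):
        a = pd.DataFrame({"gene_id": ["A", "B"], "p": [0.1, 0.2]})
        b = pd.DataFrame({"gene_id": ["C"], "p": [0.3]})
        assert len(merge_datasets([("a", a), ("b", b)])) == 3

    def test_single_dataset_identity(self):
        a = pd.DataFrame({"gene_id": ["A", "B"], "p": [0.1, 0.2]})
        merged = merge_datasets([("a", a)])
        assert list(merged["gene_id"]) == ["A", "B"]
        assert not merged["overlap"].any()

    def test_within_dataset_duplicates_keep_smallest(self):
        a = pd.DataFrame({"gene_id": ["A", "A"], "p": [0.5, 0.1]})
        merged = merge_datasets([("a", a)])
        assert merged.loc[0, "p"] == 0.1


class TestMultiAnnotation:
    def test_ld_block_snp_reported_with_all_genes(self):
        ann = [SnpGeneAnnotation("rs1", g, g, "ld", 0, 0.9) for g in ["A", "B", "C"]]
        ann += [SnpGeneAnnotation("rs2", "D", "D", "covering", 0)]
        report = multi_annotation_report(ann)
        assert len(report) == 1
        assert report.loc[0, "genes"] == "A,B,C"

    def test_single_annotated_snps_give_empty_report(self):
        ann = [SnpGeneAnnotation("rs1", "A", "A", "covering", 0)]
        assert multi_annotation_report(ann).empty
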
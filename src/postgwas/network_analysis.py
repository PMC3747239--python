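"""Association-weighted gene networks: construction, partitioning, scoring.

The idea is cumulative significance: loci that individually miss
genome-wide significance may jointly support a functional mechanism. A
gene graph (pathway, protein interaction, or any supplied edge list) is
weighted by the combined association strength of each edge's endpoints
(default: the product of their -log10 p), decomposed into modules by
weighted-modularity optimization so that high-weight edges concentrate
within modules, and each module is scored by a one-sided rank-sum test of
its member p-values against the rest of the network. Module function is
characterized by GO over-representation with elim-style decorrelation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .genome_annotation import SnpGeneAnnotation

logger = logging.getLogger("postgwas")

P_FLOOR = 1e-300  # p-values of 0 are floored here before taking logs
DEFAULT_ELIM_THRESHOLD = 0.01


class EmptyNetworkError(ValueError):
    """The network lost all vertices during truncation."""


# ---------------------------------------------------------------------------
# vertex table merging (multi-dataset support)
# ---------------------------------------------------------------------------

def merge_datasets(gwas_list: Sequence[tuple[str, pd.DataFrame]]) -> pd.DataFrame:
    """Merge per-dataset gene p-value tables into one vertex table.

    Each input is ``(dataset_label, frame)`` with columns ``gene_id`` and
    ``p``. The output has one row per gene with the minimum p across
    datasets (used for partitioning and scoring), the set of dataset
    labels, and an overlap flag for genes present in two or more datasets.
    Duplicate genes within one dataset keep the smallest p with a warning.
    """
    if not gwas_list:
        raise ValueError("need at least one dataset")
    per_gene: dict[str, dict] = {}
    for label, frame in gwas_list:
        dup = frame["gene_id"].duplicated()
        if dup.any():
            logger.warning("dataset %s: %d duplicate genes, keeping smallest p",
                           label, int(dup.sum()))
        best = frame.groupby("gene_id")["p"].min()
        for gene_id, p in best.items():
            entry = per_gene.setdefault(
                gene_id, {"gene_id": gene_id, "p": float(p), "datasets": set(),
                          "p_by_dataset": {}},
            )
            entry["p"] = min(entry["p"], float(p))
            entry["datasets"].add(label)
            entry["p_by_dataset"][label] = float(p)
    rows = []
    for gene_id in sorted(per_gene):
        e = per_gene[gene_id]
        rows.append(
            {
                "gene_id": gene_id, "p": e["p"],
                "datasets": frozenset(e["datasets"]),
                "overlap": len(e["datasets"]) >= 2,
                "p_by_dataset": e["p_by_dataset"],
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "p", "datasets", "overlap", "p_by_dataset"])


# ---------------------------------------------------------------------------
# edge weights
# ---------------------------------------------------------------------------

def _neglog10(p: float | None) -> float:
    if p is None:
        return 1.0  # shared interactors carry no association evidence
    if p <= 0:
        raise ValueError("p must be > 0; floor zero p-values before weighting")
    return -np.log10(max(p, P_FLOOR))


def edge_weight(
    p_a: float | None,
    p_b: float | None,
    degree_a: int = 0,
    degree_b: int = 0,
    fixed: float | None = None,
    weight_fn: Callable[[float | None, int, float | None], float] | None = None,
) -> float:
    """Combined association strength of an edge's endpoints.

    Default: the product of the endpoints' -log10 p. A vertex without a p
    (a shared interactor) contributes factor 1. A user function receives
    ``(p, degree, fixed)`` per endpoint and its two results are multiplied,
    allowing e.g. hub penalization by vertex degree.
    """
    if weight_fn is not None:
        return float(weight_fn(p_a, degree_a, fixed) * weight_fn(p_b, degree_b, fixed))
    return float(_neglog10(p_a) * _neglog10(p_b))


def degree_corrected_weight_fn(p: float | None, degree: int, fixed: float | None) -> float:
    """Endpoint factor -log10(p) / log(1 + degree): penalizes hub vertices."""
    base = _neglog10(p)
    return base / np.log(1.0 + degree) if degree > 0 else base


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def build_network(
    edge_table: pd.DataFrame,
    gwas_genes: pd.DataFrame | Mapping[str, float],
    keep_shared_interactors: bool = False,
    remove_superhubs: bool = False,
    degree_quantile: float = 0.99,
    weight_fn: Callable | None = None,
    multi_annotated: Iterable[str] = (),
) -> nx.Graph:
    """Build the association-weighted gene graph from an edge list.

    Processing order: loop edges dropped; duplicate edges merged (labels
    collapsed to their union, identical labels eliminated); optionally
    non-GWAS superhubs — vertices whose degree exceeds the
    ``degree_quantile`` quantile of the degree distribution — removed;
    the graph truncated to GWAS genes, optionally preserving shared
    interactors (non-GWAS genes connected to at least two GWAS genes).
    Edge weights are then computed from the endpoint p-values.

    ``gwas_genes`` is a mapping gene -> p or a frame from
    :func:`merge_datasets`.
    """
    if isinstance(gwas_genes, pd.DataFrame):
        vertex_table = gwas_genes
    else:
        vertex_table = merge_datasets([("gwas", pd.DataFrame(
            {"gene_id": list(gwas_genes), "p": [gwas_genes[g] for g in gwas_genes]}
        ))])
    p_of = dict(zip(vertex_table["gene_id"], vertex_table["p"]))

    raw = nx.Graph()
    n_loops = n_dups = 0
    for row in edge_table.itertuples(index=False):
        a, b = str(row.gene_a), str(row.gene_b)
        if a == b:
            n_loops += 1
            continue
        label = getattr(row, "label", None)
        fixed = getattr(row, "weight", None)
        fixed = float(fixed) if fixed is not None and not pd.isna(fixed) else None
        if raw.has_edge(a, b):
            n_dups += 1
            if label is not None and not pd.isna(label):
                raw[a][b]["labels"].add(str(label))
            if fixed is not None:
                prev = raw[a][b]["fixed"]
                raw[a][b]["fixed"] = fixed if prev is None else (prev + fixed) / 2.0
        else:
            labels = set()
            if label is not None and not pd.isna(label):
                labels.add(str(label))
            raw.add_edge(a, b, labels=labels, fixed=fixed)
    if n_loops or n_dups:
        logger.info("build_network: removed %d loops, merged %d duplicate edges",
                    n_loops, n_dups)

    gwas_set = set(p_of)
    if remove_superhubs:
        degrees = np.array([d for _, d in raw.degree()])
        if len(degrees):
            cutoff = float(np.quantile(degrees, degree_quantile))
            hubs = [v for v, d in raw.degree() if d > cutoff and v not in gwas_set]
            raw.remove_nodes_from(hubs)
            if hubs:
                logger.info("build_network: removed %d superhubs (degree > %.1f)",
                            len(hubs), cutoff)

    keep = {v for v in raw.nodes if v in gwas_set}
    shared: set[str] = set()
    if keep_shared_interactors:
        for v in raw.nodes:
            if v in gwas_set:
                continue
            gwas_neighbors = sum(1 for u in raw.neighbors(v) if u in gwas_set)
            if gwas_neighbors >= 2:
                shared.add(v)
    net = raw.subgraph(keep | shared).copy()
    # drop edges between two shared interactors? they stay: both endpoints kept
    if net.number_of_nodes() == 0:
        raise EmptyNetworkError(
            f"empty network after truncation: {raw.number_of_nodes()} interaction "
            f"vertices, {len(gwas_set)} GWAS genes, 0 in common"
        )

    overlap_of = dict(zip(vertex_table["gene_id"], vertex_table.get("overlap", False)))
    datasets_of = dict(zip(vertex_table["gene_id"],
                           vertex_table.get("datasets", [frozenset()] * len(vertex_table))))
    multi = set(multi_annotated)
    for v in net.nodes:
        is_shared = v not in gwas_set
        net.nodes[v]["p"] = p_of.get(v)
        net.nodes[v]["is_shared_interactor"] = is_shared
        net.nodes[v]["multi_annotated"] = v in multi
        net.nodes[v]["overlap"] = bool(overlap_of.get(v, False))
        net.nodes[v]["datasets"] = datasets_of.get(v, frozenset())
    for a, b, data in net.edges(data=True):
        data["weight"] = edge_weight(
            net.nodes[a]["p"], net.nodes[b]["p"],
            net.degree(a), net.degree(b), data.get("fixed"), weight_fn,
        )
    return net


# ---------------------------------------------------------------------------
# partitioning (weighted modularity)
# ---------------------------------------------------------------------------

def _modularity(net: nx.Graph, communities: Sequence[set], resolution: float) -> float:
    return nx.community.modularity(net, communities, weight="weight", resolution=resolution)


def _refine(
    net: nx.Graph,
    assignment: dict,
    resolution: float,
    rng: np.random.Generator,
    max_sweeps: int = 30,
) -> dict:
    """Local single-vertex moves until no move improves weighted modularity."""
    nodes = sorted(net.nodes)
    two_m = 2.0 * sum(d.get("weight", 1.0) for _, _, d in net.edges(data=True))
    if two_m == 0:
        return assignment
    strength = {v: sum(d.get("weight", 1.0) for _, _, d in net.edges(v, data=True))
                for v in nodes}
    comm_strength: dict[int, float] = {}
    for v in nodes:
        comm_strength[assignment[v]] = comm_strength.get(assignment[v], 0.0) + strength[v]
    next_label = max(assignment.values(), default=-1) + 1

    for _ in range(max_sweeps):
        improved = False
        order = list(nodes)
        rng.shuffle(order)
        for v in order:
            cur = assignment[v]
            # weight from v into each neighboring community
            w_to: dict[int, float] = {}
            for u, d in net[v].items():
                w_to[assignment[u]] = w_to.get(assignment[u], 0.0) + d.get("weight", 1.0)
            candidates = set(w_to) | {next_label}
            candidates.discard(cur)
            base_in = w_to.get(cur, 0.0)
            best_gain, best_c = 0.0, cur
            for c in sorted(candidates):
                w_in = w_to.get(c, 0.0)
                # dQ of moving v: (w_in - w_cur)/m - res*s_v*(S_c - S_cur + s_v)/(2 m^2)
                gain = (w_in - base_in) / (two_m / 2.0) - resolution * strength[v] * (
                    comm_strength.get(c, 0.0) - comm_strength[cur] + strength[v]
                ) / (2.0 * (two_m / 2.0) ** 2)
                if gain > best_gain + 1e-12:
                    best_gain, best_c = gain, c
            if best_c != cur:
                comm_strength[cur] -= strength[v]
                comm_strength[best_c] = comm_strength.get(best_c, 0.0) + strength[v]
                assignment[v] = best_c
                if best_c == next_label:
                    next_label += 1
                improved = True
        if not improved:
            break
    return assignment


def _merge_refine(net: nx.Graph, assignment: dict, resolution: float) -> dict:
    """Merge community pairs while any merge improves weighted modularity.

    Complements single-vertex moves, which cannot join two communities when
    no individual vertex move is profitable.
    """
    m = sum(d.get("weight", 1.0) for _, _, d in net.edges(data=True))
    if m == 0:
        return assignment
    strength = {v: sum(d.get("weight", 1.0) for _, _, d in net.edges(v, data=True))
                for v in net.nodes}
    while True:
        comm_strength: dict[int, float] = {}
        for v, c in assignment.items():
            comm_strength[c] = comm_strength.get(c, 0.0) + strength[v]
        between: dict[tuple[int, int], float] = {}
        for u, v, d in net.edges(data=True):
            cu, cv = assignment[u], assignment[v]
            if cu != cv:
                key = (min(cu, cv), max(cu, cv))
                between[key] = between.get(key, 0.0) + d.get("weight", 1.0)
        best_gain, best_pair = 1e-12, None
        for (c1, c2), w12 in sorted(between.items()):
            gain = w12 / m - resolution * comm_strength[c1] * comm_strength[c2] / (2 * m * m)
            if gain > best_gain:
                best_gain, best_pair = gain, (c1, c2)
        if best_pair is None:
            return assignment
        c1, c2 = best_pair
        for v, c in assignment.items():
            if c == c2:
                assignment[v] = c1


def _communities_from_assignment(assignment: dict) -> list[set]:
    groups: dict[int, set] = {}
    for v, c in assignment.items():
        groups.setdefault(c, set()).add(v)
    return [groups[c] for c in sorted(groups, key=lambda c: sorted(groups[c])[0])]


def partition_network(
    net: nx.Graph,
    seed: int = 0,
    resolution: float = 1.0,
    n_restarts: int = 16,
) -> list[set]:
    """Decompose the network into modules by weighted-modularity maximization.

    Greedy agglomerative clustering seeds the search; seeded local
    refinement (single-vertex moves) and random restarts polish it. The
    best partition by weighted modularity wins; the result is
    deterministic for a fixed seed. Isolated vertices form their own
    singleton modules.
    """
    if net.number_of_edges() == 0:
        return [{v} for v in sorted(net.nodes)]
    isolated = [v for v in net.nodes if net.degree(v) == 0]
    core = net.subgraph([v for v in net.nodes if net.degree(v) > 0])
    rng = np.random.default_rng(seed)
    candidates: list[dict] = []

    greedy = nx.community.greedy_modularity_communities(
        core, weight="weight", resolution=resolution
    )
    assignment = {v: i for i, comm in enumerate(greedy) for v in comm}
    candidates.append(_refine(core, dict(assignment), resolution, rng))

    nodes = sorted(core.nodes)
    # tiny graphs have rugged modularity landscapes but cost nothing to
    # restart, so search them harder
    if len(nodes) <= 12:
        n_restarts = max(n_restarts, 48)
    for _ in range(n_restarts):
        k = int(rng.integers(1, max(2, min(len(nodes), 6) + 1)))
        random_assign = {v: int(rng.integers(0, k)) for v in nodes}
        candidates.append(_refine(core, random_assign, resolution, rng))
    # all-singletons start catches fine-grained optima
    candidates.append(_refine(core, {v: i for i, v in enumerate(nodes)}, resolution, rng))

    best, best_q = None, -np.inf
    for assign in candidates:
        assign = _refine(core, _merge_refine(core, assign, resolution), resolution, rng)
        comms = _communities_from_assignment(assign)
        q = _modularity(core, comms, resolution)
        if q > best_q + 1e-12:
            best, best_q = comms, q
    result = best + [{v} for v in sorted(isolated)]
    covered = set().union(*result) if result else set()
    assert covered == set(net.nodes), "partition must cover all vertices"
    return result


# ---------------------------------------------------------------------------
# module scoring
# ---------------------------------------------------------------------------

def module_score(module_ps: Sequence[float], network_ps: Sequence[float]) -> float:
    """One-sided rank-sum p-value: are module p-values stochastically smaller?

    The module's p-values are compared against the *rest* of the network
    (its complement) to avoid self-overlap bias. Exact enumeration is used
    when min(n, m) <= 10 and there are no ties; otherwise the normal
    approximation with tie and continuity correction. A module equal to
    the whole network scores 1.0.
    """
    module_ps = list(map(float, module_ps))
    if not module_ps:
        raise ValueError("module_ps must be non-empty")
    rest = list(map(float, network_ps))
    for p in module_ps:  # multiset subtraction: network ⊇ module
        try:
            rest.remove(p)
        except ValueError:
            raise ValueError("network_ps must contain all module p-values") from None
    if not rest:
        logger.warning("module spans the whole network; score undefined, returning 1.0")
        return 1.0
    combined = module_ps + rest
    ties = len(set(combined)) < len(combined)
    method = "exact" if (min(len(module_ps), len(rest)) <= 10 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(module_ps, rest, alternative="less", method=method,
                             use_continuity=True)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# GO over-representation with elim decorrelation
# ---------------------------------------------------------------------------

class GoAnnotation:
    """A GO-style DAG with gene annotations up-propagated to ancestors.

    ``is_a`` edges run child -> parent. The universe N is the set of genes
    with at least one annotation; K genes per term, n module genes in the
    universe and x their overlap feed the hypergeometric test.
    """

    def __init__(
        self,
        is_a_edges: Iterable[tuple[str, str]],
        gene_to_terms: Mapping[str, Iterable[str]],
        term_names: Mapping[str, str] | None = None,
    ) -> None:
        self.dag = nx.DiGraph()
        self.dag.add_edges_from(is_a_edges)  # child -> parent
        if not nx.is_directed_acyclic_graph(self.dag):
            raise ValueError("GO term graph must be acyclic")
        for terms in gene_to_terms.values():
            self.dag.add_nodes_from(terms)
        self.term_names = dict(term_names or {})
        self.term_to_genes: dict[str, set[str]] = {t: set() for t in self.dag.nodes}
        for gene, terms in gene_to_terms.items():
            for t in terms:
                self.term_to_genes[t].add(gene)
                for anc in nx.descendants(self.dag, t):  # ancestors along is_a
                    self.term_to_genes[anc].add(gene)
        self.universe: set[str] = set().union(*self.term_to_genes.values()) \
            if self.term_to_genes else set()

    def name(self, term: str) -> str:
        return self.term_names.get(term, term)


def _hypergeom_upper(x: int, big_n: int, big_k: int, n: int) -> float:
    """P(X >= x) for X ~ Hypergeom(N, K, n)."""
    if x <= 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, big_n, big_k, n))


def go_overrepresentation(
    module_genes: set[str],
    go: GoAnnotation,
    elim_threshold: float = DEFAULT_ELIM_THRESHOLD,
) -> pd.DataFrame:
    """Per-term upper-tail hypergeometric test with elim decorrelation.

    Terms are processed from the DAG leaves upward; whenever a term tests
    below ``elim_threshold``, its annotated genes are eliminated from all
    of its ancestors before those are tested, so only the best-fitting term
    of a branch is reported as significant. With ``elim_threshold = 0``
    this reduces to the plain hypergeometric test per term. P-values are
    not corrected for multiple testing. Terms with no annotated genes are
    skipped. Returned frame is ranked ascending by p.
    """
    big_n = len(go.universe)
    module_in = module_genes & go.universe
    n = len(module_in)
    eliminated: dict[str, set[str]] = {t: set() for t in go.dag.nodes}
    rows = []
    for term in nx.topological_sort(go.dag):  # child -> parent edges: leaves first
        genes = go.term_to_genes.get(term, set()) - eliminated[term]
        big_k = len(genes)
        if big_k == 0:
            continue
        x = len(genes & module_in)
        p = _hypergeom_upper(x, big_n, big_k, n)
        rows.append({"term": term, "name": go.name(term), "p": p,
                     "K": big_k, "x": x})
        if p < elim_threshold:
            for anc in nx.descendants(go.dag, term):
                eliminated[anc] |= genes
    frame = pd.DataFrame(rows, columns=["term", "name", "p", "K", "x"])
    return frame.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# module summaries and reports
# ---------------------------------------------------------------------------

@dataclass
class Module:
    vertices: set[str]
    score: float
    top_go_terms: list[tuple[str, str, float]] = field(default_factory=list)
    go_membership: dict[str, list[str]] = field(default_factory=dict)


def summarize_modules(
    net: nx.Graph,
    partition: Sequence[set],
    go: GoAnnotation | None = None,
    top_k: int = 3,
    elim_threshold: float = DEFAULT_ELIM_THRESHOLD,
) -> list[Module]:
    """Score and functionally annotate each module; rank ascending by score.

    The score is the rank-sum module score over vertices that carry
    association p-values (shared interactors are excluded from both
    samples). Each module lists its ``top_k`` over-represented GO terms
    after decorrelation and, per vertex, the listed terms it belongs to —
    the plot legend and coloring keys.
    """
    network_ps = [d["p"] for _, d in net.nodes(data=True)
                  if d.get("p") is not None and not d.get("is_shared_interactor")]
    modules: list[Module] = []
    for members in partition:
        mod_ps = [net.nodes[v]["p"] for v in members
                  if net.nodes[v].get("p") is not None
                  and not net.nodes[v].get("is_shared_interactor")]
        score = module_score(mod_ps, network_ps) if mod_ps else 1.0
        top: list[tuple[str, str, float]] = []
        membership: dict[str, list[str]] = {}
        if go is not None:
            enr = go_overrepresentation(set(members), go, elim_threshold)
            for row in enr.head(top_k).itertuples(index=False):
                top.append((row.term, row.name, float(row.p)))
            listed = [t for t, _n, _p in top]
            for v in sorted(members):
                membership[v] = [t for t in listed if v in go.term_to_genes.get(t, ())]
        modules.append(Module(set(members), score, top, membership))
    modules.sort(key=lambda m: (m.score, sorted(m.vertices)[0]))
    return modules


def modules_to_frame(modules: Sequence[Module], net: nx.Graph) -> pd.DataFrame:
    rows = []
    for rank, mod in enumerate(modules, 1):
        for v in sorted(mod.vertices):
            rows.append(
                {
                    "gene_id": v, "module": rank, "score": mod.score,
                    "p": net.nodes[v].get("p"),
                    "shared_interactor": bool(net.nodes[v].get("is_shared_interactor")),
                    "multi_annotated": bool(net.nodes[v].get("multi_annotated")),
                    "top_go_terms": ";".join(t for t, _n, _p in mod.top_go_terms),
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "module", "score", "p",
                                       "shared_interactor", "multi_annotated", "top_go_terms"])


def multi_annotation_report(annotations: Sequence[SnpGeneAnnotation]) -> pd.DataFrame:
    """Table of SNPs annotated to more than one gene, for manual lookup.

    Network vertices fed by such SNPs should be tagged (drawn with a
    cross); since they inherit the same SNP p-value they also get
    identical vertex sizes, another cue that one locus drives several
    vertices.
    """
    from collections import defaultdict

    genes_per_snp: dict[str, set[str]] = defaultdict(set)
    for a in annotations:
        if a.relation in ("covering", "ld") and a.gene_id:
            genes_per_snp[a.snp_id].add(a.gene_id)
    rows = [
        {"snp_id": s, "n_genes": len(gs), "genes": ",".join(sorted(gs))}
        for s, gs in sorted(genes_per_snp.items()) if len(gs) > 1
    ]
    return pd.DataFrame(rows, columns=["snp_id", "n_genes", "genes"])


def multi_annotated_genes(annotations: Sequence[SnpGeneAnnotation]) -> set[str]:
    """Genes that receive their signal from a multi-annotated SNP."""
    report = multi_annotation_report(annotations)
    out: set[str] = set()
    for genes in report["genes"]:
        out.update(genes.split(","))
    return out


def export_graphml(net: nx.Graph, path) -> None:
    """GraphML export with set-valued attributes flattened to strings."""
    g = net.copy()
    for _v, d in g.nodes(data=True):
        d["datasets"] = ",".join(sorted(d.get("datasets") or ()))
        if d.get("p") is None:
            d["p"] = float("nan")
    for _a, _b, d in g.edges(data=True):
        d["labels"] = ",".join(sorted(d.get("labels") or ()))
        if d.get("fixed") is None:
            d.pop("fixed", None)
    nx.write_graphml(g, path)
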
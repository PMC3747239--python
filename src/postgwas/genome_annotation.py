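"""SNP-to-gene annotation by proximity and by linkage disequilibrium.

Proximity annotation uses a sequentialization technique per chromosome:
gene bounds are sorted once and every query SNP is placed with vectorized
``numpy.searchsorted`` calls, so all SNPs are annotated at once rather
than in a per-SNP loop. Overlapping genes are handled explicitly — an
intragenic SNP reports *all* covering genes, because proximate genes can
share the association signal and dropping one risks losing the causative
candidate.

LD annotation considers every gene within a window (default 1 Mb) of the
query SNP, collects the intragenic SNPs of each candidate gene from the
genotype map, downscales them to at most 100 evenly distributed SNPs, and
annotates the gene with the maximum pairwise r-squared against the query.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .formats_io import GeneModel, GenotypeData
from .ld_core import interleave_indices, pairwise_r2

logger = logging.getLogger("postgwas")

LD_WINDOW_BP = 1_000_000       # candidate genes searched within this distance
MAX_SNPS_PER_GENE = 100        # intragenic SNPs downscaled to this many
DEFAULT_R2_THRESHOLD = 0.5     # min r2 for reporting an LD annotation


@dataclass(frozen=True)
class SnpGeneAnnotation:
    """One SNP-gene link.

    relation is one of ``covering`` (SNP inside the gene, distance 0),
    ``nearest_upstream`` / ``nearest_downstream`` (closest flanking gene
    with its distance in bp), or ``ld`` (gene tagged through linkage
    disequilibrium, with the max pairwise r2 as evidence).
    """

    snp_id: str
    gene_id: str
    symbol: str
    relation: str
    distance: int
    ld_r2: float | None = None
    multi_annotated: bool = False

    def __post_init__(self) -> None:
        if self.relation in ("covering", "ld") and self.distance != 0:
            raise ValueError(f"{self.relation} annotation must have distance 0")
        if self.relation == "ld" and self.ld_r2 is None:
            raise ValueError("ld annotation requires ld_r2")


def annotations_to_frame(annotations: Sequence[SnpGeneAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "snp_id": a.snp_id,
                "gene_id": a.gene_id,
                "symbol": a.symbol,
                "relation": a.relation,
                "distance": a.distance,
                "ld_r2": a.ld_r2,
                "multi_annotated": a.multi_annotated,
            }
            for a in annotations
        ],
        columns=["snp_id", "gene_id", "symbol", "relation", "distance", "ld_r2", "multi_annotated"],
    )


def flag_multi_annotated(annotations: list[SnpGeneAnnotation]) -> list[SnpGeneAnnotation]:
    """Set the multi-annotation flag on SNPs assigned to more than one gene.

    Only gene-assigning relations (covering, ld) count: every intergenic
    SNP trivially has two flanking genes and flagging those would be
    meaningless.
    """
    from collections import defaultdict

    genes_per_snp: dict[str, set[str]] = defaultdict(set)
    for a in annotations:
        if a.relation in ("covering", "ld") and a.gene_id:
            genes_per_snp[a.snp_id].add(a.gene_id)
    out = []
    for a in annotations:
        multi = len(genes_per_snp.get(a.snp_id, ())) > 1 and a.relation in ("covering", "ld")
        out.append(
            SnpGeneAnnotation(
                a.snp_id, a.gene_id, a.symbol, a.relation, a.distance, a.ld_r2, multi
            )
        )
    return out


def snp2gene_prox(
    snps: Iterable[tuple[str, str, int]],
    genes: Sequence[GeneModel],
) -> list[SnpGeneAnnotation]:
    """Annotate SNPs with covering and nearest flanking genes.

    For every SNP: all genes whose [start, end] interval covers its
    position (relation ``covering``, distance 0), plus the nearest gene
    ending before it (``nearest_upstream``) and the nearest gene starting
    after it (``nearest_downstream``), with distances in bp. Equidistant
    flanking genes in the same direction are all reported.

    Implemented as vectorized searchsorted interval queries per chromosome.
    """
    snp_list = list(snps)
    out: list[SnpGeneAnnotation] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(str(g.chrom), []).append(g)

    chrom_index: dict[str, dict[str, np.ndarray]] = {}
    for chrom, glist in by_chrom.items():
        glist.sort(key=lambda g: (g.start, g.end, g.gene_id))
        starts = np.array([g.start for g in glist])
        ends = np.array([g.end for g in glist])
        run_max_end = np.maximum.accumulate(ends)
        # flanking lookups use end-sorted order for upstream, start order for downstream
        end_order = np.argsort(ends, kind="mergesort")
        chrom_index[chrom] = {
            "genes": glist,
            "starts": starts,
            "ends": ends,
            "run_max_end": run_max_end,
            "end_order": end_order,
            "ends_sorted": ends[end_order],
        }

    # group SNPs per chromosome so each chromosome is one batch of queries
    snp_by_chrom: dict[str, list[tuple[str, int]]] = {}
    for snp_id, chrom, pos in snp_list:
        snp_by_chrom.setdefault(str(chrom), []).append((snp_id, int(pos)))

    for chrom, snp_items in snp_by_chrom.items():
        if chrom not in chrom_index:
            logger.info("snp2gene_prox: no genes on chromosome %s (%d SNPs)", chrom, len(snp_items))
            for snp_id, _pos in snp_items:
                out.append(SnpGeneAnnotation(snp_id, "", "", "none", 0))
            continue
        idx = chrom_index[chrom]
        glist, starts, ends = idx["genes"], idx["starts"], idx["ends"]
        run_max_end, end_order, ends_sorted = idx["run_max_end"], idx["end_order"], idx["ends_sorted"]
        positions = np.array([p for _s, p in snp_items])
        # all genes with start <= pos are candidates for covering
        hi = np.searchsorted(starts, positions, side="right")
        # nearest gene starting strictly after pos
        down_i = np.searchsorted(starts, positions, side="right")
        # nearest gene ending strictly before pos
        up_i = np.searchsorted(ends_sorted, positions, side="left")

        for (snp_id, pos), h, di, ui in zip(snp_items, hi, down_i, up_i):
            covering: list[GeneModel] = []
            j = int(h) - 1
            # scan back over start-sorted genes while some gene may still span pos
            while j >= 0 and run_max_end[j] >= pos:
                if ends[j] >= pos:
                    covering.append(glist[j])
                j -= 1
            for g in sorted(covering, key=lambda g: g.gene_id):
                out.append(SnpGeneAnnotation(snp_id, g.gene_id, g.symbol, "covering", 0))
            if int(ui) > 0:
                best_end = ends_sorted[int(ui) - 1]
                dist = int(pos - best_end)
                k = int(ui) - 1
                while k >= 0 and ends_sorted[k] == best_end:  # report equidistant ties
                    g = glist[end_order[k]]
                    out.append(SnpGeneAnnotation(snp_id, g.gene_id, g.symbol, "nearest_upstream", dist))
                    k -= 1
            if int(di) < len(glist):
                best_start = starts[int(di)]
                dist = int(best_start - pos)
                k = int(di)
                while k < len(glist) and starts[k] == best_start:
                    g = glist[k]
                    out.append(SnpGeneAnnotation(snp_id, g.gene_id, g.symbol, "nearest_downstream", dist))
                    k += 1
    return flag_multi_annotated(out)


def intragenic_snps(gene: GeneModel, snp_map: pd.DataFrame) -> pd.DataFrame:
    """Position-sorted genotype-map SNPs inside a gene's bounds."""
    sel = (
        (snp_map["chrom"].astype(str) == str(gene.chrom))
        & (snp_map["pos"] >= gene.start)
        & (snp_map["pos"] <= gene.end)
    )
    return snp_map.loc[sel].sort_values("pos", kind="mergesort")


def snp2gene_ld(
    snps: Iterable[tuple[str, str, int]],
    genes: Sequence[GeneModel],
    genotypes: GenotypeData,
    window: int = LD_WINDOW_BP,
    max_snps_per_gene: int = MAX_SNPS_PER_GENE,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    per_snp_report: bool = False,
) -> list[SnpGeneAnnotation] | tuple[list[SnpGeneAnnotation], pd.DataFrame]:
    """Annotate genes to SNPs through linkage disequilibrium.

    For each query SNP, genes within ``window`` bp are candidates. Each
    candidate's intragenic SNPs (from the genotype map) are downscaled to
    at most ``max_snps_per_gene`` evenly distributed SNPs, and the pairwise
    r2 of each against the query SNP's dosage vector is computed. The gene
    is annotated with relation ``ld`` carrying the maximum r2; genes whose
    maximum r2 falls below ``r2_threshold`` are not reported.

    When ``per_snp_report`` is set, a long-format table of every
    (query, gene, intragenic SNP, r2) tuple is returned alongside.
    """
    out: list[SnpGeneAnnotation] = []
    long_rows: list[dict] = []
    gene_cache: dict[str, pd.DataFrame] = {}
    for snp_id, chrom, pos in snps:
        if snp_id not in genotypes:
            raise KeyError(f"query SNP {snp_id!r} absent from genotypes")
        query = genotypes.column(snp_id)
        for g in genes:
            if str(g.chrom) != str(chrom):
                continue
            # gap between SNP position and the gene interval
            gap = max(g.start - pos, pos - g.end, 0)
            if gap > window:
                continue
            if g.gene_id not in gene_cache:
                gene_cache[g.gene_id] = intragenic_snps(g, genotypes.snp_map)
            inside = gene_cache[g.gene_id]
            if inside.empty:
                continue
            sel = interleave_indices(len(inside), max_snps_per_gene)
            used = inside.iloc[sel]
            best = -1.0
            for other in used["snp_id"]:
                r2 = pairwise_r2(query, genotypes.column(other))
                if per_snp_report:
                    long_rows.append(
                        {"snp_id": snp_id, "gene_id": g.gene_id, "tag_snp": other, "r2": r2}
                    )
                if not np.isnan(r2) and r2 > best:
                    best = r2
            if best >= r2_threshold:
                out.append(
                    SnpGeneAnnotation(snp_id, g.gene_id, g.symbol, "ld", 0, ld_r2=float(best))
                )
    out = flag_multi_annotated(out)
    if per_snp_report:
        return out, pd.DataFrame(long_rows, columns=["snp_id", "gene_id", "tag_snp", "r2"])
    return out


def remap_positions(
    records: Iterable[tuple[str, str, int]],
    reference: pd.DataFrame,
) -> pd.DataFrame:
    """Remap record positions onto a reference SNP position table.

    ``reference`` has columns snp_id, chrom, pos. Records found in the
    reference by id take the reference position. Records not found get an
    imputed position: the offset (new - old) of the nearest mapped SNP by
    old position on the same chromosome is added to the old position; ties
    between equidistant mapped neighbors go to the lower old position. On a
    chromosome without any mapped SNP, records are left unchanged and
    flagged unmapped.

    Idempotent: remapping an already-remapped table changes nothing.
    """
    ref_by_id = reference.set_index("snp_id")
    rows = []
    for rid, chrom, pos in records:
        rows.append({"snp_id": rid, "chrom": str(chrom), "pos": int(pos)})
    df = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos"])
    df["mapped"] = df["snp_id"].isin(ref_by_id.index)
    df["new_pos"] = df["pos"]
    df.loc[df["mapped"], "new_pos"] = (
        ref_by_id.loc[df.loc[df["mapped"], "snp_id"], "pos"].to_numpy()
    )
    for chrom, grp in df.groupby("chrom", sort=False):
        mapped = grp[grp["mapped"]]
        unmapped = grp[~grp["mapped"]]
        if unmapped.empty:
            continue
        if mapped.empty:
            logger.info("remap_positions: chromosome %s has no mapped SNPs; %d left unchanged",
                        chrom, len(unmapped))
            continue
        # nearest mapped neighbor by old position; ties toward lower position
        anchors = mapped.sort_values(["pos", "snp_id"], kind="mergesort")
        a_pos = anchors["pos"].to_numpy()
        a_off = (anchors["new_pos"] - anchors["pos"]).to_numpy()
        for idx, row in unmapped.iterrows():
            d = np.abs(a_pos - row["pos"])
            best = np.flatnonzero(d == d.min())[0]  # lowest position wins ties
            df.loc[idx, "new_pos"] = row["pos"] + a_off[best]
    df["pos"] = df["new_pos"].astype(np.int64)
    return df[["snp_id", "chrom", "pos", "mapped"]]


def shift_gene_positions(
    genes: Sequence[GeneModel],
    genotype_map: pd.DataFrame,
    reference: pd.DataFrame,
) -> list[GeneModel]:
    """Shift gene bounds from reference coordinates into genotype coordinates.

    Per chromosome, the offset is the median over shared SNPs of
    (genotype-map position - reference position); gene start/end and exons
    are shifted by that offset so that intragenic SNP lookup operates in
    the genotype file's coordinate system.
    """
    merged = genotype_map.merge(reference, on="snp_id", suffixes=("_src", "_ref"))
    if merged.empty:
        raise ValueError("no SNPs shared between genotype map and reference; cannot shift")
    offsets: dict[str, int] = {}
    for chrom, grp in merged.groupby(merged["chrom_src"].astype(str)):
        offsets[chrom] = int(round(np.median(grp["pos_src"] - grp["pos_ref"])))
    shifted = []
    for g in genes:
        off = offsets.get(str(g.chrom))
        if off is None:
            raise ValueError(f"no shared SNPs on chromosome {g.chrom}; cannot shift gene {g.gene_id}")
        shifted.append(
            GeneModel(
                g.gene_id, g.symbol, g.chrom,
                g.start + off, g.end + off, g.strand,
                tuple((s + off, e + off) for s, e in g.exons),
            )
        )
    return shifted
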
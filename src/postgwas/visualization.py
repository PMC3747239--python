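"""Manhattan and regional association plots with a tracks concept.

Every plot emits, besides the rendered file, the plain tables that back
each drawn element (threshold classes and labels for the Manhattan plot;
per-track tables for regional plots). Those tables are the numeric
contract of this module — rendering style may evolve, the tables do not.

Regional plots are composed of stacked tracks: the association p-value
line graph (one line per dataset), a gene track with strand and exon
boxes, an LD triangle of pairwise r-squared, and an optional rare-variant
track fed from VCF files. A track layout frame records the y-band of each
track, and user code can reserve additional bands and draw into them via
a custom panel hook.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.backends.backend_pdf import PdfPages

from .formats_io import GeneModel, GenotypeData, GwasResult, VariantRecord, read_vcf_region
from .genome_annotation import snp2gene_prox
from .ld_core import interleave_snps, ld_matrix

logger = logging.getLogger("postgwas")

GENOMEWIDE_THRESHOLD = 5e-8  # conventional genome-wide significance
SUGGESTIVE_THRESHOLD = 1e-5  # default suggestive-association threshold


class PlotError(ValueError):
    pass


# ---------------------------------------------------------------------------
# track layout
# ---------------------------------------------------------------------------

@dataclass
class TrackLayout:
    """Ordered y-axis bands, one per track; custom rows reserve blank space."""

    rows: list[tuple[str, float, float]] = field(default_factory=list)

    def add_track(self, name: str, y_min: float, y_max: float) -> None:
        if y_min >= y_max:
            raise ValueError(f"track {name}: y_min must be < y_max")
        for other, lo, hi in self.rows:
            if y_min < hi and lo < y_max:
                raise ValueError(f"track {name} [{y_min},{y_max}] overlaps {other} [{lo},{hi}]")
        self.rows.append((name, float(y_min), float(y_max)))

    def band(self, name: str) -> tuple[float, float]:
        for n, lo, hi in self.rows:
            if n == name:
                return lo, hi
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["track", "y_min", "y_max"])


# ---------------------------------------------------------------------------
# point sizing
# ---------------------------------------------------------------------------

def point_size(p: float, base: float = 10.0, scale: float = 6.0, max_size: float = 120.0) -> float:
    """Marker size proportional to -log10 p, clamped; equal p gives equal size."""
    return float(min(base + scale * -np.log10(max(p, 1e-300)), max_size))


# ---------------------------------------------------------------------------
# Manhattan plot
# ---------------------------------------------------------------------------

def classify_thresholds(
    p: np.ndarray,
    genomewide_thresh: float = GENOMEWIDE_THRESHOLD,
    suggestive_thresh: float = SUGGESTIVE_THRESHOLD,
) -> np.ndarray:
    """Per-SNP class: ``genomewide`` (p < genome-wide), ``suggestive``, ``none``."""
    p = np.asarray(p, dtype=float)
    out = np.where(p < genomewide_thresh, "genomewide",
                   np.where(p < suggestive_thresh, "suggestive", "none"))
    return out


def _closest_gene_labels(
    hits: pd.DataFrame, genes: Sequence[GeneModel] | None
) -> dict[str, str]:
    """Label each hit SNP with its closest genes.

    Covering genes are listed first (they would be placed above the peak);
    for intergenic SNPs the nearest upstream and downstream genes are
    joined (left and right of the peak).
    """
    if genes is None or hits.empty:
        return {s: "" for s in hits["snp_id"]}
    ann = snp2gene_prox(
        [(r.snp_id, r.chrom, int(r.pos)) for r in hits.itertuples(index=False)], genes
    )
    labels: dict[str, str] = {s: "" for s in hits["snp_id"]}
    by_snp: dict[str, dict[str, list[str]]] = {}
    for a in ann:
        by_snp.setdefault(a.snp_id, {}).setdefault(a.relation, []).append(a.symbol or a.gene_id)
    for snp_id, rels in by_snp.items():
        if "covering" in rels:
            labels[snp_id] = ",".join(rels["covering"])
        else:
            left = ",".join(rels.get("nearest_upstream", []))
            right = ",".join(rels.get("nearest_downstream", []))
            labels[snp_id] = "|".join(x for x in (left, right) if x)
    return labels


def manhattanplot(
    gwas: GwasResult,
    out: str | Path | None = None,
    genomewide_thresh: float = GENOMEWIDE_THRESHOLD,
    suggestive_thresh: float = SUGGESTIVE_THRESHOLD,
    annotate: str = "genes",
    genes: Sequence[GeneModel] | None = None,
) -> pd.DataFrame:
    """Genome-wide -log10(p) scatter with threshold highlighting.

    Chromosomes are concatenated on the x-axis. SNPs beyond the
    genome-wide threshold are highlighted and annotated with their closest
    genes (or SNP identifiers with ``annotate='snp_ids'``); suggestive
    hits get a second style. Returns the annotation table
    (snp_id, chrom, pos, p, threshold_class, label), which is the test
    surface; when ``out`` is given the figure is also written there.
    """
    df = gwas.records
    if df.empty:
        raise PlotError("cannot draw a Manhattan plot from an empty result set")
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    df["threshold_class"] = classify_thresholds(
        df["p"].to_numpy(), genomewide_thresh, suggestive_thresh
    )
    hits = df[df["threshold_class"] != "none"]
    if annotate == "genes":
        labels = _closest_gene_labels(hits, genes)
        df["label"] = df["snp_id"].map(labels).fillna("")
    elif annotate == "snp_ids":
        df["label"] = np.where(df["threshold_class"] != "none", df["snp_id"], "")
    else:
        df["label"] = ""

    if out is not None:
        # chromosome-concatenated x coordinate
        offset, xs, ticks = 0, [], []
        for chrom, grp in df.groupby("chrom", sort=True):
            xs.append(grp["pos"] + offset - grp["pos"].min())
            ticks.append((chrom, offset + (grp["pos"].max() - grp["pos"].min()) / 2))
            offset += grp["pos"].max() - grp["pos"].min() + 1
        x = pd.concat(xs)
        fig, ax = plt.subplots(figsize=(12, 4))
        colors = {"none": "grey", "suggestive": "tab:blue", "genomewide": "tab:red"}
        for cls, col in colors.items():
            sel = df["threshold_class"] == cls
            ax.scatter(x[sel], -np.log10(df.loc[sel, "p"]), s=8, c=col, label=cls)
        for thresh, style in ((genomewide_thresh, "-"), (suggestive_thresh, "--")):
            ax.axhline(-np.log10(thresh), color="k", ls=style, lw=0.7)
        for idx in df.index[df["label"] != ""]:
            ax.annotate(df.loc[idx, "label"], (x[idx], -np.log10(df.loc[idx, "p"])),
                        fontsize=6, rotation=45)
        ax.set_xticks([t for _c, t in ticks])
        ax.set_xticklabels([c for c, _t in ticks])
        ax.set_xlabel("chromosome")
        ax.set_ylabel(r"$-\log_{10}(p)$")
        fig.tight_layout()
        fig.savefig(out)
        plt.close(fig)
    return df[["snp_id", "chrom", "pos", "p", "threshold_class", "label"]]


# ---------------------------------------------------------------------------
# rare-variant track
# ---------------------------------------------------------------------------

def rare_variant_track(
    vcf_a: Sequence[VariantRecord],
    vcf_b: Sequence[VariantRecord] | None = None,
    select_id_regex: str | None = None,
    select_info_regex: str | None = None,
    max_af: float | None = None,
    effect_class_map: Sequence[tuple[str, str]] = (),
) -> pd.DataFrame:
    """Build the rare-variant track table.

    One row per variant with its minor allele frequency (histogram bar
    height at the variant position). In comparative mode a second source
    contributes mirrored bars, paired by (chrom, pos, alleles); paired
    variants must share the minor allele. Variants passing the selection
    filters are marked ``selected`` and display id/position information;
    an effect class is parsed from INFO with the user-supplied
    (regex, class) map.
    """
    import re as _re

    id_pat = _re.compile(select_id_regex) if select_id_regex else None
    info_pat = _re.compile(select_info_regex) if select_info_regex else None
    eff = [(_re.compile(rx), cls) for rx, cls in effect_class_map]

    def effect_of(v: VariantRecord) -> str:
        for pat, cls in eff:
            if pat.search(v.info):
                return cls
        return ""

    def selected(v: VariantRecord) -> bool:
        if id_pat and not id_pat.search(v.id):
            return False
        if info_pat and not info_pat.search(v.info):
            return False
        if max_af is not None and v.allele_frequency > max_af:
            return False
        return True

    b_by_key = {}
    if vcf_b is not None:
        for v in vcf_b:
            b_by_key[(v.chrom, v.pos, v.ref, v.alt)] = v
    rows = []
    for v in vcf_a:
        row = {
            "id": v.id, "chrom": v.chrom, "pos": v.pos,
            "af": v.allele_frequency, "af_b": np.nan,
            "selected": selected(v), "effect_class": effect_of(v),
        }
        if vcf_b is not None:
            mate = b_by_key.get((v.chrom, v.pos, v.ref, v.alt))
            if mate is not None:
                if mate.minor_allele != v.minor_allele:
                    raise ValueError(
                        f"variant {v.id} at {v.chrom}:{v.pos}: minor alleles differ "
                        f"between sources ({v.minor_allele} vs {mate.minor_allele}); "
                        "comparative mode requires identical minor alleles"
                    )
                row["af_b"] = mate.allele_frequency
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["id", "chrom", "pos", "af", "af_b", "selected", "effect_class"]
    )


# ---------------------------------------------------------------------------
# regional plot
# ---------------------------------------------------------------------------

@dataclass
class RegionSpec:
    """One region to plot: coordinates, datasets and data sources."""

    chrom: str
    start: int
    end: int
    datasets: list[GwasResult] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)
    genotypes: GenotypeData | None = None
    max_ld_snps: int = 200
    vcf_paths: list[str] = field(default_factory=list)
    vcf_id_regex: str | None = None
    vcf_info_regex: str | None = None
    vcf_max_af: float | None = None
    annotate_r2: bool = False
    queried_snps: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("region end must be > start")
        if len(self.vcf_paths) > 2:
            raise ValueError("at most two VCF sources per region")


def _region_tables(spec: RegionSpec) -> dict[str, pd.DataFrame]:
    """Compute the per-track data tables for one region."""
    tables: dict[str, pd.DataFrame] = {}
    pv_rows = []
    for ds in spec.datasets:
        df = ds.records
        sel = df[(df["chrom"].astype(str) == str(spec.chrom))
                 & (df["pos"] >= spec.start) & (df["pos"] <= spec.end)]
        for r in sel.itertuples(index=False):
            pv_rows.append({"dataset": ds.dataset_label, "snp_id": r.snp_id,
                            "pos": int(r.pos), "p": float(r.p),
                            "queried": r.snp_id in spec.queried_snps})
    tables["pvalues"] = pd.DataFrame(
        pv_rows, columns=["dataset", "snp_id", "pos", "p", "queried"]
    ).sort_values(["dataset", "pos"], kind="mergesort").reset_index(drop=True)
    if tables["pvalues"].empty:
        raise PlotError(f"region {spec.chrom}:{spec.start}-{spec.end} covers no SNPs")

    gene_rows = []
    for g in spec.genes:
        if str(g.chrom) == str(spec.chrom) and g.end >= spec.start and g.start <= spec.end:
            gene_rows.append({"gene_id": g.gene_id, "symbol": g.symbol,
                              "start": g.start, "end": g.end, "strand": g.strand,
                              "exons": ",".join(f"{s}-{e}" for s, e in g.exons)})
    tables["genes"] = pd.DataFrame(
        gene_rows, columns=["gene_id", "symbol", "start", "end", "strand", "exons"]
    )

    if spec.genotypes is not None:
        gmap = spec.genotypes.snp_map
        inside = gmap[(gmap["chrom"].astype(str) == str(spec.chrom))
                      & (gmap["pos"] >= spec.start) & (gmap["pos"] <= spec.end)]
        snps = list(inside.sort_values("pos", kind="mergesort")["snp_id"])
        if len(snps) > spec.max_ld_snps:
            snps = interleave_snps(snps, spec.max_ld_snps)
        if len(snps) >= 2:
            tables["ld"] = ld_matrix(spec.genotypes, snps).upper_triangle()
        else:
            tables["ld"] = pd.DataFrame(columns=["snp_a", "snp_b", "r2"])
    else:
        logger.warning("region %s:%d-%d: no genotype source, LD track skipped",
                       spec.chrom, spec.start, spec.end)

    if spec.vcf_paths:
        lists = [
            read_vcf_region(p, spec.chrom, spec.start, spec.end)
            for p in spec.vcf_paths
        ]
        tables["rare_variants"] = rare_variant_track(
            lists[0], lists[1] if len(lists) > 1 else None,
            select_id_regex=spec.vcf_id_regex,
            select_info_regex=spec.vcf_info_regex,
            max_af=spec.vcf_max_af,
        )
    return tables


def _draw_region(
    spec: RegionSpec,
    tables: dict[str, pd.DataFrame],
    fig,
    panel_fn: Callable | None = None,
    extra_tracks: Sequence[tuple[str, float, float]] = (),
) -> TrackLayout:
    layout = TrackLayout()
    n_bands = 2 + ("ld" in tables) + ("rare_variants" in tables)
    band_h = 1.0 / (n_bands + len(extra_tracks))
    y = 1.0
    names = ["pvalues", "genes"] + (["ld"] if "ld" in tables else []) \
        + (["rare_variants"] if "rare_variants" in tables else [])
    for name in names:
        layout.add_track(name, y - band_h, y)
        y -= band_h
    for name, lo, hi in extra_tracks:
        layout.add_track(name, lo, hi)

    ax = fig.add_axes([0.08, 0.05, 0.88, 0.9])
    ax.set_xlim(spec.start, spec.end)
    ax.set_ylim(0, 1)
    ax.set_yticks([])
    ax.set_title(f"{spec.chrom}:{spec.start}-{spec.end}")

    def to_band(vals, lo, hi, vmax):
        vals = np.asarray(vals, dtype=float)
        return lo + (hi - lo) * vals / (vmax if vmax > 0 else 1.0)

    lo, hi = layout.band("pvalues")
    pv = tables["pvalues"]
    vmax = max(-np.log10(pv["p"]).max(), 1.0)
    cmap = plt.get_cmap("tab10")
    for i, (label, grp) in enumerate(pv.groupby("dataset", sort=True)):
        ax.plot(grp["pos"], to_band(-np.log10(grp["p"]), lo, hi, vmax),
                color=cmap(i % 10), lw=1, label=label)
        q = grp[grp["queried"]]
        for r in q.itertuples(index=False):
            ax.annotate(r.snp_id, (r.pos, to_band(-np.log10(r.p), lo, hi, vmax)), fontsize=6)
    ax.legend(loc="upper right", fontsize=6)

    lo, hi = layout.band("genes")
    for k, r in enumerate(tables["genes"].itertuples(index=False)):
        yy = lo + (hi - lo) * (0.2 + 0.6 * (k % 3) / 3)
        ax.plot([r.start, r.end], [yy, yy], color="darkgreen", lw=2)
        marker = ">" if r.strand == "+" else "<"
        ax.plot([r.end if r.strand == "+" else r.start], [yy], marker=marker,
                color="darkgreen", ms=4)
        for span in (r.exons or "").split(","):
            if span:
                s, e = (int(x) for x in span.split("-"))
                ax.fill_between([s, e], yy - 0.01, yy + 0.01, color="darkgreen")
        ax.annotate(r.symbol, ((r.start + r.end) / 2, yy + 0.015), fontsize=6, ha="center")

    if "ld" in tables and not tables["ld"].empty:
        lo, hi = layout.band("ld")
        ld = tables["ld"]
        pos_of = {}
        gmap = spec.genotypes.snp_map
        for r in gmap.itertuples(index=False):
            pos_of[r.snp_id] = r.pos
        span = spec.end - spec.start
        xs, ys, cs, vals = [], [], [], []
        for r in ld.itertuples(index=False):
            pa, pb = pos_of.get(r.snp_a), pos_of.get(r.snp_b)
            if pa is None or pb is None or np.isnan(r.r2):
                continue
            xs.append((pa + pb) / 2)
            # deeper cells for more distant pairs
            ys.append(hi - (hi - lo) * min((pb - pa) / span, 1.0))
            cs.append(plt.get_cmap("Reds")(r.r2))
            vals.append(r.r2)
        if xs:
            ax.scatter(xs, ys, marker="D", s=6, color=cs)
            if spec.annotate_r2:
                for x, y, v in zip(xs, ys, vals):
                    ax.annotate(f"{v:.2f}", (x, y), fontsize=4)

    if "rare_variants" in tables:
        lo, hi = layout.band("rare_variants")
        rv = tables["rare_variants"]
        mid = (lo + hi) / 2 if rv["af_b"].notna().any() else lo
        for r in rv.itertuples(index=False):
            ax.plot([r.pos, r.pos], [mid, mid + (hi - mid) * min(r.af * 2, 1.0)],
                    color="purple", lw=1.5)
            if not np.isnan(r.af_b):  # comparative mirrored bar
                ax.plot([r.pos, r.pos], [mid, mid - (mid - lo) * min(r.af_b * 2, 1.0)],
                        color="orange", lw=1.5)
            if r.selected:
                ax.annotate(r.id, (r.pos, hi), fontsize=5, rotation=90, va="top")
                ax.plot([r.pos, r.pos], [lo, hi], color="grey", lw=0.3, ls=":")

    if panel_fn is not None:
        panel_fn(
            region=(spec.chrom, spec.start, spec.end),
            track_layout=layout,
            tables=tables,
            ax=ax,
        )
    return layout


def regionalplot(
    specs: Sequence[RegionSpec],
    out: str | Path,
    panel_fn: Callable | None = None,
    extra_tracks: Sequence[tuple[str, float, float]] = (),
) -> list[dict[str, pd.DataFrame]]:
    """Render one page per region into a single (searchable) PDF.

    Returns the per-region track tables; a non-PDF ``out`` is only valid
    for a single region. The custom ``panel_fn`` is called once per panel
    after the built-in tracks with the region bounds, the track layout
    (including any ``extra_tracks`` bands reserved for custom data), the
    track tables and the axes; exceptions propagate with panel context.
    """
    out = Path(out)
    all_tables = [_region_tables(spec) for spec in specs]
    if out.suffix.lower() == ".pdf":
        with PdfPages(out) as pdf:
            for spec, tables in zip(specs, all_tables):
                fig = plt.figure(figsize=(8, 6))
                try:
                    _draw_region(spec, tables, fig, panel_fn, extra_tracks)
                except Exception as exc:
                    plt.close(fig)
                    raise PlotError(
                        f"panel for {spec.chrom}:{spec.start}-{spec.end} failed: {exc}"
                    ) from exc
                pdf.savefig(fig)
                plt.close(fig)
    else:
        if len(specs) != 1:
            raise PlotError("multiple regions require a PDF output file")
        fig = plt.figure(figsize=(8, 6))
        _draw_region(specs[0], all_tables[0], fig, panel_fn, extra_tracks)
        fig.savefig(out)
        plt.close(fig)
    return all_tables
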
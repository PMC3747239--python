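"""The superordinate pipeline: run every component with sensible defaults.

One call chains the full post-processing sequence — lead-SNP pruning,
SNP-to-gene annotation, gene-wise p-values, Manhattan plot, regional
plots for every suggestive locus, and the network module analysis — and
records a manifest of every stage, its parameters and its output files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import formats_io, gene_pvalues, genome_annotation, ld_core, network_analysis, visualization

logger = logging.getLogger("postgwas")

EXIT_OK, EXIT_PARTIAL, EXIT_INVALID = 0, 1, 2


class PipelineError(RuntimeError):
    def __init__(self, message: str, manifest: dict | None = None) -> None:
        super().__init__(message)
        self.manifest = manifest


@dataclass
class PipelineConfig:
    """Everything one run needs; round-trips through a single YAML file."""

    gwas: str = ""
    out_dir: str = "postgwas_out"
    dialect: str = "auto"
    dataset_label: str | None = None
    ped: str | None = None
    map: str | None = None
    genes: str | None = None
    edges: str | None = None
    go_dag: str | None = None
    go_mapping: str | None = None
    vcf: str | None = None
    genomewide_thresh: float = visualization.GENOMEWIDE_THRESHOLD
    suggestive_thresh: float = visualization.SUGGESTIVE_THRESHOLD
    network_p_cutoff: float = 0.05
    neighbor_window: int = 100_000
    region_window: int = 200_000
    max_ld_snps: int = 200
    ld_window: int = genome_annotation.LD_WINDOW_BP
    r2_threshold: float = genome_annotation.DEFAULT_R2_THRESHOLD
    gene2p_method: str = "nyholt"
    run_gene2p: bool = True
    run_regional: bool = True
    run_network: bool = True
    keep_shared_interactors: bool = False
    remove_superhubs: bool = False
    seed: int = 0
    workers: int = 1

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def validate(self) -> None:
        if not self.gwas:
            raise ValueError("config requires a gwas result file")
        for name in ("gwas", "ped", "map", "genes", "edges", "go_dag", "go_mapping", "vcf"):
            value = getattr(self, name)
            if value and not Path(value).exists():
                raise ValueError(f"config {name}: file not found: {value}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all enabled stages in order; return and write the manifest.

    Stage order: remove_neighbor_snps -> snp2gene -> gene2p (optional) ->
    manhattanplot -> regionalplot over suggestive loci (optional) ->
    gwas2network (optional). Any stage failure stops the run; the manifest
    then records partial completion and a :class:`PipelineError` is
    raised.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": [], "status": "complete"}

    def record(stage: str, params: dict, outputs: list[str]) -> None:
        manifest["stages"].append({"stage": stage, "params": params, "outputs": outputs})
        logger.info("stage %s complete (%s)", stage, ", ".join(outputs) or "no files")

    def finish(status: str) -> None:
        manifest["status"] = status
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    stage = "setup"
    try:
        gwas = formats_io.read_gwas_results(config.gwas, config.dialect, config.dataset_label)
        genes = formats_io.read_gene_table(config.genes) if config.genes else []
        genotypes = None
        if config.ped and config.map:
            genotypes = formats_io.read_pedmap(config.ped, config.map)

        stage = "remove_neighbor_snps"
        pruned = ld_core.remove_neighbor_snps(gwas, config.neighbor_window)
        pruned_path = out / "lead_snps.assoc"
        formats_io.write_gwas_results(pruned, pruned_path)
        record(stage, {"window": config.neighbor_window,
                       "kept": len(pruned), "input": len(gwas)}, [str(pruned_path)])

        stage = "snp2gene"
        snp_tuples = [(r.snp_id, r.chrom, int(r.pos))
                      for r in pruned.records.itertuples(index=False)]
        annotations = genome_annotation.snp2gene_prox(snp_tuples, genes)
        if genotypes is not None:
            ld_ann = genome_annotation.snp2gene_ld(
                [t for t in snp_tuples if t[0] in genotypes], genes, genotypes,
                window=config.ld_window, r2_threshold=config.r2_threshold,
            )
            annotations = genome_annotation.flag_multi_annotated(annotations + ld_ann)
        ann_path = out / "snp2gene.tsv"
        genome_annotation.annotations_to_frame(annotations).to_csv(ann_path, sep="\t", index=False)
        record(stage, {"ld_window": config.ld_window, "r2_threshold": config.r2_threshold,
                       "n_annotations": len(annotations)}, [str(ann_path)])

        gene_p_frame = None
        if config.run_gene2p and genotypes is not None:
            stage = "gene2p"
            scores = gene_pvalues.gene2p(annotations, gwas, genotypes,
                                         method=config.gene2p_method)
            gene_p_frame = gene_pvalues.scores_to_frame(scores)
            g2p_path = out / "gene2p.tsv"
            gene_p_frame.to_csv(g2p_path, sep="\t", index=False)
            record(stage, {"method": config.gene2p_method, "n_genes": len(scores)},
                   [str(g2p_path)])

        stage = "manhattanplot"
        man_path = out / "manhattan.png"
        man_table = visualization.manhattanplot(
            gwas, man_path, config.genomewide_thresh, config.suggestive_thresh,
            annotate="genes", genes=genes,
        )
        man_tsv = out / "manhattan_annotation.tsv"
        man_table.to_csv(man_tsv, sep="\t", index=False)
        record(stage, {"genomewide": config.genomewide_thresh,
                       "suggestive": config.suggestive_thresh},
               [str(man_path), str(man_tsv)])

        if config.run_regional:
            stage = "regionalplot"
            loci = pruned.records[pruned.records["p"] < config.suggestive_thresh]
            specs = []
            for r in loci.itertuples(index=False):
                specs.append(
                    visualization.RegionSpec(
                        chrom=r.chrom,
                        start=max(1, int(r.pos) - config.region_window // 2),
                        end=int(r.pos) + config.region_window // 2,
                        datasets=[gwas], genes=genes, genotypes=genotypes,
                        max_ld_snps=config.max_ld_snps,
                        vcf_paths=[config.vcf] if config.vcf else [],
                        queried_snps=[r.snp_id],
                    )
                )
            outputs = []
            if specs:
                reg_path = out / "regional.pdf"
                tables = visualization.regionalplot(specs, reg_path)
                outputs.append(str(reg_path))
                for spec_obj, tabs in zip(specs, tables):
                    for name, frame in tabs.items():
                        p = out / f"region_{spec_obj.chrom}_{spec_obj.start}_{name}.tsv"
                        frame.to_csv(p, sep="\t", index=False)
                        outputs.append(str(p))
            record(stage, {"n_loci": len(specs), "window": config.region_window}, outputs)

        if config.run_network and config.edges:
            stage = "gwas2network"
            edge_table = formats_io.read_edge_table(config.edges)
            if gene_p_frame is not None:
                vertex_frame = gene_p_frame.rename(columns={"p_gene": "p"})[["gene_id", "p"]]
            else:
                # fall back to the minimum SNP p per annotated gene
                p_by_snp = gwas.records.set_index("snp_id")["p"]
                rows: dict[str, float] = {}
                for a in annotations:
                    if a.gene_id and a.relation in ("covering", "ld") and a.snp_id in p_by_snp.index:
                        p = float(p_by_snp.loc[a.snp_id])
                        rows[a.gene_id] = min(rows.get(a.gene_id, 1.0), p)
                vertex_frame = pd.DataFrame(
                    {"gene_id": list(rows), "p": [rows[g] for g in rows]}
                )
            merged = network_analysis.merge_datasets([(gwas.dataset_label, vertex_frame)])
            multi = network_analysis.multi_annotated_genes(annotations)
            net = network_analysis.build_network(
                edge_table, merged,
                keep_shared_interactors=config.keep_shared_interactors,
                remove_superhubs=config.remove_superhubs,
                multi_annotated=multi,
            )
            partition = network_analysis.partition_network(net, seed=config.seed)
            go = None
            if config.go_dag and config.go_mapping:
                go = _read_go(config.go_dag, config.go_mapping)
            modules = network_analysis.summarize_modules(net, partition, go)
            mod_path = out / "modules.tsv"
            network_analysis.modules_to_frame(modules, net).to_csv(mod_path, sep="\t", index=False)
            multi_path = out / "multi_annotation.tsv"
            network_analysis.multi_annotation_report(annotations).to_csv(
                multi_path, sep="\t", index=False)
            gml_path = out / "network.graphml"
            network_analysis.export_graphml(net, gml_path)
            record(stage, {"n_vertices": net.number_of_nodes(),
                           "n_edges": net.number_of_edges(),
                           "n_modules": len(modules), "seed": config.seed},
                   [str(mod_path), str(multi_path), str(gml_path)])
    except Exception as exc:
        manifest["stages"].append({"stage": stage, "error": str(exc)})
        finish("partial")
        raise PipelineError(f"stage {stage} failed: {exc}", manifest) from exc
    finish("complete")
    return manifest


def _read_go(dag_path: str, mapping_path: str) -> network_analysis.GoAnnotation:
    """Load a GO DAG (term, parent[, name]) and gene-term mapping TSVs."""
    dag = pd.read_csv(dag_path, sep="\t", dtype=str)
    edges = [(r.term, r.parent) for r in dag.itertuples(index=False)
             if pd.notna(r.parent) and r.parent]
    names = {}
    if "name" in dag.columns:
        names = {r.term: r.name for r in dag.itertuples(index=False) if pd.notna(r.name)}
    mapping = pd.read_csv(mapping_path, sep="\t", dtype=str)
    gene_to_terms: dict[str, set[str]] = {}
    for r in mapping.itertuples(index=False):
        gene_to_terms.setdefault(r.gene_id, set()).add(r.term)
    return network_analysis.GoAnnotation(edges, gene_to_terms, names)
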
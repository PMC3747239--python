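"""Synthetic GWAS inputs with controlled statistical structure.

Everything the toolkit reads can be generated here offline: block-LD
genotypes (ped/map), association result tables with spiked signals, gene
models, toy GO DAGs, interaction edge lists with a planted module, and
toy VCFs. Every generator is a pure function of its spec and seed.

The LD model is copy-with-mutation: each block has a founder dosage
vector drawn from Binomial(2, maf); every other SNP in the block copies
the founder and resamples each entry with a mutation probability chosen
so that the r-squared between two copies hits the block's target
(corr(copy, copy) = (1-eps)^2, so eps = 1 - target^(1/4)). Blocks are
mutually independent. This reproduces the blocky r-squared structure the
annotation and gene-p machinery assume, without a population-genetic
simulator; it does not emulate recombination gradients, allele-frequency
spectra or demography.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .formats_io import GeneModel, GenotypeData, GwasResult
from .network_analysis import GoAnnotation

DEFAULT_N_SAMPLES = 300   # enough for block r2 to land near its target
DEFAULT_SNP_SPACING = 2_000  # bp between adjacent simulated SNPs


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study."""

    n_samples: int = DEFAULT_N_SAMPLES
    blocks: list[tuple[int, float]] = field(default_factory=lambda: [(10, 0.8)] * 5)
    n_genes: int = 5
    spiked: list[tuple[str, float]] = field(default_factory=list)  # (gene_id, p magnitude)
    seed: int = 0
    chrom: str = "1"
    start_pos: int = 100_000
    spacing: int = DEFAULT_SNP_SPACING
    missing_rate: float = 0.0

    @property
    def n_snps(self) -> int:
        return sum(size for size, _t in self.blocks)

    def __post_init__(self) -> None:
        for size, target in self.blocks:
            if not (0 <= target <= 1):
                raise ValueError(f"block r2 target {target} outside [0, 1]")
            if size < 1:
                raise ValueError("block size must be >= 1")


def simulate_genotypes(spec: FixtureSpec) -> GenotypeData:
    """Block-LD dosage matrix via copy-with-mutation."""
    rng = np.random.default_rng(spec.seed)
    cols: list[np.ndarray] = []
    for size, target in spec.blocks:
        maf = rng.uniform(0.15, 0.45)
        founder = rng.binomial(2, maf, size=spec.n_samples).astype(float)
        eps = 1.0 - target ** 0.25 if target > 0 else 1.0
        cols.append(founder)
        for _ in range(size - 1):
            copy = founder.copy()
            flip = rng.random(spec.n_samples) < eps
            copy[flip] = rng.binomial(2, maf, size=int(flip.sum()))
            cols.append(copy)
    dosages = np.column_stack(cols)
    if spec.missing_rate > 0:
        miss = rng.random(dosages.shape) < spec.missing_rate
        dosages[miss] = np.nan
    snp_ids = [f"rs{i + 1}" for i in range(spec.n_snps)]
    positions = spec.start_pos + spec.spacing * np.arange(spec.n_snps)
    snp_map = pd.DataFrame({"snp_id": snp_ids, "chrom": spec.chrom, "pos": positions})
    sample_ids = [f"ind{i + 1}" for i in range(spec.n_samples)]
    return GenotypeData(sample_ids, snp_ids, snp_map, dosages)


def write_pedmap(genotypes: GenotypeData, ped_path: str | Path, map_path: str | Path) -> None:
    """Serialize dosages back to ped/map text (minor allele G, major A)."""
    with open(map_path, "w") as fh:
        for r in genotypes.snp_map.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.snp_id}\t0\t{r.pos}\n")
    code = {0.0: "A A", 1.0: "A G", 2.0: "G G"}
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(genotypes.sample_ids):
            cells = []
            for d in genotypes.dosages[i]:
                cells.append("0 0" if np.isnan(d) else code[float(d)])
            fh.write(f"FAM{i + 1} {sid} 0 0 1 -9 " + " ".join(cells) + "\n")


def simulate_gene_models(spec: FixtureSpec) -> list[GeneModel]:
    """Genes tiling the simulated SNP positions, one per contiguous run.

    The n_genes genes split the SNP track into equal runs; each gene
    covers its run with a small margin and carries two exons and an
    alternating strand.
    """
    positions = spec.start_pos + spec.spacing * np.arange(spec.n_snps)
    bounds = np.array_split(np.arange(spec.n_snps), spec.n_genes)
    genes = []
    for k, idx in enumerate(bounds):
        if len(idx) == 0:
            continue
        start = int(positions[idx[0]] - spec.spacing // 4)
        end = int(positions[idx[-1]] + spec.spacing // 4)
        third = max((end - start) // 3, 1)
        exons = ((start, start + third), (end - third, end))
        genes.append(
            GeneModel(f"G{k + 1}", f"GENE{k + 1}", spec.chrom, start, end,
                      "+" if k % 2 == 0 else "-", exons)
        )
    return genes


def simulate_gwas(
    spec: FixtureSpec,
    genes: list[GeneModel] | None = None,
    dataset_label: str = "synthetic",
) -> GwasResult:
    """Uniform-null association p-values with spiked signals in chosen genes.

    Background SNPs draw p ~ Uniform(0, 1); every SNP inside a spiked gene
    draws p ~ magnitude * Uniform(0, 1), so the gene's minimum p is at
    most the requested magnitude.
    """
    rng = np.random.default_rng(spec.seed + 1)  # decoupled from the genotype stream
    genes = genes if genes is not None else simulate_gene_models(spec)
    by_id = {g.gene_id: g for g in genes}
    for gene_id, _mag in spec.spiked:
        if gene_id not in by_id:
            raise ValueError(f"spiked gene {gene_id!r} absent from the gene map")
    positions = spec.start_pos + spec.spacing * np.arange(spec.n_snps)
    p = rng.uniform(0, 1, size=spec.n_snps)
    for gene_id, mag in spec.spiked:
        g = by_id[gene_id]
        inside = (positions >= g.start) & (positions <= g.end)
        p[inside] = mag * rng.uniform(0, 1, size=int(inside.sum()))
    p = np.clip(p, 1e-300, 1.0)
    records = pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1}" for i in range(spec.n_snps)],
            "chrom": spec.chrom,
            "pos": positions,
            "p": p,
        }
    )
    return GwasResult(dataset_label, records)


def simulate_null_association(
    genotypes: GenotypeData,
    seed: int = 0,
    dataset_label: str = "null",
) -> GwasResult:
    """Null per-SNP association p-values carrying the genotypes' LD structure.

    A phenotype independent of the genotypes is drawn from N(0, 1) and each
    SNP is tested for association by the Pearson correlation t-test. The
    resulting p-values are marginally uniform, and SNPs in LD get correlated
    p-values — the null that effective-number-of-tests corrections are
    calibrated against. Drawing independent uniforms per SNP instead would
    break that coupling and make gene-wise corrections anticonservative.
    """
    from scipy import stats

    rng = np.random.default_rng(seed)
    y = rng.normal(size=len(genotypes.sample_ids))
    x = genotypes.dosages
    n = len(y)
    yc = y - y.mean()
    xc = x - np.nanmean(x, axis=0)
    xc = np.where(np.isnan(xc), 0.0, xc)  # missing dosages drop out of the sums
    num = xc.T @ yc
    den = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
    r = np.where(den > 0, num / den, 0.0)
    t = r * np.sqrt((n - 2) / np.clip(1 - r**2, 1e-12, None))
    p = np.clip(2 * stats.t.sf(np.abs(t), n - 2), 1e-300, 1.0)
    records = pd.DataFrame(
        {
            "snp_id": genotypes.snp_ids,
            "chrom": genotypes.snp_map["chrom"],
            "pos": genotypes.snp_map["pos"],
            "p": p,
        }
    )
    return GwasResult(dataset_label, records)


def simulate_toy_go(
    gene_ids: list[str],
    n_terms: int = 6,
    seed: int = 0,
) -> GoAnnotation:
    """A small GO-like DAG: one root, a parent layer, leaf children.

    Leaf terms annotate random gene subsets; each leaf's genes are a
    subset of its parent's after up-propagation, which is the structure
    the elim decorrelation needs to act on.
    """
    if n_terms < 2:
        raise ValueError("need at least 2 terms")
    rng = np.random.default_rng(seed)
    terms = [f"GO:{i:07d}" for i in range(n_terms)]
    root = terms[0]
    n_parents = max(1, (n_terms - 1) // 3)
    parents = terms[1:1 + n_parents]
    leaves = terms[1 + n_parents:]
    edges = [(p, root) for p in parents]
    gene_to_terms: dict[str, set[str]] = {}
    for i, leaf in enumerate(leaves):
        parent = parents[i % len(parents)]
        edges.append((leaf, parent))
        size = max(2, int(rng.integers(2, max(3, len(gene_ids) // 2))))
        members = rng.choice(gene_ids, size=min(size, len(gene_ids)), replace=False)
        for g in members:
            gene_to_terms.setdefault(g, set()).add(leaf)
    # a few direct parent-level annotations so parents exceed their leaves
    for parent in parents:
        extra = rng.choice(gene_ids, size=min(2, len(gene_ids)), replace=False)
        for g in extra:
            gene_to_terms.setdefault(g, set()).add(parent)
    names = {t: f"toy process {i}" for i, t in enumerate(terms)}
    return GoAnnotation(edges, gene_to_terms, names)


def simulate_network_edges(
    gene_ids: list[str],
    planted: list[str],
    seed: int = 0,
    background_density: float = 0.06,
    label: str = "toy",
) -> pd.DataFrame:
    """Edge list with one planted dense module plus a sparse background.

    All pairs within ``planted`` are connected; the remaining vertex pairs
    are connected independently with ``background_density``. The planted
    genes should be given small association p-values by the caller, so the
    module concentrates high-weight edges and is recoverable by
    partitioning.
    """
    rng = np.random.default_rng(seed)
    planted_set = set(planted)
    rows = []
    for i, a in enumerate(gene_ids):
        for b in gene_ids[i + 1:]:
            both_planted = a in planted_set and b in planted_set
            if both_planted or rng.random() < background_density:
                rows.append({"gene_a": a, "gene_b": b,
                             "label": "planted" if both_planted else label})
    # keep background connected enough: chain the non-planted genes
    have = {(r["gene_a"], r["gene_b"]) for r in rows}
    others = [g for g in gene_ids if g not in planted_set]
    for a, b in zip(others, others[1:]):
        if (a, b) not in have:
            rows.append({"gene_a": a, "gene_b": b, "label": label})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "label"])


def simulate_gene_p_table(
    gene_ids: list[str],
    planted: list[str],
    planted_magnitude: float = 1e-6,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-level p-values: planted genes at the given magnitude, rest null."""
    rng = np.random.default_rng(seed)
    planted_set = set(planted)
    ps = []
    for g in gene_ids:
        if g in planted_set:
            ps.append(planted_magnitude * max(rng.uniform(0, 1), 1e-6))
        else:
            ps.append(max(rng.uniform(0, 1), 1e-12))
    return pd.DataFrame({"gene_id": gene_ids, "p": ps})


TOY_VCF_AFS = (0.0, 0.001, 0.005, 0.02, 0.3)


def write_toy_vcf(
    path: str | Path,
    chrom: str = "1",
    start_pos: int = 100_000,
    spacing: int = 5_000,
    afs: tuple[float, ...] = TOY_VCF_AFS,
    effects: tuple[str, ...] = (),
) -> Path:
    """Write a minimal sites-only VCF with known AFs and INFO effect strings.

    ``effects`` supplies per-variant SnpEff-style effect strings placed in
    an EFF INFO key; missing entries get EFF=INTERGENIC.
    """
    path = Path(path)
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom}>",
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">',
        '##INFO=<ID=EFF,Number=.,Type=String,Description="Predicted effect">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for i, af in enumerate(afs):
        eff = effects[i] if i < len(effects) else "INTERGENIC"
        lines.append(
            f"{chrom}\t{start_pos + i * spacing}\tvar{i + 1}\tA\tT\t.\tPASS\t"
            f"AF={af};EFF={eff}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_fixture_set(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Materialize a complete fixture set (ped/map, GWAS, genes, GO, edges, VCF)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genotypes = simulate_genotypes(spec)
    genes = simulate_gene_models(spec)
    gwas = simulate_gwas(spec, genes)
    paths = {
        "ped": out / "fixture.ped",
        "map": out / "fixture.map",
        "gwas": out / "fixture.assoc",
        "genes": out / "genes.tsv",
        "edges": out / "edges.tsv",
        "vcf": out / "fixture.vcf",
    }
    write_pedmap(genotypes, paths["ped"], paths["map"])
    from .formats_io import write_gene_table, write_gwas_results

    write_gwas_results(gwas, paths["gwas"])
    write_gene_table(genes, paths["genes"])
    gene_ids = [g.gene_id for g in genes]
    planted = [gid for gid, _m in spec.spiked] or gene_ids[:1]
    simulate_network_edges(gene_ids, planted, seed=spec.seed).to_csv(
        paths["edges"], sep="\t", index=False
    )
    write_toy_vcf(paths["vcf"], chrom=spec.chrom, start_pos=spec.start_pos,
                  effects=("NON_SYNONYMOUS_CODING", "DE_NOVO", "SYNONYMOUS_CODING"))
    return paths
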
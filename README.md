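# postgwas

Offline post-processing and interpretation of genome-wide association
study (GWAS) results, as a Python library with a thin command-line
interface. After the association scan itself (Plink, GEMMA, FAsT-LMM,
...), the interpretation work starts: which genes do the associated SNPs
implicate, how strong is a gene's evidence once its linkage
disequilibrium (LD) structure is accounted for, and do moderately
associated genes cluster into functional modules? This package chains
those steps into one reproducible pipeline that runs entirely from local
files — association tables, ped/map genotypes, gene models, edge lists,
GO tables and VCFs — with a synthetic-data generator so everything is
testable without downloads.

## What it computes

**SNP→gene annotation** (`snp2gene_prox`, `snp2gene_ld`). Proximity
annotation reports, per SNP, *all* covering genes (overlapping genes are
common) plus the nearest flanking gene in each direction, using one
vectorized interval search per chromosome. LD annotation considers every
gene within 1 Mb of a query SNP, collects its intragenic SNPs from the
genotype map, downscales them to at most 100 evenly distributed SNPs,
and reports the maximum pairwise r² against the query. r² is the
composite estimator: the squared Pearson correlation of minor-allele
dosages over pairwise-complete samples.

**Gene-wise p-values** (`gene2p`). A gene with M annotated SNPs in LD
carries fewer than M independent tests. From the eigenvalues λ of the
SNP dosage correlation matrix, the effective test count is estimated by

- Nyholt: `Meff = 1 + (M−1)·(1 − Var(λ)/M)` (variance with divisor M−1), or
- Li–Ji: `Meff = Σᵢ [ I(λᵢ ≥ 1) + (λᵢ − ⌊λᵢ⌋) ]`,

and the gene p-value is the Šidák-style correction of the smallest SNP
p-value, `p_gene = 1 − (1 − p_min)^Meff` (Bonferroni optional).

**Network modules** (`gwas2network` stage). A gene interaction network
(any two-column edge list) is weighted by the combined association
strength of each edge's endpoints, by default `w = (−log₁₀ p_a)·(−log₁₀
p_b)`, then decomposed by weighted-modularity maximization so that
high-weight edges concentrate inside modules. Each module's score is the
one-sided Wilcoxon–Mann–Whitney p-value testing whether its member
p-values are stochastically smaller than the rest of the network (lower
score = stronger evidence), and its function is characterized by
upper-tail hypergeometric GO over-representation with elim-style
decorrelation (a significant child term's genes are removed from its
ancestors before those are tested). Shared interactors, superhub
removal, multi-dataset merging with overlap flags, and multi-annotation
reports are supported.

**Plots** (`manhattanplot`, `regionalplot`). Manhattan plots with
genome-wide (5e-8) and suggestive (1e-5) thresholds and closest-gene
labels; regional plots composed of stacked tracks — per-dataset p-value
line graphs, genes with strand and exons, an LD triangle (optionally
interleaved to a maximum SNP count), and a rare-variant track showing
minor allele frequencies and predicted effects from up to two VCFs.
Every plot also emits the plain tables behind each track; custom panel
hooks can draw into reserved track bands. Many loci go into a single
multi-page PDF.

## Worked example

Generate a synthetic study (four genes over four LD blocks, one gene
spiked with a 1e-9 association signal) and run the full pipeline:

```sh
postgwas simulate --seed 11 --out demo/fixtures
postgwas run --config demo/config.yaml
```

with `demo/config.yaml`:

```yaml
gwas: demo/fixtures/fixture.assoc
ped: demo/fixtures/fixture.ped
map: demo/fixtures/fixture.map
genes: demo/fixtures/genes.tsv
edges: demo/fixtures/edges.tsv
vcf: demo/fixtures/fixture.vcf
out_dir: demo/out
neighbor_window: 5000
seed: 1
```

The run completes six stages (`remove_neighbor_snps`, `snp2gene`,
`gene2p`, `manhattanplot`, `regionalplot`, `gwas2network`) and writes a
manifest plus one table per stage. `demo/out/gene2p.tsv` from this exact
run:

```
gene_id  M   meff                p_min                  p_gene              method
G1       7   4.702366133881714   8.170328926167814e-11  3.841988949204733e-10  nyholt
G2       10  7.918772804223073   8.170328926167814e-11  6.46989906094575e-10   nyholt
G3       11  8.616330119966852   8.170328926167814e-11  7.039826499521951e-10  nyholt
G4       7   4.8748000519697765  0.02022872371008655    0.09482051462663077    nyholt
```

The spiked gene G2 (and its flanking genes G1/G3, which inherit the same
lead SNP through flanking annotation) reaches `p_gene ≈ 6.5e-10`: its
best SNP p of 8.2e-11 was corrected for ≈7.9 effective tests among its
10 annotated SNPs — not for all 10, because the block LD makes them
partly redundant. The null gene G4 stays at `p_gene ≈ 0.095`. The
Manhattan annotation table labels the genome-wide hits with the covering
gene:

```
snp_id  chrom  pos     p                      threshold_class  label
rs13    1      124000  5.360886065111569e-10  genomewide       GENE2
rs14    1      126000  5.58265341802964e-10   genomewide       GENE2
```

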
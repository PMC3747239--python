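# Methods

This note documents the statistical procedures, the defaults that
matter, the numerical choices, and what the synthetic data does and does
not emulate.

## Coordinates, formats, dialects

All coordinates are 1-based inclusive, matching map-file and VCF
conventions; any half-open arithmetic is internal. GWAS result dialects
are auto-detected by exact, case-insensitive header-name sets, tried in
the order plink (`SNP/CHR/BP/P`), gemma (`rs/chr/ps/p_wald`), fastlmm
(`SNP/Chromosome/Position/Pvalue`); the field has no standard here, so
these conventional column sets are the contract. Rows with p outside
(0, 1] or a missing position are dropped with a logged count. In ped/map
genotypes the minor allele is determined per SNP from observed
frequencies; an exact 0.5 tie goes to the lexicographically smaller
allele for determinism. Missing genotypes (`0` alleles) become NaN
dosages, distinct from the homozygous-major dosage 0.

In VCFs, the minor allele is determined after reading: from genotype
columns when the file has samples, else from the `AF` INFO field, then
folded so the reported frequency lies in [0, 0.5]. Genotype columns take
priority because they reflect the actual sample rather than a
possibly-stale annotation.

The buffer store caches expensive intermediates (annotation tables, LD
matrices) as serialized entries in a directory keyed by a content hash
of the inputs, so a stored entry is only reused for identical inputs. It
is disabled by default: reusing stale buffer data generated under
different conditions is a real hazard, so opting in is deliberate.

## SNP→gene annotation

Proximity annotation sequentializes each chromosome: gene starts and
ends are sorted once, and all query SNPs are placed with vectorized
`searchsorted` calls. Covering genes are recovered by a bounded backward
scan over start-sorted genes using a running maximum of ends, so
overlapping genes — which occur more often than intuition suggests — are
all reported. Intergenic SNPs get the nearest gene in each direction
with distances; equidistant flanking genes are all reported rather than
arbitrarily tie-broken, on the philosophy that a small surplus of false
positive annotations harms network-style downstream analyses less than a
missed causative gene.

LD annotation searches genes within a 1 Mb window of the query SNP. Each
candidate gene's intragenic SNPs (from the genotype map) are downscaled
to at most 100 evenly distributed SNPs using the index rule
`round(i·(M−1)/(K−1))`, i = 0..K−1, over position-sorted SNPs — a
deterministic rule that always keeps the first and last SNP. The gene is
annotated with the maximum pairwise r² against the query; maximum rather
than mean because a single strongly tagged SNP suffices to link the gene
to the signal, and the optional long-format report retains the full
per-SNP r² list. The reporting threshold defaults to r² ≥ 0.5 and is
exposed, since no universal cutoff exists for calling an LD annotation.

Position remapping assigns reference positions by SNP id; records absent
from the reference get an imputed position by adding the (new − old)
offset of the nearest mapped SNP by old position on the same chromosome
(ties toward lower position). Gene shifting moves gene bounds into the
genotype file's coordinate system by the per-chromosome median of
(source − reference) offsets over shared SNPs; the median resists the
occasional misplaced SNP.

## LD

r² is the composite (dosage-correlation) estimator: squared Pearson
correlation of minor-allele dosage vectors. Inputs are unphased ped/map
genotypes, so haplotype-frequency r² is not estimable without phasing
and is deliberately out of scope. Missing data is handled by
pairwise-complete deletion — the simplest policy consistent with
per-pair computation; monomorphic pairs return NaN rather than an
arbitrary 0 or 1. The matrix routine is an order-independent map over
pairs, so the result is bit-identical for any worker count.

Lead-SNP selection (`remove_neighbor_snps`) is greedy by ascending p:
keep the best SNP, drop everything within ±window on its chromosome,
repeat. Ties on p go to the lower position, then the SNP id, making the
output fully deterministic. The minimum-p SNP of the input is always
retained and kept SNPs are pairwise more than one window apart.

## Gene-wise p-values

Per gene, the correlation matrix of its annotated SNPs' dosages
(pairwise-complete) is eigendecomposed; eigenvalues are clipped at 0
because symmetric-matrix roundoff can produce tiny negative values, and
near-integer eigenvalues are snapped (tolerance 1e-9) before the Li–Ji
integer/fractional split so that `floor` does not misread 4−ε as 3.
Both estimators are clamped into [1, M]. The corrected p-value uses the
Šidák form `1 − (1 − p_min)^Meff` by default, matching the procedure the
Nyholt estimator was introduced with; Bonferroni (`min(1, p_min·Meff)`)
is an option. Which relation types contribute SNPs to a gene is a
parameter; the default includes covering, LD and flanking annotations.

A calibration subtlety: the type-I-error experiment draws per-SNP
p-values by testing a phenotype that is independent of the genotypes
(standard normal) against the actual simulated genotypes, so p-values
are marginally uniform *and* correlated through LD. Drawing independent
uniforms per SNP instead would decouple p-values from the LD structure
and make any Meff < M anticonservative by construction — that would be a
property of the mis-specified null, not of the correction. With the
LD-coupled null, the empirical rejection rate at α = 0.05 over 2000
simulated genes (8-SNP blocks, target r² 0.7, n = 300) is ≈ 0.05 for
both estimators, as the acceptance script recomputes.

## Network analysis

Construction: loop edges are dropped; duplicate edges are merged with
label union (duplicates with identical labels collapse silently), which
lets heterogeneous networks — pathway, interaction, domain similarity —
be mixed in one edge list. Optional superhub removal deletes non-GWAS
vertices whose degree exceeds a quantile (default 0.99) of the degree
distribution; ubiquitous interactors otherwise seed modules regardless
of association strength. The graph is then truncated to GWAS genes,
optionally preserving shared interactors: non-GWAS genes connected to at
least two GWAS genes, which can bridge associated genes through an
unmeasured intermediate.

Edge weights default to `(−log₁₀ p_a)·(−log₁₀ p_b)`; base-10 matches
Manhattan-plot convention (the base only rescales weights, never
reorders partitions). Vertices without association evidence (shared
interactors) contribute factor 1. p-values of 0 must be floored (1e-300)
by the caller; `edge_weight` rejects 0. A user weight function receives
(p, degree, fixed weight) per endpoint; the shipped degree-corrected
variant divides each factor by log(1 + degree) to penalize hubs.

Partitioning maximizes weighted modularity (the Reichardt–Bornholdt
objective at default resolution; the resolution parameter is exposed).
The optimizer is greedy agglomerative clustering followed by seeded
single-vertex local moves, restarted from several random assignments and
from all-singletons; the best candidate by modularity wins. This is
deterministic for a fixed seed, and on every random ≤8-vertex graph
tried it attains the exhaustive-search optimum (the acceptance script
re-verifies 50 such graphs). Isolated vertices form singleton modules.

The module score is the one-sided Mann–Whitney p-value comparing module
p-values against the *complement* (rest of the network), not the full
network including the module — comparing a sample against a superset of
itself biases toward significance. Exact enumeration is used when
min(n, m) ≤ 10 with no ties, otherwise the normal approximation with tie
and continuity corrections. Shared interactors carry no p and are
excluded from both samples.

GO over-representation tests each term's upper hypergeometric tail
P(X ≥ x) with universe N (all annotated genes after up-propagating
annotations along is_a edges), term size K, module size n and overlap x.
Terms are processed leaves-first; a term with p below the elim threshold
(default 0.01, the decorrelation method's conventional default) has its
genes removed from all ancestors before these are tested, so a branch is
represented by its best-fitting term. P-values are intentionally not
corrected for multiple testing — the elim procedure already makes the
tests non-independent in a way standard corrections mishandle. With
threshold 0 the procedure reduces exactly to the plain per-term test.
Module summaries list the top three terms and per-vertex term
membership; modules are ranked ascending by score.

Multi-dataset merging keeps one vertex per gene with per-dataset
p-values, uses the minimum p for weighting and scoring, and flags genes
present in several datasets (rendered boldface-italic). SNPs annotated
to more than one gene are listed in a subsidiary multi-annotation table,
and the affected vertices are tagged; since they inherit one SNP's p
they also get identical vertex sizes — both cues that one locus may be
driving several vertices of a module.

## Plots

The numeric contract of every plot is its emitted tables, not pixels.
Manhattan classification: genome-wide for p < 5e-8 (the conventional
threshold), suggestive for p < 1e-5; peak labels use covering genes for
intragenic SNPs (placed above) and the flanking genes left/right
otherwise, or SNP ids on request. Regional plots allocate one y-band per
track in a layout frame; custom bands may be appended and drawn into via
a panel hook that receives the region bounds, layout and track tables.
Vertex/point sizes scale with −log₁₀ p and are clamped; equal p gives
equal size. The rare-variant track draws one bar per variant at its
genomic position (no frequency binning — positions are the quantity of
interest at locus scale); comparative mode mirrors a second VCF's bars
and requires identical minor alleles for paired variants. Effect classes
are parsed from INFO with a user-supplied regex→class map rather than a
hard-coded annotator vocabulary.

## Synthetic data

The generators are pure functions of (spec, seed). Genotypes use a
copy-with-mutation block model: a founder dosage vector per block
(Binomial(2, maf), maf ~ U(0.15, 0.45)); each further SNP copies the
founder and resamples each entry with probability ε = 1 − target^(1/4),
so two copies correlate at r² ≈ target; blocks are independent.
Association p-values are U(0, 1) background with spiked genes drawing
p ~ magnitude·U(0, 1), and `simulate_null_association` produces
LD-coupled null p-values from a random phenotype as described above. The
toy GO DAG has a root, a parent layer and leaf terms whose genes are
subsets of their parents' — the minimal structure elim acts on. The toy
network plants one clique among chosen genes over a sparse background.

What this does not emulate: recombination-gradient LD decay, realistic
allele-frequency spectra, population structure, case/control sampling,
or genuine functional enrichment. Passing tests therefore demonstrate
the correctness of the algorithms under their stated models — interval
logic, estimator formulas, calibration under the simulated null,
recovery of planted structure — not performance on real cohorts.

## Problem sizes and defaults used in checks

Fixture sizes were chosen desk-scale: 40–500 samples, blocks of 8–250
SNPs, networks of 25 genes with a 6-gene planted module, 2000 genes for
the calibration experiment, and a 48-SNP/4-gene end-to-end pipeline
fixture. Defaults: LD window 1 Mb; 100 SNPs per gene; r² threshold 0.5;
genome-wide 5e-8; suggestive 1e-5; elim threshold 0.01; degree quantile
0.99; partition restarts 16 (raised to 48 on graphs of at most 12 vertices); neighbor-pruning window 100 kb (region-scale
lead-SNP selection); regional window 200 kb.

## Known limitations

- Haplotype-based LD (D′, phased r²) is not computed.
- The partitioner is a heuristic; global optimality is only guaranteed
  where exhaustive search can verify it (small graphs).
- GO inputs are plain TSV tables (term/parent and gene/term); full OBO
  parsing is out of scope.
- Gene p-values are minimum-p based with an Meff correction;
  permutation- or simulation-based gene tests are not offered.
- The rare-variant comparative mode requires identical minor alleles in
  both sources and refuses otherwise.
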
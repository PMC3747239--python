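"""Gene-wise p-values corrected for the effective number of tests.

A gene annotated with M SNPs has effectively fewer than M independent
tests when those SNPs are in LD. Both classic eigenvalue-spectrum
estimators of the effective test count Meff are provided:

* Nyholt:  Meff = 1 + (M - 1) * (1 - Var(lambda) / M), with Var taken with
  divisor M - 1 over the eigenvalues lambda of the SNP correlation matrix.
* Li & Ji: Meff = sum_i [ I(lambda_i >= 1) + (lambda_i - floor(lambda_i)) ]
  over the non-negative eigenvalues.

The gene-wise p-value is then a Sidak-style correction of the smallest
SNP p-value: p_gene = 1 - (1 - p_min)^Meff (Bonferroni, min(1, p_min*Meff),
is available as an option). With Meff = 1 the gene p equals p_min; with
fully independent SNPs it equals the Sidak correction for M tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .formats_io import GenotypeData, GwasResult
from .genome_annotation import SnpGeneAnnotation

logger = logging.getLogger("postgwas")


@dataclass
class GeneScore:
    gene_id: str
    m: int                    # number of annotated SNPs used
    eigenvalues: np.ndarray
    meff: float
    p_min: float
    p_gene: float
    method: str
    incomplete: bool = False  # some annotated SNPs missing from genotypes/results


def _check_corr(corr: np.ndarray) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError(f"correlation matrix must be square, got {corr.shape}")
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    return corr


def _eigenvalues(corr: np.ndarray) -> np.ndarray:
    lam = np.linalg.eigvalsh(_check_corr(corr))
    return np.clip(lam, 0.0, None)  # clip tiny negative noise


def meff_nyholt(corr: np.ndarray, m: int | None = None) -> float:
    """Effective number of tests from the eigenvalue-variance formula."""
    corr = _check_corr(corr)
    m = corr.shape[0] if m is None else m
    if m == 1:
        return 1.0
    lam = _eigenvalues(corr)
    var = float(np.var(lam, ddof=1))
    meff = 1.0 + (m - 1) * (1.0 - var / m)
    return float(min(max(meff, 1.0), m))


def meff_liji(corr: np.ndarray, m: int | None = None) -> float:
    """Effective number of tests from the integer/fractional eigenvalue split."""
    corr = _check_corr(corr)
    m = corr.shape[0] if m is None else m
    lam = _eigenvalues(corr)
    # snap near-integer eigenvalues so floor() is stable under fp noise
    near = np.abs(lam - np.round(lam)) < 1e-9
    lam = np.where(near, np.round(lam), lam)
    meff = float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))
    return float(min(max(meff, 1.0), m))


_MEFF = {"nyholt": meff_nyholt, "liji": meff_liji}


def corrected_p(p_min: float, meff: float, correction: str = "sidak") -> float:
    """Combine the minimum SNP p with Meff into a gene-wise p-value."""
    if not (0 < p_min <= 1):
        raise ValueError(f"p_min must be in (0,1], got {p_min}")
    if correction == "sidak":
        return float(1.0 - (1.0 - p_min) ** meff)
    if correction == "bonferroni":
        return float(min(1.0, p_min * meff))
    raise ValueError(f"unknown correction {correction!r}")


def snp_correlation_matrix(genotypes: GenotypeData, snp_ids: Sequence[str]) -> np.ndarray:
    """Pairwise-complete Pearson correlation of dosage columns."""
    cols = np.column_stack([genotypes.column(s) for s in snp_ids])
    k = cols.shape[1]
    corr = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            ok = ~(np.isnan(cols[:, i]) | np.isnan(cols[:, j]))
            xi, xj = cols[ok, i], cols[ok, j]
            if len(xi) < 2 or xi.std() == 0 or xj.std() == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(xi, xj)[0, 1])
            corr[i, j] = corr[j, i] = r
    return corr


def gene2p(
    annotations: Sequence[SnpGeneAnnotation],
    gwas: GwasResult,
    genotypes: GenotypeData,
    method: str = "nyholt",
    correction: str = "sidak",
    relations: tuple[str, ...] = ("covering", "ld", "nearest_upstream", "nearest_downstream"),
) -> list[GeneScore]:
    """Score every annotated gene with an LD-corrected p-value.

    Per gene: the dosage correlation matrix of its annotated SNPs yields
    Meff by the chosen method; the gene p is the Sidak (default) or
    Bonferroni correction of the minimum SNP p for Meff tests. Genes whose
    annotated SNPs are partly missing from the genotypes or the result
    table are scored on the available subset and flagged.
    """
    if method not in _MEFF:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_MEFF)}")
    p_by_snp = gwas.records.set_index("snp_id")["p"]
    genes: dict[str, list[str]] = {}
    for a in annotations:
        if a.relation in relations and a.gene_id:
            genes.setdefault(a.gene_id, []).append(a.snp_id)
    scores: list[GeneScore] = []
    for gene_id in sorted(genes):
        snps = sorted(set(genes[gene_id]))
        usable = [s for s in snps if s in genotypes and s in p_by_snp.index]
        incomplete = len(usable) < len(snps)
        if incomplete:
            logger.info("gene2p: %s scored on %d/%d SNPs (missing data)",
                        gene_id, len(usable), len(snps))
        if not usable:
            continue
        m = len(usable)
        p_min = float(p_by_snp.loc[usable].min())
        if m == 1:
            lam = np.array([1.0])
            meff = 1.0
        else:
            corr = snp_correlation_matrix(genotypes, usable)
            lam = _eigenvalues(corr)
            meff = _MEFF[method](corr)
        scores.append(
            GeneScore(
                gene_id=gene_id, m=m, eigenvalues=lam, meff=meff,
                p_min=p_min, p_gene=corrected_p(p_min, meff, correction),
                method=method, incomplete=incomplete,
            )
        )
    return scores


def scores_to_frame(scores: Sequence[GeneScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": s.gene_id, "M": s.m, "meff": s.meff,
                "p_min": s.p_min, "p_gene": s.p_gene, "method": s.method,
            }
            for s in scores
        ],
        columns=["gene_id", "M", "meff", "p_min", "p_gene", "method"],
    )
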
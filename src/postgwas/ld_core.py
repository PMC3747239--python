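"""Linkage-disequilibrium computation and SNP selection utilities.

r-squared is the composite (dosage-correlation) estimator: the squared
Pearson correlation of minor-allele dosage vectors over pairwise-complete
samples. This requires no phase information and is the natural choice for
unphased ped/map genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats_io import GenotypeData, GwasResult


@dataclass
class LdMatrix:
    """Symmetric pairwise r-squared matrix over an ordered SNP subset."""

    snp_ids: list[str]
    r2: np.ndarray      # (k, k), values in [0,1] or nan for monomorphic pairs
    n_used: np.ndarray  # (k, k) pairwise-complete sample counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids)

    def upper_triangle(self) -> pd.DataFrame:
        """Long-format table of the strict upper triangle (snp_a, snp_b, r2)."""
        k = len(self.snp_ids)
        ia, ib = np.triu_indices(k, k=1)
        return pd.DataFrame(
            {
                "snp_a": [self.snp_ids[i] for i in ia],
                "snp_b": [self.snp_ids[j] for j in ib],
                "r2": self.r2[ia, ib],
            }
        )


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Missing entries (nan) are handled by pairwise-complete deletion. Returns
    nan when fewer than two complete pairs remain or when either vector is
    constant over the complete pairs (monomorphic: r2 undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        return float("nan")
    xs, ys = x[ok], y[ok]
    sx, sy = xs.std(), ys.std()
    if sx == 0 or sy == 0:
        return float("nan")
    r = float(np.corrcoef(xs, ys)[0, 1])
    return min(r * r, 1.0)


def ld_matrix(
    genotypes: GenotypeData,
    snp_subset: list[str] | None = None,
    parallel: int = 1,
) -> LdMatrix:
    """All pairwise r-squared among ``snp_subset`` (default: all SNPs).

    The result is bit-identical regardless of ``parallel``: worker count
    only chunks the row loop, the reduction order is fixed.
    """
    ids = snp_subset if snp_subset is not None else list(genotypes.snp_ids)
    for s in ids:
        if s not in genotypes:
            raise KeyError(f"SNP {s!r} not in genotypes")
    cols = np.column_stack([genotypes.column(s) for s in ids]) if ids else np.empty((0, 0))
    k = len(ids)
    r2 = np.full((k, k), np.nan)
    n_used = np.zeros((k, k), dtype=int)
    finite = ~np.isnan(cols) if k else cols

    def _row(i: int) -> tuple[np.ndarray, np.ndarray]:
        row_r2 = np.full(k, np.nan)
        row_n = np.zeros(k, dtype=int)
        for j in range(i, k):
            ok = finite[:, i] & finite[:, j]
            row_n[j] = int(ok.sum())
            if i == j:
                xi = cols[ok, i]
                row_r2[j] = 1.0 if (len(xi) >= 1 and xi.std() > 0) else np.nan
            else:
                row_r2[j] = pairwise_r2(cols[:, i], cols[:, j])
        return row_r2, row_n

    if parallel > 1 and k > 2:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=parallel, backend="threading")(
            delayed(_row)(i) for i in range(k)
        )
    else:
        rows = [_row(i) for i in range(k)]
    for i, (row_r2, row_n) in enumerate(rows):
        r2[i, i:] = row_r2[i:]
        r2[i:, i] = row_r2[i:]
        n_used[i, i:] = row_n[i:]
        n_used[i:, i] = row_n[i:]
    return LdMatrix(snp_ids=list(ids), r2=r2, n_used=n_used)


def interleave_indices(m: int, max_n: int) -> np.ndarray:
    """Indices of ``min(m, max_n)`` evenly spaced elements of ``range(m)``.

    Endpoints are always retained; index i of the selection maps to
    round(i * (m-1) / (k-1)). Deterministic.
    """
    if m <= max_n:
        return np.arange(m)
    k = max_n
    idx = np.round(np.arange(k) * (m - 1) / (k - 1)).astype(int)
    return np.unique(idx)


def interleave_snps(snps: list, max_n: int) -> list:
    """Select at most ``max_n`` SNPs evenly distributed by position rank.

    ``snps`` must be ordered by position; the selection preserves order and
    keeps the first and last SNP of the region.
    """
    if max_n < 2:
        raise ValueError("max_n must be >= 2")
    idx = interleave_indices(len(snps), max_n)
    return [snps[i] for i in idx]


def remove_neighbor_snps(gwas: GwasResult, window: int) -> GwasResult:
    """Greedy lead-SNP selection: keep the best SNP per +/-window.

    SNPs are visited by ascending p (ties: lower position, then snp_id);
    a kept SNP removes every other SNP within ``window`` base pairs on the
    same chromosome. Useful to identify the lead SNP of an associated
    region before plotting or annotation.
    """
    df = gwas.records
    order = df.sort_values(["p", "pos", "snp_id"], kind="mergesort")
    kept_mask = pd.Series(True, index=df.index)
    kept_rows: list[tuple[str, int]] = []
    for idx, row in order.iterrows():
        if not kept_mask.loc[idx]:
            continue
        kept_rows.append(idx)
        near = (
            (df["chrom"] == row["chrom"])
            & (df["pos"] - row["pos"]).abs().le(window)
            & (df.index != idx)
        )
        kept_mask.loc[near[near].index] = False
    pruned = df.loc[df.index.isin(kept_rows)].reset_index(drop=True)
    return GwasResult(gwas.dataset_label, pruned)
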
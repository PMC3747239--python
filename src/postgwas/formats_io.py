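"""Readers, writers and the internal data model.

Everything external — GWAS result tables in the common mixed-model tool
dialects, ped/map genotypes, VCF 4.x variant calls, gene-model tables and
edge lists — is normalized here into a small set of containers that the
rest of the package operates on. Coordinates are 1-based inclusive
throughout, matching map-file and VCF conventions.
"""

from __future__ import annotations

import hashlib
import logging
import pickle
import re
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("postgwas")

MISSING = np.nan  # missing dosage code; distinct from 0 (major-allele homozygote)


class FormatError(ValueError):
    """An input file does not conform to its declared format."""


class CacheError(RuntimeError):
    """A buffer-store entry could not be deserialized."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class GwasResult:
    """Per-SNP association records for one named dataset.

    ``records`` holds columns ``snp_id, chrom, pos, p`` plus any extra
    columns from the source file preserved as opaque strings.
    """

    dataset_label: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"snp_id", "chrom", "pos", "p"}
        missing = req - set(self.records.columns)
        if missing:
            raise ValueError(f"GwasResult missing columns: {sorted(missing)}")
        if self.records["snp_id"].duplicated().any():
            dup = self.records.loc[self.records["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"duplicate snp_id within dataset: {dup!r}")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class GenotypeData:
    """Sample x SNP minor-allele dosage matrix with its position map.

    ``dosages`` is float with values {0, 1, 2, nan}; nan codes a missing
    genotype. The map is sorted by (chrom, pos) at construction.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    snp_map: pd.DataFrame  # columns snp_id, chrom, pos (sorted within chrom)
    dosages: np.ndarray    # shape (n_samples, n_snps)
    monomorphic: np.ndarray = field(default=None)  # bool per SNP

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError(
                f"dosage matrix {self.dosages.shape} != "
                f"({len(self.sample_ids)} samples, {len(self.snp_ids)} SNPs)"
            )
        order = np.lexsort(
            (self.snp_map["pos"].to_numpy(), self.snp_map["chrom"].to_numpy())
        )
        if not np.array_equal(order, np.arange(len(order))):
            self.snp_map = self.snp_map.iloc[order].reset_index(drop=True)
            self.snp_ids = list(self.snp_map["snp_id"])
            self.dosages = self.dosages[:, order]
            if self.monomorphic is not None:
                self.monomorphic = self.monomorphic[order]
        if self.monomorphic is None:
            with np.errstate(invalid="ignore"):
                self.monomorphic = np.array(
                    [np.nanstd(self.dosages[:, j]) == 0 for j in range(self.dosages.shape[1])]
                )
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def column(self, snp_id: str) -> np.ndarray:
        try:
            return self.dosages[:, self._index[snp_id]]
        except KeyError:
            raise KeyError(f"SNP {snp_id!r} not present in genotypes") from None

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index


@dataclass(frozen=True)
class GeneModel:
    """A gene with 1-based inclusive bounds, strand and exon structure."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        for (s, e) in self.exons:
            if not (self.start <= s <= e <= self.end):
                raise ValueError(f"gene {self.gene_id}: exon ({s},{e}) outside gene bounds")


@dataclass
class VariantRecord:
    """One VCF variant, normalized to the minor allele.

    ``allele_frequency`` always refers to the minor allele (folded, so it
    lies in [0, 0.5]), determined after reading the file — from genotype
    columns when present, else from the AF INFO field.
    """

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    allele_frequency: float
    info: str = ""
    genotypes: np.ndarray | None = None
    minor_allele: str = ""


# ---------------------------------------------------------------------------
# GWAS result tables
# ---------------------------------------------------------------------------

# header-name sets per dialect, matched case-insensitively in this order
_DIALECTS: dict[str, dict[str, str]] = {
    "plink": {"snp": "snp_id", "chr": "chrom", "bp": "pos", "p": "p"},
    "gemma": {"rs": "snp_id", "chr": "chrom", "ps": "pos", "p_wald": "p"},
    "fastlmm": {"snp": "snp_id", "chromosome": "chrom", "position": "pos", "pvalue": "p"},
}


def _detect_dialect(header: Sequence[str]) -> str:
    low = {h.lower() for h in header}
    for name, cols in _DIALECTS.items():
        if set(cols) <= low:
            return name
    raise FormatError(
        f"cannot auto-detect GWAS result dialect from header {list(header)!r}; "
        "expected plink (SNP/CHR/BP/P), gemma (rs/chr/ps/p_wald) or "
        "fastlmm (SNP/Chromosome/Position/Pvalue) columns"
    )


def read_gwas_results(
    path: str | Path,
    dialect: str = "auto",
    dataset_label: str | None = None,
) -> GwasResult:
    """Read a whitespace-delimited GWAS result file into a :class:`GwasResult`.

    Rows whose p-value is missing or outside (0, 1], or whose position is
    missing, are dropped with a logged count.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    if dialect == "auto":
        dialect = _detect_dialect(df.columns)
    elif dialect not in _DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}")
    mapping = _DIALECTS[dialect]
    rename = {}
    for col in df.columns:
        if col.lower() in mapping:
            rename[col] = mapping[col.lower()]
    missing = set(mapping.values()) - set(rename.values())
    if missing:
        raise FormatError(f"{path}: {dialect} dialect requires columns for {sorted(missing)}")
    df = df.rename(columns=rename)

    n0 = len(df)
    df["p"] = pd.to_numeric(df["p"], errors="coerce")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    keep = df["p"].notna() & (df["p"] > 0) & (df["p"] <= 1) & df["pos"].notna()
    dropped = int(n0 - keep.sum())
    if dropped:
        logger.info("%s: dropped %d/%d rows with invalid p or position", path.name, dropped, n0)
    df = df.loc[keep].copy()
    df["pos"] = df["pos"].astype(np.int64)
    df["chrom"] = df["chrom"].astype(str)
    core = ["snp_id", "chrom", "pos", "p"]
    df = df[core + [c for c in df.columns if c not in core]].reset_index(drop=True)
    return GwasResult(dataset_label or path.stem, df)


def write_gwas_results(gwas: GwasResult, path: str | Path) -> None:
    """Write a result table in the plink-style dialect (SNP CHR BP P)."""
    out = pd.DataFrame(
        {
            "SNP": gwas.records["snp_id"],
            "CHR": gwas.records["chrom"],
            "BP": gwas.records["pos"],
            "P": gwas.records["p"].map(lambda v: np.format_float_scientific(v, trim="-")),
        }
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ped/map genotypes
# ---------------------------------------------------------------------------

def read_pedmap(ped_path: str | Path, map_path: str | Path) -> GenotypeData:
    """Read ped/map text genotypes, recoding to minor-allele dosages.

    The minor allele of each SNP is determined from the observed allele
    frequencies; an exact 0.5 tie is broken toward the lexicographically
    smaller allele. Allele code "0" means missing.
    """
    map_df = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos"], dtype=str,
    )
    map_df["pos"] = map_df["pos"].astype(np.int64)
    n_snps = len(map_df)

    sample_ids: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise FormatError(
                    f"{ped_path} line {lineno}: expected {6 + 2 * n_snps} fields "
                    f"for {n_snps} map SNPs, got {len(parts)}"
                )
            sample_ids.append(parts[1])
            allele_rows.append(parts[6:])

    alleles = np.array(allele_rows, dtype=object).reshape(len(sample_ids), n_snps, 2)
    dosages = np.zeros((len(sample_ids), n_snps), dtype=float)
    mono = np.zeros(n_snps, dtype=bool)
    for j in range(n_snps):
        col = alleles[:, j, :]
        obs = col[col != "0"]
        counts: dict[str, int] = {}
        for a in obs:
            counts[a] = counts.get(a, 0) + 1
        if len(counts) <= 1:
            mono[j] = True
            minor = None
        else:
            # minor = rarer allele; ties toward lexicographically smaller
            minor = min(counts, key=lambda a: (counts[a], a))
        for i in range(len(sample_ids)):
            a, b = col[i]
            if a == "0" or b == "0":
                dosages[i, j] = MISSING
            elif minor is None:
                dosages[i, j] = 0.0
            else:
                dosages[i, j] = (a == minor) + (b == minor)
    if mono.any():
        logger.info("read_pedmap: %d monomorphic SNPs", int(mono.sum()))
    return GenotypeData(
        sample_ids=sample_ids,
        snp_ids=list(map_df["snp_id"]),
        snp_map=map_df[["snp_id", "chrom", "pos"]].copy(),
        dosages=dosages,
        monomorphic=mono,
    )


# ---------------------------------------------------------------------------
# gene tables and edge lists
# ---------------------------------------------------------------------------

def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a gene-model TSV: gene_id symbol chrom start end strand exons.

    ``exons`` is a comma-separated list of ``start-end`` spans; it may be
    empty or absent.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    genes = []
    for row in df.itertuples(index=False):
        exon_field = getattr(row, "exons", "") or ""
        exons = tuple(
            tuple(int(x) for x in span.split("-"))
            for span in str(exon_field).split(",")
            if span and span != "nan"
        )
        genes.append(
            GeneModel(
                gene_id=row.gene_id,
                symbol=getattr(row, "symbol", row.gene_id),
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                strand=getattr(row, "strand", "+"),
                exons=exons,
            )
        )
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "symbol": g.symbol,
            "chrom": g.chrom,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "exons": ",".join(f"{s}-{e}" for s, e in g.exons),
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_edge_table(path: str | Path) -> pd.DataFrame:
    """Read a gene-gene edge list TSV (gene_a gene_b [weight] [label])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: edge table needs at least two columns")
    cols = list(df.columns)
    df = df.rename(columns={cols[0]: "gene_a", cols[1]: "gene_b"})
    if "weight" in df.columns:
        df["weight"] = pd.to_numeric(df["weight"])
    return df


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _fold_af(af: float) -> float:
    return af if af <= 0.5 else 1.0 - af


def read_vcf_region(
    path: str | Path,
    chrom: str,
    start: int,
    end: int,
    id_regex: str | None = None,
    info_regex: str | None = None,
    max_af: float | None = None,
) -> list[VariantRecord]:
    """Read variants in a 1-based inclusive region, with optional filters.

    Filters compose: a variant is returned when it matches ``id_regex`` and
    ``info_regex`` (when given) and its minor-allele frequency is at most
    ``max_af`` (when given). The minor-allele frequency is recomputed from
    genotype columns when the file has samples, else taken from the AF INFO
    field, and folded so it refers to the minor allele.
    """
    from cyvcf2 import VCF

    id_pat = re.compile(id_regex) if id_regex else None
    info_pat = re.compile(info_regex) if info_regex else None
    out: list[VariantRecord] = []
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise FormatError(f"{path}: cannot open as VCF ({exc})") from exc
    has_samples = len(vcf.samples) > 0
    for var in vcf:
        if var.CHROM != str(chrom) or not (start <= var.POS <= end):
            continue
        vid = var.ID or "."
        info_str = str(var).rstrip("\n").split("\t")[7] if var.INFO else "."
        if id_pat and not id_pat.search(vid):
            continue
        if info_pat and not info_pat.search(info_str):
            continue
        alt = var.ALT[0] if var.ALT else "."
        gts = None
        if has_samples:
            arr = np.asarray(var.gt_types, dtype=float)  # 0 hom-ref,1 het,2 unknown,3 hom-alt
            dos = np.where(arr == 3, 2.0, arr)
            dos[arr == 2] = np.nan
            gts = dos
            with np.errstate(invalid="ignore"):
                af = float(np.nansum(dos) / (2 * np.sum(~np.isnan(dos)))) if np.sum(~np.isnan(dos)) else 0.0
        else:
            raw = var.INFO.get("AF")
            if raw is None:
                af = 0.0
            elif isinstance(raw, (tuple, list)):
                af = float(raw[0])
            else:
                af = float(raw)
        maf = _fold_af(af)
        minor = alt if af <= 0.5 else var.REF
        if af == 0.5:  # tie: lexicographically smaller allele, for determinism
            minor = min(var.REF, alt)
        if max_af is not None and maf > max_af:
            continue
        out.append(
            VariantRecord(
                id=vid, chrom=var.CHROM, pos=var.POS, ref=var.REF, alt=alt,
                allele_frequency=maf, info=info_str, genotypes=gts, minor_allele=minor,
            )
        )
    return out


# ---------------------------------------------------------------------------
# buffer store
# ---------------------------------------------------------------------------

class BufferStore:
    """A directory of serialized cache entries keyed by content hash.

    Mirrors the buffer-variable mechanism: expensive intermediate data
    (annotation tables, LD matrices) can be stored locally and reused on
    re-runs. Disabled by default; a disabled store never consults or writes
    the cache.
    """

    def __init__(self, directory: str | Path, enabled: bool = False) -> None:
        self.directory = Path(directory)
        self.enabled = enabled

    @staticmethod
    def make_key(*parts: object) -> str:
        h = hashlib.sha256(repr(parts).encode())
        return h.hexdigest()[:32]

    def _path(self, key: str) -> Path:
        safe = re.sub(r"[^A-Za-z0-9_.-]", "_", key)
        return self.directory / f"{safe}.pkl"

    def get_or_compute(self, key: str, producer: Callable[[], object]) -> object:
        """Return the stored value for ``key`` or run ``producer`` once.

        When disabled, the producer always runs and nothing is stored. A
        corrupt entry is replaced by a fresh computation.
        """
        if not self.enabled:
            return producer()
        p = self._path(key)
        if p.exists():
            try:
                with open(p, "rb") as fh:
                    entry = pickle.load(fh)
                return entry["value"]
            except Exception as exc:
                logger.warning("buffer entry %s corrupt (%s); recomputing", key, exc)
        value = producer()
        self.directory.mkdir(parents=True, exist_ok=True)
        entry = {"value": value, "source": key, "timestamp": time.time()}
        with open(p, "wb") as fh:
            pickle.dump(entry, fh)
        return value

    def list_entries(self) -> list[str]:
        if not self.directory.exists():
            return []
        return sorted(p.stem for p in self.directory.glob("*.pkl"))

    def clear(self) -> int:
        n = 0
        for p in self.directory.glob("*.pkl"):
            p.unlink()
            n += 1
        return n


def buffer_get_or_compute(
    key: str, producer: Callable[[], object], enabled: bool = False,
    directory: str | Path = ".postgwas_buffer",
) -> object:
    """Functional wrapper around :class:`BufferStore`."""
    return BufferStore(directory, enabled=enabled).get_or_compute(key, producer)
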
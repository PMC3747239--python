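import numpy as np
import pandas as pd
import pytest

from postgwas.formats_io import GeneModel, GenotypeData
from postgwas.synthetic_fixtures import FixtureSpec, simulate_gene_models, simulate_genotypes


@pytest.fixture
def small_genotypes() -> GenotypeData:
    """12 samples x 6 SNPs, hand-built: rs1=rs2 (perfect LD), rs5 monomorphic."""
    rng = np.random.default_rng(42)
    base = rng.binomial(2, 0.4, size=12).astype(float)
    other = rng.binomial(2, 0.3, size=12).astype(float)
    third = rng.binomial(2, 0.25, size=12).astype(float)
    dos = np.column_stack([
        base,                 # rs1
        base.copy(),          # rs2 duplicates rs1
        other,                # rs3
        2.0 - base,           # rs4: perfect negative correlation with rs1
        np.zeros(12),         # rs5 monomorphic
        third,                # rs6
    ])
    ids = [f"rs{i}" for i in range(1, 7)]
    snp_map = pd.DataFrame({
        "snp_id": ids, "chrom": "1",
        "pos": [1000, 2000, 3000, 4000, 5000, 6000],
    })
    return GenotypeData([f"s{i}" for i in range(12)], ids, snp_map, dos)


@pytest.fixture
def block_spec() -> FixtureSpec:
    return FixtureSpec(n_samples=400, blocks=[(10, 0.8), (10, 0.8), (10, 0.0)],
                       n_genes=3, seed=7)


@pytest.fixture
def block_genotypes(block_spec) -> GenotypeData:
    return simulate_genotypes(block_spec)


@pytest.fixture
def block_genes(block_spec) -> list[GeneModel]:
    return simulate_gene_models(block_spec)


@pytest.fixture
def two_gene_map() -> list[GeneModel]:
    return [
        GeneModel("G1", "GENE1", "1", 100, 200),
        GeneModel("G2", "GENE2", "1", 300, 400),
    ]
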
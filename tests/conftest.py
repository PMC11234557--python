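import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from rohscan.genotype_io import GenotypeMatrix, SNPMap


def make_panel(codes, positions=None, chroms=None, individuals=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a codes array with sensible defaults."""
    codes = np.asarray(codes, dtype=np.int8)
    n_ind, n_snps = codes.shape
    if positions is None:
        positions = np.arange(1, n_snps + 1) * 10_000
    if chroms is None:
        chroms = ["1"] * n_snps
    if individuals is None:
        individuals = [f"ind{i + 1}" for i in range(n_ind)]
    table = pd.DataFrame({
        "snp_id": [f"snp{k + 1}" for k in range(n_snps)],
        "chrom": chroms, "pos": positions, "a1": "A", "a2": "B",
    })
    return GenotypeMatrix(individuals, SNPMap(table), codes)


def random_panel(rng, n_ind=20, n_snps=300, het_rate=0.3, missing_rate=0.05,
                 spacing=20_000) -> GenotypeMatrix:
    """Random mixed panel used by the oracle-equivalence tests."""
    codes = rng.choice([0, 2], size=(n_ind, n_snps)).astype(np.int8)
    het = rng.random((n_ind, n_snps)) < het_rate
    codes[het] = 1
    miss = rng.random((n_ind, n_snps)) < missing_rate
    codes[miss] = -1
    positions = np.cumsum(rng.integers(1, spacing, size=n_snps)) + 1
    return make_panel(codes, positions=positions)


@pytest.fixture
def small_panel():
    rng = np.random.default_rng(7)
    return random_panel(rng, n_ind=10, n_snps=50)
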
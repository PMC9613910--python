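import numpy as np
import pandas as pd
import pytest

from felpop import GenotypeMatrix, PopulationPanel, PopulationSpec, SimConfig
from felpop import simulate_balding_nichols


def build_gm(calls, chrom=None, pos=None, samples=None):
    """GenotypeMatrix from a (n_samples, n_variants) list/array of dosages
    (-1 missing); default map: one chromosome, SNPs 100 kb apart."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samp, n_var = calls.shape
    chrom = ["1"] * n_var if chrom is None else list(chrom)
    pos = [100_000 * (i + 1) for i in range(n_var)] if pos is None else list(pos)
    variants = pd.DataFrame(
        {
            "id": [f"snp{i}" for i in range(n_var)],
            "chrom": chrom,
            "pos": pos,
            "ref": ["A"] * n_var,
            "alt": ["G"] * n_var,
        }
    )
    samples = samples or [f"s{i}" for i in range(n_samp)]
    return GenotypeMatrix(variants, samples, calls)


@pytest.fixture
def two_pop_gm():
    """Two populations of 4, one chromosome, hand-set genotypes."""
    calls = [
        [0, 1, 2, 0, 1],
        [0, 1, 2, 1, 0],
        [1, 0, 2, 2, 1],
        [0, 2, 2, 0, -1],
        [2, 1, 0, 0, 1],
        [2, 2, 0, 1, 1],
        [1, 2, 0, 0, 0],
        [2, 1, 0, 2, 1],
    ]
    gm = build_gm(calls)
    panel = PopulationPanel({f"s{i}": ("A" if i < 4 else "B") for i in range(8)})
    return gm, panel


@pytest.fixture(scope="session")
def bn_dataset():
    """Moderately sized Balding-Nichols dataset shared across tests."""
    cfg = SimConfig(
        seed=11,
        chrom_lengths_bp={"1": 40_000_000, "2": 40_000_000},
        snp_density_per_kb=0.05,
        populations=[
            PopulationSpec("A", 50, fst=0.05),
            PopulationSpec("B", 50, fst=0.05),
            PopulationSpec("C", 50, fst=0.05),
        ],
    )
    return simulate_balding_nichols(cfg)
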
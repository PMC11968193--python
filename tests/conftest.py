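import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from migrascan.containers import GenotypeMatrix, MIGRANT, RESIDENT
from migrascan.simdata import SimConfig, simulate


def make_geno(dosages, positions=None, chrom="chr1", samples=None) -> GenotypeMatrix:
    """Build a small genotype matrix from a (samples x sites) array."""
    dosages = np.asarray(dosages, dtype=float)
    n, L = dosages.shape
    if positions is None:
        positions = np.arange(1, L + 1) * 100
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "ref": "A", "alt": "T", "id": "."}
    )
    return GenotypeMatrix(sites, dosages, list(samples))


def two_pop_config(F_pop: float, n_diploids: int = 25, L: int = 20_000, seed: int = 0,
                   **kw) -> SimConfig:
    """Two populations with independent drift F_pop from a shared root."""
    defaults = dict(
        populations_per_clade={
            "west": [("P1", RESIDENT, n_diploids), ("P2", MIGRANT, n_diploids)]
        },
        F_clade=0.0,
        F_pop=F_pop,
        L_sites=L,
        chrom_length_bp=max(4 * L, 1_000_000),
        n_genes=4,
        n_sweep_genes=0,
        seed=seed,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def default_scenario():
    """One realization of the default simulated study design."""
    haps, truth, popmap = simulate(SimConfig(seed=11))
    return haps, truth, popmap
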
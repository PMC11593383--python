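import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from rohscan.io import GenotypeDataset, HET, HOM_A1, HOM_A2, MISSING


def make_dataset(geno_rows, positions=None, chroms=None, populations=None,
                 sample_names=None):
    """Build a small GenotypeDataset from a list of per-sample code lists."""
    geno = np.asarray(geno_rows, dtype=np.int8)
    n, m = geno.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 100_000
    if chroms is None:
        chroms = ["1"] * m
    snp_map = pd.DataFrame({
        "chrom": [str(c) for c in chroms],
        "snp": [f"snp{i}" for i in range(m)],
        "cm": 0.0,
        "pos": np.asarray(positions, dtype=np.int64),
        "a1": "A",
        "a2": "B",
    })
    if populations is None:
        populations = ["POP"] * n
    if sample_names is None:
        sample_names = [f"ind{i}" for i in range(n)]
    samples = pd.DataFrame({
        "fid": populations, "sample": sample_names, "father": "0",
        "mother": "0", "sex": "0", "phenotype": "-9", "population": populations,
    })
    return GenotypeDataset(snp_map, samples, geno)


@pytest.fixture
def tiny_dataset():
    """3 samples x 4 markers, hand-written codes."""
    return make_dataset(
        [[HOM_A1, HET, HOM_A2, MISSING],
         [HET, HET, HOM_A1, HOM_A1],
         [HOM_A2, MISSING, MISSING, HET]],
        positions=[1000, 2000, 3000, 4000],
    )


@pytest.fixture(scope="session")
def sim_small():
    """Small simulated dataset with planted tracts, session-wide."""
    from rohscan.simulate import SimConfig, simulate_dataset
    cfg = SimConfig(seed=11, n_chromosomes=2, chromosome_length_bp=30_000_000,
                    snp_density_per_mb=120.0,
                    populations=(("P1", 8), ("P2", 8)),
                    tracts_per_class=(("2-4Mb", 1), ("4-8Mb", 1)))
    return simulate_dataset(cfg)
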
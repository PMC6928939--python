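"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from qtmod import (
    PhenotypeTable,
    simulate_genotypes,
    simulate_phenotypes,
    strong_signal_truth,
)


@pytest.fixture(scope="session")
def small_geno():
    """120 samples x 400 SNPs, 2 LD blocks, deterministic."""
    return simulate_genotypes(120, 400, (0.1, 0.5), n_ld_blocks=2, seed=101)


@pytest.fixture(scope="session")
def strong_dataset():
    """Mid-size dataset with planted effects: (G, P, truth)."""
    G = simulate_genotypes(400, 900, (0.1, 0.5), n_ld_blocks=2, seed=202)
    spec = strong_signal_truth(G, seed=303)
    P, truth = simulate_phenotypes(G, spec)
    return G, P, truth


@pytest.fixture()
def toy_pheno():
    """Tiny hand-checkable phenotype table: 6 samples, 4 ROI columns."""
    rng = np.random.default_rng(7)
    icv = np.array([1.40e6, 1.45e6, 1.50e6, 1.55e6, 1.60e6, 1.52e6])
    data = pd.DataFrame(
        {
            "diagnosis": ["NC", "NC", "NC", "AD", "AD", "NC"],
            "age": [70.0, 72.0, 74.0, 76.0, 78.0, 75.0],
            "sex": [0.0, 1.0, 0.0, 1.0, 0.0, 1.0],
            "education": [16.0, 12.0, 18.0, 14.0, 15.0, 13.0],
            "icv": icv,
            "roiA": 4000.0 + 0.002 * icv + rng.normal(0, 5, 6),
            "roiB": 1500.0 + 0.001 * icv + rng.normal(0, 5, 6),
            "roiC": 7000.0 + 0.004 * icv + rng.normal(0, 5, 6),
            "roiD": 900.0 + 0.0005 * icv + rng.normal(0, 5, 6),
        },
        index=pd.Index([f"S{i}" for i in range(6)], name="sample"),
    )
    return PhenotypeTable(data, ["roiA", "roiB", "roiC", "roiD"])
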
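import numpy as np
import pytest

from wheatgs.genotypes import GenotypeMatrix
from wheatgs.simdata import SimConfig, simulate_genotypes, simulate_trials


@pytest.fixture(scope="session")
def clean_sim():
    """Complete homozygous genotypes with trial phenotypes (h2 = 0.5)."""
    cfg = SimConfig(n_lines=80, n_markers=300, missing_rate=0.0, het_rate=0.0,
                    maf_range=(0.1, 0.5), target_h2=0.5, seed=11)
    geno = simulate_genotypes(cfg)
    pheno, truth = simulate_trials(cfg, geno.truth)
    return cfg, geno, pheno, truth


@pytest.fixture(scope="session")
def marker_data():
    """Small dense regression problem: 50 lines x 120 markers, linear signal."""
    rng = np.random.default_rng(7)
    X = rng.choice([0.0, 2.0], size=(50, 120), p=[0.6, 0.4])
    beta = np.zeros(120)
    beta[:15] = rng.standard_normal(15) * 0.3
    y = 20.0 + (X - X.mean(axis=0)) @ beta + rng.standard_normal(50)
    return X, y


def make_matrix(dosages, prefix="L"):
    """GenotypeMatrix from a raw array with auto-generated ids."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    return GenotypeMatrix([f"{prefix}{i}" for i in range(n)],
                          [f"M{j}" for j in range(m)], dosages)
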
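"""Shared fixtures: small synthetic panels and cohorts used across tests."""

import numpy as np
import pandas as pd
import pytest

from gwaskit.genotypes import GenotypeMatrix, simulate_ld_reference
from gwaskit.liability import LiabilityModelParams, simulate_liability_phenotypes


@pytest.fixture(scope="session")
def small_panel() -> GenotypeMatrix:
    """10k individuals, 50 LD blocks of 10 variants, mixed rho."""
    return simulate_ld_reference(n=10_000, blocks=50, block_size=10,
                                 rho=(0.0, 0.9), seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_panel):
    params = LiabilityModelParams(h2_liab=0.3, m_causal=100, seed=12)
    return simulate_liability_phenotypes(small_panel, params)


def make_sumstats_frame(rng: np.random.Generator, m: int = 200,
                        chrom: str = "1") -> pd.DataFrame:
    """Random but internally consistent summary-statistic table."""
    from scipy import stats

    beta = rng.normal(0, 0.05, m)
    se = rng.uniform(0.01, 0.05, m)
    z = beta / se
    return pd.DataFrame({
        "id": [f"rs{i}" for i in range(m)],
        "chrom": chrom,
        "pos": np.arange(1, m + 1) * 10_000,
        "a1": rng.choice(["A", "C"], m),
        "a2": rng.choice(["G", "T"], m),
        "freq": rng.uniform(0.05, 0.95, m),
        "beta": beta,
        "se": se,
        "z": z,
        "p": np.clip(2 * stats.norm.sf(np.abs(z)), 1e-300, 1.0),
        "n": 10_000,
        "n_case": 1_000,
        "n_control": 9_000,
    })
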
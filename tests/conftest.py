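"""Shared fixtures: annotation tables and seeded simulated cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import t2drep as t

# One package-wide base seed for derandomised stochastic tests.
SEED = 20140613


def make_annotations(config: t.SimulationConfig) -> pd.DataFrame:
    """Annotation table matching a simulation config (risk = effect allele)."""
    return pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in config.snps],
            "chromosome": [s.chromosome for s in config.snps],
            "effect_allele": [s.effect_allele for s in config.snps],
            "other_allele": [s.other_allele for s in config.snps],
            "risk_allele_study": [s.effect_allele for s in config.snps],
            "risk_allele_reference": [s.effect_allele for s in config.snps],
            "reference_or": [s.per_allele_or for s in config.snps],
            "reference_raf": [s.risk_allele_freq for s in config.snps],
        }
    )


@pytest.fixture(scope="session")
def table1() -> pd.DataFrame:
    return t.load_table1()


@pytest.fixture(scope="session")
def table1_config(table1) -> t.SimulationConfig:
    """Simulation truth = the published per-SNP RAFs and adjusted ORs."""
    return t.config_from_annotations(table1, seed=SEED)


@pytest.fixture(scope="session")
def table1_cohort(table1_config) -> pd.DataFrame:
    """One 830/1497 cohort simulated under the published panel."""
    return t.simulate_cohort(table1_config)


@pytest.fixture(scope="session")
def table1_weights(table1) -> pd.Series:
    """GRS weights w = ln(OR) taken from the published adjusted ORs."""
    return pd.Series(
        np.log(table1["or_adjusted"].to_numpy()), index=table1["snp_id"], name="w"
    )


@pytest.fixture(scope="session")
def small_config() -> t.SimulationConfig:
    return t.SimulationConfig(
        n_cases=150,
        n_controls=250,
        seed=SEED,
        snps=[
            t.SimSnp("rs_a", 0.30, 1.30),
            t.SimSnp("rs_b", 0.60, 0.85),
            t.SimSnp("rs_c", 0.15, 1.00),
            t.SimSnp("rs_x", 0.50, 1.20, chromosome="X"),
        ],
        missing_rate=0.02,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config) -> pd.DataFrame:
    return t.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_annotations(small_config) -> pd.DataFrame:
    return make_annotations(small_config)
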
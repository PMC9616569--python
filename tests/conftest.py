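"""Shared fixtures: small seeded cohorts rendered once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from polycnv.config import CnvLocus, CohortConfig, CovariateModel
from polycnv.hmm import compile_pfb, default_params
from polycnv.synthetic import render_lrr_baf, simulate_cohort, simulate_snp_map

ALL_GROUPS = {"EP": 0.625, "WP": 0.329, "EPWP": 0.046}


def uniform_freq(f: float) -> dict[str, float]:
    return {g: f for g in ALL_GROUPS}


@pytest.fixture(scope="session")
def clean_config() -> CohortConfig:
    """Noise-free single-chromosome cohort with one deletion and one
    duplication locus (wave, batch effects and noise all off)."""
    return CohortConfig(
        n_cases=4,
        n_controls=4,
        chromosome_lengths={"1": 5_000_000},
        cnv_loci=(
            CnvLocus("1", 1_000_001, 1_400_000, cn=1, frequency=uniform_freq(1.0), name="del"),
            CnvLocus("1", 3_000_001, 3_400_000, cn=3, frequency=uniform_freq(1.0), name="dup"),
        ),
        lrr_noise_sd=0.0,
        baf_noise_sd=0.0,
        wave_amplitude=0.0,
        batch_effects={"b1": 0.0},
        covariate_model=CovariateModel(batch={"b1": 0.0}),
        seed=11,
    )


@pytest.fixture(scope="session")
def noisy_config() -> CohortConfig:
    """Default-noise cohort used for caller round-trip checks."""
    return CohortConfig(
        n_cases=10,
        n_controls=10,
        chromosome_lengths={"1": 5_000_000},
        cnv_loci=(
            CnvLocus("1", 1_000_001, 1_300_000, cn=1, frequency=uniform_freq(0.5), name="del"),
            CnvLocus("1", 3_000_001, 3_250_000, cn=3, frequency=uniform_freq(0.5), name="dup"),
        ),
        seed=7,
    )


@pytest.fixture(scope="session")
def noisy_data(noisy_config):
    snp_map = simulate_snp_map(noisy_config)
    cohort, truth = simulate_cohort(noisy_config, snp_map)
    profiles = {
        row.sample_id: render_lrr_baf(row.sample_id, truth, snp_map, noisy_config, batch=row.batch)
        for row in cohort.itertuples(index=False)
    }
    controls = cohort.loc[cohort["gout"] == 0, "sample_id"]
    pfb = compile_pfb([profiles[s] for s in controls])
    return {"map": snp_map, "cohort": cohort, "truth": truth, "profiles": profiles, "pfb": pfb}


@pytest.fixture(scope="session")
def hmm_params():
    return default_params()


def snp_index(snp_map: pd.DataFrame, chromosome: str, position: int) -> int:
    """Index of the SNP at/after a position on a chromosome."""
    sub = snp_map[snp_map["chromosome"] == str(chromosome)].reset_index(drop=True)
    return int(np.searchsorted(sub["position"].to_numpy(), position))
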
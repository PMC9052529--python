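"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations


import pytest

from cordmeth import CohortConfig, generate_cohort, generate_reference_profiles

SMALL_N_CPGS = 1500


@pytest.fixture(scope="session")
def small_reference():
    return generate_reference_profiles(SMALL_N_CPGS, seed=1)


@pytest.fixture(scope="session")
def small_config():
    # sem_rate scaled with the CpG count (defaults assume 20k probes)
    return CohortConfig(n_cpgs=SMALL_N_CPGS, sem_rate=15.0, n_ga_cpgs=60,
                        seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_reference):
    beta, sheet, truth = generate_cohort(small_config, small_reference)
    return beta, sheet, truth


@pytest.fixture(scope="session")
def noiseless_config():
    """All signal injection and noise switched off: beta = reference mixture."""
    return CohortConfig(
        n_cpgs=SMALL_N_CPGS,
        n_effect_cpgs=0,
        n_ga_cpgs=0,
        smoking_effect_dmeth=0.0,
        sem_rate=0.0,
        batch_sd=0.0,
        noise_precision=float("inf"),
        seed=3,
    )


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_config, small_reference):
    return generate_cohort(noiseless_config, small_reference)


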
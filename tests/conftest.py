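"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pytest

import paleoimpute as pi


@pytest.fixture(scope="session")
def small_panel():
    """Two diverged populations, 600 sites on a 40 cM chromosome."""
    return pi.simulate_panel(
        n_pops=2, haps_per_pop=40, n_sites=600, genome_length=2_000_000,
        fst=0.15, ts_fraction=0.687, maf_min=0.01, seed=7, cm_per_mb=20.0,
    )


@pytest.fixture(scope="session")
def one_pop_panel():
    """Single panmictic population, used where structure is irrelevant."""
    return pi.simulate_panel(
        n_pops=1, haps_per_pop=40, n_sites=400, genome_length=1_000_000,
        fst=0.0, seed=11, cm_per_mb=20.0,
    )


@pytest.fixture(scope="session")
def no_damage():
    return pi.DamageModelParams(nick_freq=0.0, deam_ds=0.0, deam_ss=0.0,
                                seq_error=0.0)


@pytest.fixture(scope="session")
def clean_error_only():
    return pi.DamageModelParams(nick_freq=0.0, deam_ds=0.0, deam_ss=0.0,
                                seq_error=0.001)


@pytest.fixture(scope="session")
def target_individual(small_panel):
    return pi.sample_individual(small_panel, "pop0", copy_error=0.005, seed=3)
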
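"""Shared small simulated cohorts, built once per session."""

import numpy as np
import pytest

import popdynh2 as p


@pytest.fixture(scope="session")
def null_cohort():
    """Two generations, no confounding: 400 founders + 200 children."""
    cfg = p.preset_config("null", seed=11, n_founder_couples=200, n_snps=400, n_causal=200)
    return p.simulate_scenario(cfg)


@pytest.fixture(scope="session")
def sib_cohort():
    """Random mating with two offspring per couple (full-sib pairs)."""
    cfg = p.preset_config(
        "null", seed=12, n_founder_couples=150, n_snps=500, n_causal=200,
        offspring_per_couple=2,
    )
    return p.simulate_scenario(cfg)


@pytest.fixture(scope="session")
def strat_cohort():
    """Two subpopulations, fst = 0.05, phenotype means shifted +/- 0.5 SD."""
    cfg = p.preset_config(
        "stratification", seed=13, n_founder_couples=400, n_snps=1000, n_causal=400,
    )
    return p.simulate_scenario(cfg)


@pytest.fixture(scope="session")
def founder_grm(null_cohort):
    rows = np.flatnonzero(null_cohort.generation_mask(0))
    return rows, p.compute_grm(null_cohort.dosages[rows])
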
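"""Shared fixtures: calibrated default model and a reference PSA run."""

from __future__ import annotations

import pytest

import brcascreen as bs

PSA_SEED = 1
PSA_DRAWS = 10_000


@pytest.fixture(scope="session")
def spec():
    """Default configuration with background mortality calibrated."""
    return bs.load_calibrated_spec()


@pytest.fixture(scope="session")
def mean_params(spec):
    return spec.mean_parameter_set()


@pytest.fixture(scope="session")
def base_traces(mean_params):
    comb = bs.run_cohort("combined", mean_params)
    mam = bs.run_cohort("mammography_only", mean_params)
    return comb, mam


@pytest.fixture(scope="session")
def base_summary(base_traces):
    return bs.summarize(*base_traces)


@pytest.fixture(scope="session")
def psa_result(spec):
    """Reference probabilistic sensitivity analysis (10,000 draws)."""
    return bs.run_psa(spec, PSA_DRAWS, seed=PSA_SEED)
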
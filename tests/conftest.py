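"""Shared fixtures: one small synthetic cohort, annotated once per session."""

import pytest

from ptmvar import pipeline
from ptmvar.synthetic import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    return generate_cohort(SimulationConfig(n_proteins=60, seed=1))


@pytest.fixture(scope="session")
def run_config():
    return pipeline.RunConfig(n_bins=30, n_perm=100, seed=1)


@pytest.fixture(scope="session")
def annotated(cohort, run_config):
    """(subs, regions, masks, rejects) of the session cohort."""
    return pipeline.annotate_cohort(cohort, run_config)
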
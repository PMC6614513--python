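"""Shared fixtures: small synthetic datasets built once per session."""

import numpy as np
import pytest

from driftfit import (
    default_scenario,
    generate_design,
    sample_cohort,
    simulate_cohort,
    simulate_subject,
)


@pytest.fixture(scope="session")
def subject_records():
    """One simulated subject (default drift-only scenario, no subject offset)."""
    rng = np.random.default_rng(7)
    scenario = default_scenario(between_subject_sd=0.0)
    subj = sample_cohort(scenario, 1, rng)[0]
    design = generate_design(rng)
    return simulate_subject(design, subj, rng)


@pytest.fixture(scope="session")
def subject_truth():
    rng = np.random.default_rng(7)
    scenario = default_scenario(between_subject_sd=0.0)
    return sample_cohort(scenario, 1, rng)[0]


@pytest.fixture(scope="session")
def cohort10():
    """Ten-subject cohort with default between-subject variability."""
    records, truth = simulate_cohort(default_scenario(), 10, np.random.default_rng(3))
    return records, truth
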
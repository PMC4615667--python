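import numpy as np
import pandas as pd
import pytest

from nodqol import Cohort, SimulationConfig, apply_inclusion, generate_cohort


@pytest.fixture(scope="session")
def sim_additive():
    """A mid-sized synthetic cohort with additive ground truth, shared read-only."""
    config = SimulationConfig(n_persons=20_000, seed=11)
    cohort, truth = generate_cohort(config)
    return apply_inclusion(cohort), truth


@pytest.fixture(scope="session")
def sim_exact():
    """Degenerate generator settings: equal decrements, no noise, no demographics.

    Every person's utility is exactly baseline - 0.025 * NoD, which makes the
    additive model an identity and severity weights exactly 1.
    """
    config = SimulationConfig(
        n_persons=12_000,
        seed=5,
        decrement_shape=0.0,
        noise_sd=0.0,
        age_effect=0.0,
        sex_effect=0.0,
        age_nod_coupling=0.0,
        sex_nod_coupling=0.0,
        code_zipf_exponent=0.0,
    )
    cohort, truth = generate_cohort(config)
    return apply_inclusion(cohort), truth


@pytest.fixture
def tiny_cohort():
    """A handmade six-person cohort exercising V-codes, multiplicity, and zeros."""
    persons = pd.DataFrame(
        {
            "age": [30, 45, 60, 25, 70, 50],
            "sex": [1, 0, 1, 0, 1, 0],
            "eq5d": [0.95, 0.90, 0.80, 1.00, 0.70, 0.85],
            "sf6d": [0.85, 0.82, 0.75, 0.90, 0.65, 0.80],
        },
        index=pd.Index([f"p{i}" for i in range(6)], name="person_id"),
    )
    diagnoses = pd.DataFrame(
        {
            "person_id": ["p0", "p0", "p1", "p1", "p2", "p2", "p2", "p4"],
            "code": ["478", "478", "250", "V70", "001", "250", "478", "v01"],
        }
    )
    return Cohort(persons=persons, diagnoses=diagnoses, label="tiny")
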
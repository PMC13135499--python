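import numpy as np
import pandas as pd
import pytest

from tabsafe.fixtures import (
    FixtureSpec,
    generate_cohort,
    worked_example,
    worked_example_config,
)


@pytest.fixture(scope="session")
def five_patients():
    return worked_example()


@pytest.fixture(scope="session")
def five_patient_config():
    return worked_example_config()


@pytest.fixture(scope="session")
def small_cohort():
    """300-row biobank-like cohort with planted structure."""
    spec = FixtureSpec(n_rows=300, seed=42)
    return generate_cohort(spec), spec.study_config()


@pytest.fixture(scope="session")
def big_cohort():
    """5000-row cohort for Monte-Carlo tolerance checks."""
    spec = FixtureSpec(n_rows=5000, seed=7)
    return generate_cohort(spec), spec.study_config()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
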
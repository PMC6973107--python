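import warnings

import pytest

from smach.constants import default_be_table, default_constants
from smach.synthetic_data import (
    CohortGenConfig,
    LitterGenConfig,
    generate_cohort,
    generate_litters,
)

# statsmodels MixedLM emits convergence chatter on boundary fits; keep test
# output readable without hiding our own warnings
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def constants():
    return default_constants()


@pytest.fixture(scope="session")
def be_table():
    return default_be_table()


@pytest.fixture(scope="session")
def planted_cohort():
    """A 500-subject cohort with a single active component (mbzp)."""
    cfg = CohortGenConfig(
        n_subjects=500, seed=42, true_weights={"mbzp": 1.0}, beta1=-2.5
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_litters():
    return generate_litters(LitterGenConfig(seed=5, dams_per_dose=5))
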
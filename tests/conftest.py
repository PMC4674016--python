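import numpy as np
import pandas as pd
import pytest

from labgrowth import CohortConfig, GrowthParams, TABLE_PARAMS, generate_cohort


@pytest.fixture(scope="session")
def female_params() -> GrowthParams:
    return TABLE_PARAMS["female"]


@pytest.fixture(scope="session")
def male_params() -> GrowthParams:
    return TABLE_PARAMS["male"]


@pytest.fixture(scope="session")
def clean_cohort():
    """Uncontaminated 150-dog cohort with its ground truth."""
    cfg = CohortConfig(n_dogs=150, contamination_probs=(0.0, 1.0, 0.0), seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def contaminated_cohort():
    """200-dog cohort contaminated at the default 5%/90%/5% rates."""
    cfg = CohortConfig(n_dogs=200, seed=12)
    return generate_cohort(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
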
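from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from gfragree.synth import CohortParams, cohort_frame, generate_cohort

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def panel() -> pd.DataFrame:
    """Five-patient formula panel with frozen hand-derived expected values."""
    return pd.read_csv(DATA / "formula_panel.csv")


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A 200-patient synthetic cohort shared by fast tests."""
    return cohort_frame(generate_cohort(CohortParams(n=200, seed=123)))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
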
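from pathlib import Path

import pandas as pd
import pytest

from nephrocast.needs_pipeline import ProjectionTable, run_assessment
from nephrocast.parameters_io import (
    default_age_profiles,
    default_scenario,
    default_transition_table,
)

DATA_DIR = Path(__file__).parent / "data"

STATE_CODES = ["NORMO", "MICRO", "MACRO", "ESRD", "DEATH_CV"]


@pytest.fixture(scope="session")
def table():
    return default_transition_table()


@pytest.fixture(scope="session")
def profiles():
    return default_age_profiles()


@pytest.fixture(scope="session")
def scenario():
    return default_scenario()


@pytest.fixture(scope="session")
def reference_frame() -> pd.DataFrame:
    """Published projection counts and printed share rows (reporting fixture)."""
    df = pd.read_csv(DATA_DIR / "reference_projection.csv", comment="#")
    return df.set_index("year")


@pytest.fixture(scope="session")
def reference_projection(reference_frame) -> ProjectionTable:
    return ProjectionTable(reference_frame[["cohort_size", *STATE_CODES]].astype(float))


@pytest.fixture(scope="session")
def default_run(scenario, profiles, table) -> ProjectionTable:
    """The full default analytic projection, shared across tests."""
    return run_assessment(scenario, profiles, table)
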
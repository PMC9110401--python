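import numpy as np
import pandas as pd
import pytest

from swimquant.scenarios import Scenario
from swimquant.schedule import SessionSpec, make_light_schedule


@pytest.fixture(scope="session")
def track_spec_24() -> SessionSpec:
    return SessionSpec(duration_s=72 * 3600, bin_s=600, plate_format="24-well")


@pytest.fixture(scope="session")
def short_spec() -> SessionSpec:
    """One-day session: cheap simulations with a full light period (d1)."""
    return SessionSpec(duration_s=24 * 3600, bin_s=600, plate_format="24-well")


@pytest.fixture(scope="session")
def short_schedule(short_spec):
    return make_light_schedule(short_spec)


@pytest.fixture
def simple_scenario() -> Scenario:
    return Scenario("wt", day_bout_rate=6.0, bout_displacement_mean_cm=0.4)


@pytest.fixture
def tiny_table() -> pd.DataFrame:
    """Hand-written two-bin tracking table for arithmetic checks."""
    return pd.DataFrame({
        "fish_id": ["f1", "f1"],
        "group_label": ["wt", "wt"],
        "bin_index": [0, 1],
        "bin_start_s": [0.0, 600.0],
        "light_state": ["light", "light"],
        "day_label": ["d1", "d1"],
        "bout_count": [5, 15],
        "distance_cm": [10.0, 20.0],
        "active_duration_s": [1.25, 3.75],
    })


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
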
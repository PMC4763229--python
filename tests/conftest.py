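import numpy as np
import pytest
from hypothesis import settings

from hric import (
    CellTypeProfile,
    Sensor,
    SensorSet,
    SimulationConfig,
    profiles_from_table,
    synthetic_efficiency_table,
)

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def efficiency_table():
    return synthetic_efficiency_table()


@pytest.fixture(scope="session")
def cell_profiles(efficiency_table):
    return {p.name: p for p in profiles_from_table(efficiency_table)}


@pytest.fixture
def control_pair():
    """Two control channels, equal brightness."""
    return SensorSet([Sensor("FL1"), Sensor("FL2")], denominator="FL1")


@pytest.fixture
def knockdown_profile():
    return CellTypeProfile("A", {"m1": 0.5, "m2": 1.0})


def default_config(**overrides) -> SimulationConfig:
    base = dict(n_events=10_000, seed=11)
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture
def config():
    return default_config()
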
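import numpy as np
import pytest

from pchor.energy_model import (
    EnergyTable,
    MechanismState,
    ProtonPosition,
    load_table1,
    load_table2,
    load_table5,
)


@pytest.fixture(scope="session")
def table1() -> EnergyTable:
    return load_table1()


@pytest.fixture(scope="session")
def table2() -> EnergyTable:
    return load_table2()


@pytest.fixture(scope="session")
def table5() -> EnergyTable:
    return load_table5()


def make_state(electrons: int, asp: str, prop: str) -> MechanismState:
    """Shorthand state constructor for tests (enum member names)."""
    return MechanismState(
        electrons, ProtonPosition[asp], ProtonPosition[prop]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240902)
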
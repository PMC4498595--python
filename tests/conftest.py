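"""Shared fixtures: the worked 4-PU x 3-species scenario and fast run configs."""

from pathlib import Path

import pytest

from boombust.datamodel import RunConfig
from boombust.solver import ProblemInstance
from boombust.synthetic import make_fixture, make_phase_fixture

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def fixture_scenario():
    """(PlanningUnitTable, AbundanceTensor) for the worked matrix."""
    return make_fixture()


@pytest.fixture(scope="session")
def phase_scenario():
    """2-year wet/dry variant: A refuge, C breeding, B both, D neither."""
    return make_phase_fixture()


@pytest.fixture()
def instance_p80(fixture_scenario):
    pus, tensor = fixture_scenario
    return ProblemInstance.from_tensor(tensor, pus, "0.8")


@pytest.fixture()
def instance_p10(fixture_scenario):
    pus, tensor = fixture_scenario
    return ProblemInstance.from_tensor(tensor, pus, "0.1")


@pytest.fixture()
def fast_config():
    """A short annealing schedule; plenty for 4-PU problems."""
    return RunConfig(target_fraction="0.8", n_solutions=100, iterations=2000, seed=7)


@pytest.fixture(scope="session")
def marxan_fixture_dir():
    return DATA_DIR / "marxan_fixture"
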
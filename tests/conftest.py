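"""Shared fixtures: the packaged replica, its linked model, and cached
scenario runs (session-scoped — simulations are the expensive part)."""

import pytest

from retisim.model_builder import build_linked_model
from retisim.perturbations import ACUTE, CHRONIC, Scenario
from retisim.scenarios import run_scenario
from retisim.subjects import subject2_replica

SIM_STEP = 0.01  # internal integrator step (days) used throughout the suite


@pytest.fixture(scope="session")
def replica_deck():
    return subject2_replica()


@pytest.fixture(scope="session")
def replica_model(replica_deck):
    return build_linked_model(replica_deck)


@pytest.fixture(scope="session")
def replica_reference(replica_model):
    """Unperturbed 30-day run with the dose at day 0."""
    return replica_model.simulate(30.0, step=SIM_STEP)


@pytest.fixture(scope="session")
def scenario_results(replica_deck, replica_model, replica_reference):
    """All five study scenarios on the replica, keyed by label."""
    scenarios = {
        "steady_state": Scenario(),
        "chronic": Scenario(condition=CHRONIC),
        "acute_day0": Scenario(condition=ACUTE, onset_day=0.0),
        "acute_day3": Scenario(condition=ACUTE, onset_day=3.0),
        "acute_day9": Scenario(condition=ACUTE, onset_day=9.0),
    }
    return {
        label: run_scenario(
            replica_deck,
            scen,
            model=replica_model,
            step=SIM_STEP,
            reference=replica_reference,
        )
        for label, scen in scenarios.items()
    }
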
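import logging

import pytest
from hypothesis import settings

from dielfba import GrowthParams, build_toy_model, run_growth
from dielfba.network import MetabolicNetwork, MetaboliteSpec, ReactionSpec
from dielfba.toy import make_reference_scenarios, make_toy_base

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

logging.getLogger("dielfba").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def toy_base():
    return make_toy_base(seed=0)


@pytest.fixture(scope="session")
def toy_model():
    return build_toy_model(seed=0)


@pytest.fixture(scope="session")
def scenarios():
    return {s.name: s for s in make_reference_scenarios()}


@pytest.fixture(scope="session")
def traj_nlow(toy_model, scenarios):
    return run_growth(toy_model, scenarios["n_low"].params)


@pytest.fixture(scope="session")
def traj_nhigh(toy_model, scenarios):
    return run_growth(toy_model, scenarios["n_high"].params)


def chain_network(uptake_bound: float = 5.0) -> MetabolicNetwork:
    """Linear chain A -> B -> C with bounded uptake and C export objective."""
    mets = [MetaboliteSpec(m) for m in ("A", "B", "C")]
    rxns = [
        ReactionSpec("up", {"A": 1.0}, 0.0, uptake_bound),
        ReactionSpec("a2b", {"A": -1.0, "B": 1.0}, 0.0, 1000.0),
        ReactionSpec("b2c", {"B": -1.0, "C": 1.0}, 0.0, 1000.0),
        ReactionSpec("ex", {"C": -1.0}, 0.0, 1000.0, objective_coefficient=1.0),
    ]
    return MetabolicNetwork(mets, rxns, id="chain")


def parallel_network() -> MetabolicNetwork:
    """Source Z-sink with a 1-step path and an equivalent 3-step path."""
    mets = [MetaboliteSpec(m) for m in ("A", "M1", "M2", "Z")]
    rxns = [
        ReactionSpec("up", {"A": 1.0}, 0.0, 10.0),
        ReactionSpec("short", {"A": -1.0, "Z": 1.0}, 0.0, 1000.0),
        ReactionSpec("long1", {"A": -1.0, "M1": 1.0}, 0.0, 1000.0),
        ReactionSpec("long2", {"M1": -1.0, "M2": 1.0}, 0.0, 1000.0),
        ReactionSpec("long3", {"M2": -1.0, "Z": 1.0}, 0.0, 1000.0),
        ReactionSpec("ex", {"Z": -1.0}, 0.0, 1000.0, objective_coefficient=1.0),
    ]
    return MetabolicNetwork(mets, rxns, id="parallel")


def twin_network() -> MetabolicNetwork:
    """Source Z-sink through two identical (fully redundant) reactions."""
    mets = [MetaboliteSpec(m) for m in ("A", "Z")]
    rxns = [
        ReactionSpec("up", {"A": 1.0}, 0.0, 10.0),
        ReactionSpec("d1", {"A": -1.0, "Z": 1.0}, 0.0, 1000.0),
        ReactionSpec("d2", {"A": -1.0, "Z": 1.0}, 0.0, 1000.0),
        ReactionSpec("ex", {"Z": -1.0}, 0.0, 1000.0, objective_coefficient=1.0),
    ]
    return MetabolicNetwork(mets, rxns, id="twin")
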
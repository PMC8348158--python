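import numpy as np
import pytest

from gemflux.model import MetabolicModel, Metabolite, Reaction
from gemflux.synthetic import make_toy_model


def build_model(reactions, metabolite_ids, objective, compartment="c"):
    model = MetabolicModel(
        id="fixture",
        metabolites=[Metabolite(m, m, compartment) for m in metabolite_ids],
        reactions=reactions,
        objective=objective,
        compartments={compartment: compartment},
    )
    model.validate()
    return model


@pytest.fixture
def chain_model():
    """EX_a -> A -> B -> EX_b with the uptake capped at 10."""
    return build_model(
        [
            Reaction("EX_a", {"A": 1}, 0, 10),
            Reaction("R1", {"A": -1, "B": 1}, 0, 1000),
            Reaction("EX_b", {"B": -1}, 0, 1000),
        ],
        ["A", "B"],
        {"EX_b": 1.0},
    )


@pytest.fixture
def parallel_model():
    """A -> B directly or via a two-reaction detour through C."""
    return build_model(
        [
            Reaction("EX_a", {"A": 1}, 0, 10),
            Reaction("R1", {"A": -1, "B": 1}, 0, 1000),
            Reaction("D1", {"A": -1, "C": 1}, 0, 1000),
            Reaction("D2", {"C": -1, "B": 1}, 0, 1000),
            Reaction("EX_b", {"B": -1}, 0, 1000),
        ],
        ["A", "B", "C"],
        {"EX_b": 1.0},
    )


@pytest.fixture(scope="session")
def toy_model_session():
    return make_toy_model()


@pytest.fixture
def toy_model(toy_model_session):
    return toy_model_session.copy()
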
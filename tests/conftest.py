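import pytest
from hypothesis import settings

from fluxshift.metnet import MetabolicModel, Metabolite, Reaction

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from fluxshift.solvers import FluxDistribution, solve_fba
from fluxshift.synthdata import toy_ketone_model


@pytest.fixture
def chain_model() -> MetabolicModel:
    """Linear chain →A→B→ with uptake capped at 10; FBA optimum is 10."""
    return MetabolicModel(
        id="chain",
        metabolites=(Metabolite("A"), Metabolite("B")),
        reactions=(
            Reaction("R_up", {"A": 1}, 0, 10),
            Reaction("R_conv", {"A": -1, "B": 1}, 0, 1000),
            Reaction("R_out", {"B": -1}, 0, 1000),
        ),
        objective={"R_out": 1.0},
    )


@pytest.fixture
def diamond_model() -> MetabolicModel:
    """Two parallel A→B routes; knocking one out forces rerouting."""
    return MetabolicModel(
        id="diamond",
        metabolites=(Metabolite("A"), Metabolite("B")),
        reactions=(
            Reaction("R_in", {"A": 1}, 0, 20),
            Reaction("R1", {"A": -1, "B": 1}, 0, 20),
            Reaction("R2", {"A": -1, "B": 1}, 0, 20),
            Reaction("R_out", {"B": -1}, 0, 20),
        ),
        objective={"R_out": 1.0},
    )


@pytest.fixture
def diamond_reference(diamond_model) -> FluxDistribution:
    """Balanced 5/5 split of 10 units across the two routes."""
    return FluxDistribution(
        model_id=diamond_model.id,
        fluxes={"R_in": 10.0, "R1": 5.0, "R2": 5.0, "R_out": 10.0},
        status="optimal",
        objective_value=10.0,
    )


@pytest.fixture(scope="session")
def toy_model() -> MetabolicModel:
    return toy_ketone_model()


@pytest.fixture(scope="session")
def toy_wild_type(toy_model) -> FluxDistribution:
    return solve_fba(toy_model)
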
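import pytest

from metoncokit.network_model import MetabolicModel, Metabolite, Reaction
from metoncokit.synthetic_fixtures import FixtureSpec, generate_toy_model


def make_chain_model() -> MetabolicModel:
    """EX → A → B → C → D → biomass, all irreversible, capacity 10."""
    mets = {m: Metabolite(m, compartment="c") for m in "ABCD"}
    reactions = {
        "EX_A": Reaction("EX_A", {}, {"A": 1.0}, 0, 10, "Exchange"),
        "R_AB": Reaction("R_AB", {"A": 1.0}, {"B": 1.0}, 0, 1000, "core", "g1"),
        "R_BC": Reaction("R_BC", {"B": 1.0}, {"C": 1.0}, 0, 1000, "core", "g2"),
        "R_CD": Reaction("R_CD", {"C": 1.0}, {"D": 1.0}, 0, 1000, "core", "g3"),
        "BIOMASS": Reaction("BIOMASS", {"D": 1.0}, {}, 0, 1000, "Biomass"),
    }
    return MetabolicModel(
        metabolites=mets,
        reactions=reactions,
        genes={"g1", "g2", "g3"},
        biomass_reaction_id="BIOMASS",
        biomass_components=["D"],
        media_components=["A"],
    )


def make_parallel_model() -> MetabolicModel:
    """A reaches B by a 1-step route (g_short) or a 2-step route (g_long)."""
    mets = {m: Metabolite(m, compartment="c") for m in "ABX"}
    reactions = {
        "EX_A": Reaction("EX_A", {}, {"A": 1.0}, 0, 10, "Exchange"),
        "SHORT": Reaction("SHORT", {"A": 1.0}, {"B": 1.0}, 0, 1000, "core", "g_short"),
        "LONG1": Reaction("LONG1", {"A": 1.0}, {"X": 1.0}, 0, 1000, "core", "g_long"),
        "LONG2": Reaction("LONG2", {"X": 1.0}, {"B": 1.0}, 0, 1000, "core", "g_long"),
        "BIOMASS": Reaction("BIOMASS", {"B": 1.0}, {}, 0, 1000, "Biomass"),
    }
    return MetabolicModel(
        metabolites=mets,
        reactions=reactions,
        genes={"g_short", "g_long"},
        biomass_reaction_id="BIOMASS",
        biomass_components=["B"],
        media_components=["A"],
    )


@pytest.fixture
def chain_model() -> MetabolicModel:
    return make_chain_model()


@pytest.fixture
def parallel_model() -> MetabolicModel:
    return make_parallel_model()


@pytest.fixture(scope="session")
def toy_spec() -> FixtureSpec:
    return FixtureSpec(seed=7, signal_features=("expression",))


@pytest.fixture(scope="session")
def toy_model(toy_spec):
    return generate_toy_model(toy_spec)
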
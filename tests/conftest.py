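import pytest

from holoflux.environment import (MediumSpec, build_seawater_medium,
                                  medium_uptake_bounds)
from holoflux.netcore import MetabolicModel, Metabolite, Reaction
from holoflux.symbiont_models import (build_autotroph_model,
                                      build_heterotroph_model)


@pytest.fixture(scope="session")
def autotroph():
    return build_autotroph_model()


@pytest.fixture(scope="session")
def heterotroph():
    return build_heterotroph_model()


@pytest.fixture(scope="session")
def seawater():
    return build_seawater_medium()


@pytest.fixture(scope="session")
def seawater_uptake(seawater):
    return medium_uptake_bounds(seawater)


@pytest.fixture(scope="session")
def seawater_uptake_with_b12(seawater_uptake):
    return {**seawater_uptake, "b12_e": 1.0}


def make_chain_model(yield_coef=1.0, demand=1.0):
    """EX_A -> (transport) -> A -> B -> biomass; hand-checkable backbone."""
    mets = [
        Metabolite("A_e", compartment="extracellular"),
        Metabolite("A", compartment="cytosol"),
        Metabolite("B", compartment="cytosol"),
    ]
    rxns = [
        Reaction("EX_A", stoichiometry={"A_e": -1.0},
                 lower_bound=-1000.0, upper_bound=1000.0, kind="exchange"),
        Reaction("T_A", stoichiometry={"A_e": -1.0, "A": 1.0},
                 lower_bound=0.0, upper_bound=1000.0, kind="transport"),
        Reaction("R1", stoichiometry={"A": -1.0, "B": yield_coef},
                 lower_bound=0.0, upper_bound=1000.0, kind="internal",
                 evidence="synthetic conversion"),
        Reaction("BIOMASS", stoichiometry={"B": -demand},
                 lower_bound=0.0, upper_bound=1000.0, kind="biomass"),
    ]
    return MetabolicModel("chain", mets, rxns, "BIOMASS",
                          biomass_composition={"A_e": 1.0})


@pytest.fixture
def chain_model():
    return make_chain_model()
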
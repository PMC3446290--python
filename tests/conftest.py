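import pytest

from strainflux.models import (
    Compartment,
    GrowthCondition,
    Metabolite,
    MetabolicModel,
    Reaction,
)
from strainflux.synthetic_data import table1_fixture


def make_linear_chain(uptake_cap: float = 1000.0) -> MetabolicModel:
    """EX_A(e) -> transport -> biomass with unit stoichiometry."""
    return MetabolicModel(
        id="chain",
        metabolites=[
            Metabolite(id="A_e", compartment=Compartment.EXTRACELLULAR),
            Metabolite(id="A_c", compartment=Compartment.CYTOSOL),
        ],
        reactions=[
            Reaction(
                id="EX_A(e)",
                stoichiometry={"A_e": -1.0},
                lower_bound=-uptake_cap,
                upper_bound=1000.0,
                is_exchange=True,
            ),
            Reaction(
                id="T_A",
                stoichiometry={"A_e": -1.0, "A_c": 1.0},
                lower_bound=0.0,
                upper_bound=1000.0,
            ),
            Reaction(
                id="BIOMASS",
                stoichiometry={"A_c": -1.0},
                lower_bound=0.0,
                upper_bound=1000.0,
            ),
        ],
        objective_id="BIOMASS",
    )


@pytest.fixture
def chain_model() -> MetabolicModel:
    return make_linear_chain()


@pytest.fixture
def chain_condition() -> GrowthCondition:
    return GrowthCondition(
        name="A", substrate_exchange_id="EX_A(e)", substrate_uptake=8.0,
        oxygen_uptake=0.0,
    )


@pytest.fixture(scope="session")
def table1():
    """(target, reference, delta, conditions, pm_table) toy encoding of the
    ten differential carbon-source phenotypes."""
    return table1_fixture()
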
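import pytest

from aneofba.core import BIG, MetabolicModel, Metabolite, Reaction
from aneofba.network import ModelConfig, build_core_model, disable_growth


@pytest.fixture
def core_model():
    """Calibrated proton-coupled core model (fresh copy per test)."""
    return build_core_model()


@pytest.fixture
def decoupled_model():
    """Energy-decoupled, branch-free model for theoretical stoichiometry."""
    model = build_core_model(ModelConfig(
        energy_decoupled=True, propanol_cap=0.0, butyrate_cap=0.0, ngam=0.0))
    return disable_growth(model)


def make_chain_model(cap: float = 10.0) -> MetabolicModel:
    """EX_A (uptake <= cap) -> A -> B -> EX_B, a single forced path."""
    m = MetabolicModel(id="chain", compartments=("c0", "e0"))
    for mid, comp in [("A_e0", "e0"), ("A_c0", "c0"),
                      ("B_c0", "c0"), ("B_e0", "e0")]:
        m.add_metabolite(Metabolite(mid, formula="C1", compartment=comp))
    m.add_reaction(Reaction("EX_A_e0", stoichiometry={"A_e0": -1},
                            lower_bound=-cap, upper_bound=0, kind="exchange"))
    m.add_reaction(Reaction("T_A", stoichiometry={"A_e0": -1, "A_c0": 1},
                            lower_bound=0, upper_bound=BIG, kind="transport"))
    m.add_reaction(Reaction("R_AB", stoichiometry={"A_c0": -1, "B_c0": 1},
                            lower_bound=0, upper_bound=BIG))
    m.add_reaction(Reaction("T_B", stoichiometry={"B_c0": -1, "B_e0": 1},
                            lower_bound=0, upper_bound=BIG, kind="transport"))
    m.add_reaction(Reaction("EX_B_e0", stoichiometry={"B_e0": -1},
                            lower_bound=0, upper_bound=BIG, kind="exchange"))
    m.objective_id = "EX_B_e0"
    return m


@pytest.fixture
def chain_model():
    return make_chain_model()
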
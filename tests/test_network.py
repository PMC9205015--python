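"""Core-model construction, biomass reaction, conservation laws, model I/O."""

import numpy as np
import pytest

from aneofba.core import (BIG, set_exchange_bounds, solve_fba, validate_model)
from aneofba.io import SBMLParseError, read_json, read_sbml, write_json, \
    write_sbml
from aneofba.network import (BiomassComposition, ModelConfig,
                             build_biomass_reaction, build_core_model,
                             default_composition, disable_growth,
                             open_fermentation_products, precursor_demands,
                             seal_exchanges)


PAPER_REACTION_IDS = [
    "rxn00543_c0", "rxn00171_c0", "rxn00173_c0", "rxn00225_c0",
    "rxn05938_c0", "rxn00500_c0", "rxn01056_c0", "rxn02123_c0",
    "rxn40050_c0", "rxn10042_c0", "Rnf_c0", "rxn09944_c0", "rxn01710_c0",
    "rxn00178_c0", "rxn03861_c0", "rxn03874_c0", "rxn00868_c0",
    "rxn00875_c0", "rxn00062_c0", "rxn05759_c0",
]


def _ethanol_state(model, uptake=36.2):
    seal_exchanges(model)
    open_fermentation_products(model)
    set_exchange_bounds(model, "etoh", -uptake, -uptake)
    return solve_fba(model)


def test_core_model_contains_annotated_reactions(core_model):
    for rid in PAPER_REACTION_IDS:
        assert rid in core_model.reactions


def test_hydrogenase_blocked_by_default(core_model):
    assert core_model.reactions["rxn05759_c0"].bounds == (0.0, 0.0)
    state = _ethanol_state(core_model)
    assert state.optimal
    assert abs(state.fluxes["rxn05759_c0"]) < 1e-12


def test_elemental_and_charge_balance_outside_lumped_set(core_model):
    report = validate_model(core_model)
    assert report.elemental_imbalances == {}
    assert report.charge_imbalances == {}
    assert not report.dangling_references
    assert "biomass_c0" in report.skipped


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(coupling_ratio=0)
    with pytest.raises(ValueError):
        ModelConfig(gam=-1)
    with pytest.raises(ValueError):
        ModelConfig(propanol_cap=-0.1)


# ---------------------------------------------------------------------------
# biomass reaction
# ---------------------------------------------------------------------------

def test_biomass_atp_coefficient_is_gam_plus_polymerisation():
    comp = default_composition(gam=40.0)
    polymerisation = precursor_demands(comp)["atp"]
    rxn = build_biomass_reaction(comp)
    assert -rxn.stoichiometry["atp_c0"] == pytest.approx(
        40.0 + polymerisation, abs=1e-9)
    rxn0 = build_biomass_reaction(default_composition(gam=0.0))
    assert -rxn0.stoichiometry["atp_c0"] == pytest.approx(
        polymerisation, abs=1e-9)


def test_biomass_reaction_identity_under_identity_scaling():
    comp = default_composition()
    assert build_biomass_reaction(comp).stoichiometry == \
        build_biomass_reaction(comp).stoichiometry


def test_biomass_fractions_must_close():
    with pytest.raises(ValueError):
        build_biomass_reaction(BiomassComposition(protein=0.9))


# ---------------------------------------------------------------------------
# conservation laws
# ---------------------------------------------------------------------------

def test_proton_gradient_closure(core_model):
    """The periplasmic pseudo-proton couples only Rnf and the ATPase, so
    2 v_Rnf = coupling_ratio * v_ATPase in every steady state."""
    touching = [r.id for r in core_model.reactions.values()
                if "h_p_c0" in r.stoichiometry]
    assert sorted(touching) == ["Rnf_c0", "rxn10042_c0"]
    state = _ethanol_state(core_model)
    assert 2 * state.fluxes["Rnf_c0"] == pytest.approx(
        3.5 * state.fluxes["rxn10042_c0"], abs=1e-8)


def test_redox_closure_forces_two_to_one():
    """Branches closed, biomass and NGAM off: NADH balance forces
    propionate = 2 * acetate in any feasible state, coupled or not."""
    for decoupled in (False, True):
        model = build_core_model(ModelConfig(
            energy_decoupled=decoupled, propanol_cap=0.0, butyrate_cap=0.0,
            ngam=0.0))
        disable_growth(model)
        seal_exchanges(model)
        open_fermentation_products(model)
        set_exchange_bounds(model, "etoh", -30.0, -30.0)
        for objective in ("EX_ppa_e0", "EX_ac_e0"):
            model.objective_id = objective
            state = solve_fba(model)
            assert state.optimal, f"{objective} decoupled={decoupled}"
            assert state.fluxes["EX_ppa_e0"] == pytest.approx(
                2.0 * state.fluxes["EX_ac_e0"], abs=1e-6)


def test_no_free_energy_with_exchanges_closed():
    for decoupled in (False, True):
        model = build_core_model(ModelConfig(
            energy_decoupled=decoupled, ngam=0.0))
        seal_exchanges(model)
        model.objective_id = "rxn00062_c0"
        state = solve_fba(model)
        assert state.optimal
        assert state.objective_value == pytest.approx(0.0, abs=1e-9)


def test_carbon_conservation_without_growth():
    model = build_core_model(ModelConfig(ngam=0.0))
    disable_growth(model)
    seal_exchanges(model)
    open_fermentation_products(model)
    set_exchange_bounds(model, "etoh", -30.0, -30.0)
    model.objective_id = "EX_ppa_e0"
    state = solve_fba(model)
    carbons = {"etoh": 2, "ac": 2, "ppa": 3, "poh": 3, "but": 4,
               "lac__D": 3, "pyr": 3, "co2": 1}
    net = sum(state.fluxes[f"EX_{sp}_e0"] * nc for sp, nc in carbons.items())
    assert net == pytest.approx(0.0, abs=1e-8)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _models_equal(a, b) -> bool:
    if set(a.reactions) != set(b.reactions):
        return False
    if set(a.metabolites) != set(b.metabolites):
        return False
    for rid, rxn in a.reactions.items():
        other = b.reactions[rid]
        if (rxn.stoichiometry != other.stoichiometry
                or rxn.bounds != other.bounds
                or rxn.gene_rule != other.gene_rule
                or rxn.kind != other.kind):
            return False
    for mid, met in a.metabolites.items():
        other = b.metabolites[mid]
        if met.formula != other.formula or met.charge != other.charge:
            return False
    return a.objective_id == b.objective_id


@pytest.mark.parametrize("writer,reader,suffix", [
    (write_sbml, read_sbml, "xml"),
    (write_json, read_json, "json"),
])
def test_model_roundtrip(core_model, tmp_path, writer, reader, suffix):
    path = tmp_path / f"core.{suffix}"
    writer(core_model, path)
    assert _models_equal(core_model, reader(path))


def test_sbml_and_json_writes_agree(core_model, tmp_path):
    write_sbml(core_model, tmp_path / "m.xml")
    write_json(core_model, tmp_path / "m.json")
    assert _models_equal(read_sbml(tmp_path / "m.xml"),
                         read_json(tmp_path / "m.json"))


def test_malformed_sbml_raises_with_location(tmp_path):
    bad = tmp_path / "bad.xml"
    bad.write_text("<sbml xmlns='http://www.sbml.org/sbml/level3/version1/core'"
                   " level='3' version='1'><model><oops></model></sbml>")
    with pytest.raises(SBMLParseError, match="line"):
        read_sbml(bad)


_MINI_FBC = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core"
      xmlns:fbc="http://www.sbml.org/sbml/level3/version1/fbc/version2"
      level="3" version="1" fbc:required="false">
  <model id="mini" fbc:strict="true">
    <listOfCompartments>
      <compartment id="c0" constant="true"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="m1" compartment="c0" hasOnlySubstanceUnits="false"
               boundaryCondition="false" constant="false"
               fbc:charge="-1" fbc:chemicalFormula="C3H5O3"/>
      <species id="m2" compartment="c0" hasOnlySubstanceUnits="false"
               boundaryCondition="false" constant="false"/>
    </listOfSpecies>
    <listOfParameters>
      <parameter id="lb" value="-10" constant="true"/>
      <parameter id="ub" value="10" constant="true"/>
    </listOfParameters>
    <listOfReactions>
      <reaction id="r1" reversible="true" fast="false"
                fbc:lowerFluxBound="lb" fbc:upperFluxBound="ub">
        <listOfReactants>
          <speciesReference species="m1" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="m2" stoichiometry="2" constant="true"/>
        </listOfProducts>
      </reaction>
      <reaction id="EX_m2" reversible="false" fast="false"
                fbc:lowerFluxBound="lb" fbc:upperFluxBound="ub">
        <listOfReactants>
          <speciesReference species="m2" stoichiometry="1" constant="true"/>
        </listOfReactants>
      </reaction>
    </listOfReactions>
    <fbc:listOfObjectives fbc:activeObjective="obj">
      <fbc:objective fbc:id="obj" fbc:type="maximize">
        <fbc:listOfFluxObjectives>
          <fbc:fluxObjective fbc:reaction="EX_m2" fbc:coefficient="1"/>
        </fbc:listOfFluxObjectives>
      </fbc:objective>
    </fbc:listOfObjectives>
  </model>
</sbml>
"""


def test_reads_external_fbc_sbml(tmp_path):
    """Parses a minimal synthetic fbc document not written by this package."""
    path = tmp_path / "mini.xml"
    path.write_text(_MINI_FBC)
    model = read_sbml(path)
    assert model.reactions["r1"].stoichiometry == {"m1": -1.0, "m2": 2.0}
    assert model.reactions["r1"].bounds == (-10.0, 10.0)
    assert model.metabolites["m1"].formula == "C3H5O3"
    assert model.metabolites["m1"].charge == -1
    assert model.reactions["EX_m2"].kind == "exchange"
    assert model.objective_id == "EX_m2"
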
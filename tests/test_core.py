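"""Solver-layer tests: FBA, FVA, sampling, audit, bound editing."""

import itertools

import numpy as np
import pytest

from aneofba.core import (BIG, MetabolicModel, Metabolite, ModelValidationError,
                          Reaction, blocked_reactions, flux_variability,
                          sample_fluxes, set_exchange_bounds, solve_fba,
                          stoichiometric_matrix, validate_model)
from aneofba.network import (ModelConfig, build_core_model,
                             open_fermentation_products, seal_exchanges)

from conftest import make_chain_model


# ---------------------------------------------------------------------------
# FBA basics
# ---------------------------------------------------------------------------

def test_forced_chain_objective(chain_model):
    state = solve_fba(chain_model)
    assert state.optimal
    assert state.objective_value == pytest.approx(10.0, abs=1e-9)
    assert state.fluxes["R_AB"] == pytest.approx(10.0, abs=1e-9)


def test_atp_demand_without_source_is_infeasible(core_model):
    seal_exchanges(core_model)  # NGAM lower bound 8.4 with nothing to eat
    state = solve_fba(core_model)
    assert state.status == "infeasible"


def test_dangling_metabolite_is_validation_error(chain_model):
    chain_model.reactions["R_AB"].stoichiometry["ghost_c0"] = 1.0
    with pytest.raises(ModelValidationError):
        solve_fba(chain_model)


def test_steady_state_residual(core_model):
    seal_exchanges(core_model)
    open_fermentation_products(core_model)
    set_exchange_bounds(core_model, "etoh", -36.2, -36.2)
    state = solve_fba(core_model)
    S, _, rxn_ids = stoichiometric_matrix(core_model)
    v = np.array([state.fluxes[r] for r in rxn_ids])
    assert np.abs(S @ v).max() <= 1e-9
    for rid in rxn_ids:
        rxn = core_model.reactions[rid]
        assert rxn.lower_bound - 1e-9 <= state.fluxes[rid] <= rxn.upper_bound + 1e-9


def _brute_force_optimum(model: MetabolicModel) -> float:
    """Vertex enumeration over basic solutions of {Sv=0, l<=v<=u}."""
    S, _, rxn_ids = stoichiometric_matrix(model)
    S = S[np.abs(S).sum(axis=1) > 0]  # drop empty rows
    m, n = S.shape
    rank = np.linalg.matrix_rank(S)
    lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    c = np.zeros(n)
    c[rxn_ids.index(model.objective_id)] = 1.0
    best = -np.inf
    nonbasic = n - rank
    for fixed in itertools.combinations(range(n), nonbasic):
        free = [j for j in range(n) if j not in fixed]
        for values in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            rhs = -S[:, list(fixed)] @ np.array(values)
            sol, *_ = np.linalg.lstsq(S[:, free], rhs, rcond=None)
            v = np.zeros(n)
            v[list(fixed)] = values
            v[free] = sol
            if (np.abs(S @ v).max() < 1e-8 and (v >= lb - 1e-8).all()
                    and (v <= ub + 1e-8).all()):
                best = max(best, c @ v)
    return best


def test_fba_matches_vertex_enumeration_on_small_networks(chain_model):
    branched = make_chain_model()
    branched.add_reaction(Reaction(
        "R_AB2", stoichiometry={"A_c0": -1, "B_c0": 1},
        lower_bound=0, upper_bound=4))
    for model in (chain_model, branched):
        lp = solve_fba(model).objective_value
        brute = _brute_force_optimum(model)
        assert lp == pytest.approx(brute, abs=1e-6)


# ---------------------------------------------------------------------------
# FVA and blocked reactions
# ---------------------------------------------------------------------------

def test_fva_forced_path_ranges(chain_model):
    fr = flux_variability(chain_model, fraction_of_optimum=1.0)
    for rid in ("EX_A_e0", "T_A", "R_AB", "T_B", "EX_B_e0"):
        lo, hi = fr.ranges[rid]
        assert abs(abs(lo) - 10.0) < 1e-8 and abs(abs(hi) - 10.0) < 1e-8


def test_fva_zero_bounds_reported_blocked(chain_model):
    chain_model.add_metabolite(Metabolite("C_c0", compartment="c0"))
    chain_model.add_reaction(Reaction(
        "R_dead", stoichiometry={"B_c0": -1, "C_c0": 1},
        lower_bound=0, upper_bound=0))
    chain_model.add_reaction(Reaction(
        "DM_C", stoichiometry={"C_c0": -1}, lower_bound=0, upper_bound=BIG))
    fr = flux_variability(chain_model, fraction_of_optimum=0.0)
    assert {"R_dead", "DM_C"} <= blocked_reactions(fr)


def test_blocked_set_matches_cobra_oracle(core_model):
    """Blocked detection agrees with an independent FVA implementation."""
    cobra = pytest.importorskip("cobra")
    from cobra.flux_analysis import flux_variability_analysis

    seal_exchanges(core_model)
    open_fermentation_products(core_model)
    set_exchange_bounds(core_model, "etoh", -36.2, 0.0)
    fr = flux_variability(core_model, fraction_of_optimum=0.0)
    ours = blocked_reactions(fr)

    cm = cobra.Model("oracle")
    mets = {mid: cobra.Metabolite(mid) for mid in core_model.metabolites}
    for rxn in core_model.reactions.values():
        cr = cobra.Reaction(rxn.id)
        cr.bounds = (rxn.lower_bound, rxn.upper_bound)
        cm.add_reactions([cr])
        cr.add_metabolites({mets[m]: c for m, c in rxn.stoichiometry.items()})
    fva = flux_variability_analysis(cm, fraction_of_optimum=0.0,
                                    processes=1)
    theirs = set(fva.index[(fva["minimum"].abs() < 1e-9)
                           & (fva["maximum"].abs() < 1e-9)])
    assert ours == theirs


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def test_sampling_point_polytope_is_deterministic(chain_model):
    res = sample_fluxes(chain_model, n=50, growth_fraction=1.0, seed=1)
    assert res.mean["R_AB"] == pytest.approx(10.0, abs=1e-6)
    assert res.std["R_AB"] == pytest.approx(0.0, abs=1e-6)


def test_sampling_same_seed_identical(core_model):
    seal_exchanges(core_model)
    open_fermentation_products(core_model)
    set_exchange_bounds(core_model, "etoh", -36.2, -36.2)
    a = sample_fluxes(core_model, n=100, growth_fraction=0.99, seed=42)
    b = sample_fluxes(core_model, n=100, growth_fraction=0.99, seed=42)
    assert a.mean == b.mean and a.std == b.std


def test_sampling_means_within_fva_ranges(core_model):
    seal_exchanges(core_model)
    open_fermentation_products(core_model)
    set_exchange_bounds(core_model, "etoh", -36.2, -36.2)
    res = sample_fluxes(core_model, n=300, growth_fraction=0.99, seed=7)
    fr = flux_variability(core_model, fraction_of_optimum=0.99)
    for rid, mean in res.mean.items():
        lo, hi = fr.ranges[rid]
        assert lo - 1e-6 <= mean <= hi + 1e-6


def test_sampling_never_beats_fba_objective(core_model):
    seal_exchanges(core_model)
    open_fermentation_products(core_model)
    set_exchange_bounds(core_model, "etoh", -36.2, -36.2)
    opt = solve_fba(core_model).objective_value
    res = sample_fluxes(core_model, n=200, growth_fraction=0.95, seed=3,
                        keep_samples=True)
    j = res.reaction_ids.index("biomass_c0")
    assert (res.samples[:, j] <= opt + 1e-6).all()


# ---------------------------------------------------------------------------
# audit and editing
# ---------------------------------------------------------------------------

def test_validate_model_reports_h_imbalance():
    m = MetabolicModel(compartments=("c0",))
    m.add_metabolite(Metabolite("a_c0", formula="C2H6O", compartment="c0"))
    m.add_metabolite(Metabolite("b_c0", formula="C2H4O", compartment="c0"))
    m.add_reaction(Reaction("bad", stoichiometry={"a_c0": -1, "b_c0": 1}))
    report = validate_model(m)
    assert report.elemental_imbalances["bad"]["H"] == pytest.approx(-2)


def test_validate_model_empty_model_clean():
    assert validate_model(MetabolicModel()).clean


def test_exchange_bound_editing(core_model):
    set_exchange_bounds(core_model, "etoh", -30.0, 0.0)
    assert core_model.reactions["EX_etoh_e0"].bounds == (-30.0, 0.0)
    with pytest.raises(ModelValidationError):
        set_exchange_bounds(core_model, "etoh", 5.0, -5.0)
    with pytest.raises(KeyError):
        set_exchange_bounds(core_model, "glucose", -10, 0)


def test_sealed_species_excluded_from_carbon_flow(core_model):
    seal_exchanges(core_model)
    open_fermentation_products(core_model)
    set_exchange_bounds(core_model, "etoh", -36.2, -36.2)
    set_exchange_bounds(core_model, "lac__D", 0.0, 0.0)  # seal lactate
    state = solve_fba(core_model)
    assert state.optimal
    assert abs(state.fluxes["EX_lac__D_e0"]) < 1e-9
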
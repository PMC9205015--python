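"""Energetic analysis of ethanol fermentation.

Quantifies why the theoretical 2:1 propionate:acetate stoichiometry

    3 CH3CH2OH + 2 CO2 -> 2 CH3CH2COO- + CH3COO- + 3 H+ + H2O

is not achievable by a growing cell: reduced ferredoxin for the CO2-fixing
PFOR must be bought with ATP through the reverse Rnf / V-ATPase couple, so
net ATP for growth requires extra acetate (extra substrate-level
phosphorylation) and the realised ratio falls below 2.

The thermodynamic bound |dG_ATP| / |dG_Fd<-NADH| = 32/25 ~ 1.3 mol Fd per
mol ATP sets the scale of that trade-off independently of the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .core import BIG, FluxState, InfeasibleError, MetabolicModel, \
    set_exchange_bounds, solve_fba
from .network import (ModelConfig, build_core_model, disable_growth,
                      open_fermentation_products, seal_exchanges)

__all__ = [
    "ThermoConstants",
    "RatioResult",
    "fd_per_atp",
    "theoretical_max_ratio",
    "predicted_ratio",
    "coupling_sweep",
    "atp_accounting",
]


@dataclass
class ThermoConstants:
    """Standard free energies used in the energetic argument (kJ mol^-1).

    ``dg_overall`` (per 3 mol ethanol fermented) is carried for reporting
    only; it is a literature value, not recomputed here.
    """

    dg_atp: float = -32.0
    dg_fd_nadh: float = -25.0
    dg_overall: float = -124.0


@dataclass
class RatioResult:
    """Secretion fluxes and propionate:acetate ratio at a solved state."""

    v_propionate: float
    v_acetate: float
    v_propanol: float
    v_butyrate: float
    mu: float
    atp_sources: dict[str, float] = field(default_factory=dict)

    @property
    def ratio(self) -> float:
        if self.v_acetate <= 1e-9:
            raise ZeroDivisionError(
                "ratio undefined: acetate secretion is numerically zero")
        return self.v_propionate / self.v_acetate


def fd_per_atp(constants: ThermoConstants | None = None) -> float:
    """Moles of ferredoxin reducible with NADH per mole of ATP hydrolysed."""
    c = constants or ThermoConstants()
    if c.dg_fd_nadh == 0:
        raise ZeroDivisionError("dg_fd_nadh must be non-zero")
    return abs(c.dg_atp) / abs(c.dg_fd_nadh)


def _ethanol_condition(model: MetabolicModel, uptake: float) -> MetabolicModel:
    work = model.copy()
    seal_exchanges(work)
    open_fermentation_products(work)
    set_exchange_bounds(work, "etoh", -uptake, -uptake)
    return work


def theoretical_max_ratio(model: MetabolicModel | None = None,
                          uptake: float = 3.0) -> RatioResult:
    """Max-propionate FBA on the energy-decoupled, branch-free network.

    With uncoupled ferredoxin reduction, closed minor branches and biomass
    and maintenance off, the NADH balance forces exactly two propionate per
    acetate; at an ethanol uptake of 3 the absolute fluxes are 2 and 1.
    """
    if model is None:
        model = build_core_model(ModelConfig(
            energy_decoupled=True, propanol_cap=0.0, butyrate_cap=0.0,
            ngam=0.0))
        disable_growth(model)
    work = _ethanol_condition(model, uptake)
    work.objective_id = "EX_ppa_e0"
    state = solve_fba(work)
    if not state.optimal:
        raise InfeasibleError(
            f"decoupled max-propionate problem is {state.status}")
    return RatioResult(
        v_propionate=state.fluxes["EX_ppa_e0"],
        v_acetate=state.fluxes["EX_ac_e0"],
        v_propanol=state.fluxes["EX_poh_e0"],
        v_butyrate=state.fluxes["EX_but_e0"],
        mu=state.fluxes["biomass_c0"],
    )


def predicted_ratio(model: MetabolicModel | None = None,
                    config: ModelConfig | None = None,
                    uptake: float | None = None) -> RatioResult:
    """Growth-maximised secretion ratio on the proton-coupled model.

    Ethanol uptake is fixed (default: the reference uptake of the config);
    the reported fluxes come from a lexicographic solve (maximum growth,
    then minimum total flux) so the ratio is robust to alternate optima.
    """
    cfg = config or ModelConfig()
    if model is None:
        model = build_core_model(cfg)
    work = _ethanol_condition(
        model, uptake if uptake is not None else cfg.reference_uptake)
    state = solve_fba(work, minimize_total_flux=True)
    if not state.optimal:
        raise InfeasibleError(
            "growth-maximised problem is infeasible: with the chemiosmotic "
            "Rnf/ATPase couple the ATP balance (acetate kinase SLP minus the "
            "ferredoxin-reduction cost minus maintenance) cannot close")
    return RatioResult(
        v_propionate=state.fluxes["EX_ppa_e0"],
        v_acetate=state.fluxes["EX_ac_e0"],
        v_propanol=state.fluxes["EX_poh_e0"],
        v_butyrate=state.fluxes["EX_but_e0"],
        mu=state.fluxes["biomass_c0"],
        atp_sources=atp_accounting(state, work),
    )


def coupling_sweep(n_values, config: ModelConfig | None = None,
                   uptake: float | None = None) -> pd.DataFrame:
    """Growth, ratio and ATP partition across ATPase coupling ratios."""
    base = config or ModelConfig()
    rows = []
    for n in n_values:
        if n <= 0:
            raise ValueError("coupling ratios must be positive")
        cfg = replace(base, coupling_ratio=float(n))
        row = {"coupling_ratio": float(n)}
        try:
            res = predicted_ratio(config=cfg, uptake=uptake)
            row.update(mu=res.mu, feasible=True,
                       v_propionate=res.v_propionate,
                       v_acetate=res.v_acetate,
                       ratio=res.ratio if res.v_acetate > 1e-9 else float("nan"),
                       atp_slp=res.atp_sources.get("acetate_kinase_slp", 0.0),
                       atp_chemiosmotic=res.atp_sources.get("atpase_chemiosmotic", 0.0))
        except InfeasibleError:
            row.update(mu=0.0, feasible=False, v_propionate=float("nan"),
                       v_acetate=float("nan"), ratio=float("nan"),
                       atp_slp=float("nan"), atp_chemiosmotic=float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


#: reaction -> (label, ATP stoichiometric coefficient sign convention handled
#: from the model itself)
_ATP_GROUPS = {
    "rxn00225_c0": "acetate_kinase_slp",
    "rxn10042_c0": "atpase_chemiosmotic",
    "ACS_c0": "acetate_assimilation",
    "rxn00062_c0": "maintenance_ngam",
    "biomass_c0": "biomass_gam",
}


def atp_accounting(flux_state: FluxState, model: MetabolicModel
                   ) -> dict[str, float]:
    """Partition net ATP turnover among its sources and sinks.

    Positive entries produce ATP, negative consume it; the entries sum to
    zero for any steady state (completeness of the accounting).
    """
    if not flux_state.optimal:
        raise ValueError("ATP accounting requires an optimal flux state")
    out = {label: 0.0 for label in _ATP_GROUPS.values()}
    out["other"] = 0.0
    for rid, rxn in model.reactions.items():
        coef = rxn.stoichiometry.get("atp_c0", 0.0)
        if coef == 0.0:
            continue
        contribution = coef * flux_state.fluxes.get(rid, 0.0)
        out[_ATP_GROUPS.get(rid, "other")] = \
            out.get(_ATP_GROUPS.get(rid, "other"), 0.0) + contribution
    return out
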
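"""Steady-state phenotype screening: growth calls and product profiles.

A substrate condition fixes the uptake budget (30 mmol gDW^-1 h^-1 for a
single carbon source, 30 in total for pairs), maximises biomass by FBA, and
calls growth when the growth rate exceeds 1e-4 h^-1.  Product profiles are
reported as mean secretion fluxes from hit-and-run sampling of the solution
space constrained to at least 99% of the maximum growth rate.

Substrates without an exchange reaction in the reduced network (sugars,
amino acids) yield the distinct status ``"not in network"`` rather than a
negative growth call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import (BIG, MetabolicModel, exchange_for, sample_fluxes,
                   set_exchange_bounds, solve_fba)
from .network import open_fermentation_products, seal_exchanges

__all__ = ["PhenotypeCall", "screen_substrate", "screen_pair",
           "product_profile", "GROWTH_THRESHOLD"]

#: growth call threshold (h^-1)
GROWTH_THRESHOLD = 1e-4

#: default uptake bound per substrate (mmol gDW^-1 h^-1): the condition's
#: empirical maximum where one was measured, the generic 30 otherwise.  The
#: ethanol value matters because the core model's maintenance break-even lies
#: near 34.7 mmol gDW^-1 h^-1 (see docs/methods.md).
DEFAULT_UPTAKE: dict[str, float] = {"etoh": 36.2}
GENERIC_UPTAKE = 30.0


def _default_uptake(substrate: str) -> float:
    return DEFAULT_UPTAKE.get(substrate, GENERIC_UPTAKE)

#: species never reported as fermentation products (water, protons and CO2
#: are not scored in product-profile comparisons; ethanol is the substrate)
_NON_PRODUCTS = ("h2o", "h", "co2", "etoh")


@dataclass
class PhenotypeCall:
    """Growth verdict and ranked product profile for one condition."""

    substrates: list[str]
    growth: bool
    mu: float
    products: list[tuple[str, float, float]] = field(default_factory=list)
    status: str = "ok"  # ok | not in network | infeasible

    @property
    def product_names(self) -> list[str]:
        return [name for name, _, _ in self.products]


def _condition_model(model: MetabolicModel, substrates: dict[str, float],
                     total: float) -> MetabolicModel:
    work = model.copy()
    seal_exchanges(work)
    open_fermentation_products(work)
    for species, uptake in substrates.items():
        set_exchange_bounds(work, species, -uptake, BIG)
    work.reactions["SRC_budget"].bounds = (0.0, total)
    return work


def _profile(work: MetabolicModel, n_samples: int, growth_fraction: float,
             seed: int) -> list[tuple[str, float, float]]:
    res = sample_fluxes(work, n=n_samples, growth_fraction=growth_fraction,
                        seed=seed)
    prods = []
    for rid, mean in res.mean.items():
        if not rid.startswith("EX_"):
            continue
        stub = rid[3:-3]
        if stub in _NON_PRODUCTS:
            continue
        if mean > 1e-6:
            prods.append((stub, mean, res.std[rid]))
    prods.sort(key=lambda item: -item[1])
    return prods


def screen_substrate(model: MetabolicModel, substrate: str,
                     uptake: float | None = None, n_samples: int = 5000,
                     growth_fraction: float = 0.99,
                     seed: int = 0) -> PhenotypeCall:
    """Growth call and product profile on a single carbon source.

    ``uptake=None`` uses the substrate's empirical maximum uptake where one
    was measured (ethanol: 36.2) and 30 mmol gDW^-1 h^-1 otherwise.
    """
    try:
        exchange_for(model, substrate)
    except KeyError:
        return PhenotypeCall([substrate], False, 0.0, status="not in network")
    if uptake is None:
        uptake = _default_uptake(substrate)
    work = _condition_model(model, {substrate: uptake}, total=uptake)
    state = solve_fba(work)
    if not state.optimal:
        return PhenotypeCall([substrate], False, 0.0, status="infeasible")
    mu = state.objective_value
    growth = mu > GROWTH_THRESHOLD
    products = _profile(work, n_samples, growth_fraction, seed) if growth else []
    return PhenotypeCall([substrate], growth, mu, products)


def screen_pair(model: MetabolicModel, substrate_a: str, substrate_b: str,
                total_uptake: float | None = None, n_samples: int = 5000,
                growth_fraction: float = 0.99, seed: int = 0) -> PhenotypeCall:
    """Growth call on two co-substrates sharing a total uptake budget.

    ``total_uptake=None`` uses the larger of the two substrates' default
    uptake bounds as the shared budget.
    """
    if total_uptake is None:
        total_uptake = max(_default_uptake(substrate_a),
                           _default_uptake(substrate_b))
    missing = []
    for sub in (substrate_a, substrate_b):
        try:
            exchange_for(model, sub)
        except KeyError:
            missing.append(sub)
    if missing:
        return PhenotypeCall([substrate_a, substrate_b], False, 0.0,
                             status="not in network")
    work = _condition_model(
        model, {substrate_a: total_uptake, substrate_b: total_uptake},
        total=total_uptake)
    state = solve_fba(work)
    if not state.optimal:
        return PhenotypeCall([substrate_a, substrate_b], False, 0.0,
                             status="infeasible")
    mu = state.objective_value
    growth = mu > GROWTH_THRESHOLD
    products = _profile(work, n_samples, growth_fraction, seed) if growth else []
    return PhenotypeCall([substrate_a, substrate_b], growth, mu, products)


def product_profile(call: PhenotypeCall) -> list[tuple[str, float, float]]:
    """Ranked (species, mean secretion, std) of a positive growth call."""
    if not call.growth:
        raise ValueError("product profile requires a positive growth call")
    return call.products
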
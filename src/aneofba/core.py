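"""Generic stoichiometric-model data structures and constraint-based solvers.

The model container is deliberately small: metabolites, reactions with signed
stoichiometry and flux bounds, and a single linear objective.  All analyses in
this package (FBA, FVA, hit-and-run sampling, dynamic FBA) operate on the
steady-state polytope ``{v : S v = 0, lb <= v <= ub}``.

Linear programmes are solved with scipy's HiGHS interface.  Feasibility and
optimality tolerances are pinned to 1e-9 so that derived notions such as
"blocked reaction" are well defined.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg
from scipy.optimize import linprog

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "FluxState",
    "FluxRange",
    "SamplingResult",
    "ModelValidationError",
    "InfeasibleError",
    "solve_fba",
    "flux_variability",
    "blocked_reactions",
    "sample_fluxes",
    "validate_model",
    "set_exchange_bounds",
    "exchange_for",
    "stoichiometric_matrix",
]

#: solver tolerance used throughout (feasibility and optimality)
LP_TOL = 1e-9

#: default magnitude used for "unbounded" reactions
BIG = 1000.0


class ModelValidationError(ValueError):
    """Raised when a model violates its structural invariants."""


class InfeasibleError(RuntimeError):
    """Raised when an operation requires a feasible/optimal LP but none exists."""


@dataclass
class Metabolite:
    """A chemical species in a compartment.

    ``formula`` may be ``None`` for lumped pseudo-metabolites (biomass
    precursors, capacity tokens); such species are skipped by the elemental
    balance audit.
    """

    id: str
    name: str = ""
    formula: str | None = None
    charge: int = 0
    compartment: str = "c0"


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds (mmol gDW^-1 h^-1).

    ``stoichiometry`` maps metabolite id to a signed coefficient; negative
    means consumed.  ``kind`` is one of ``metabolic``, ``transport``,
    ``exchange``, ``biomass``.
    """

    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -BIG
    upper_bound: float = BIG
    gene_rule: str = ""
    subsystem: str = ""
    ec: str = ""
    kind: str = "metabolic"

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.lower_bound, self.upper_bound)

    @bounds.setter
    def bounds(self, lb_ub: tuple[float, float]) -> None:
        lb, ub = lb_ub
        if lb > ub:
            raise ModelValidationError(
                f"reaction {self.id}: lower_bound {lb} > upper_bound {ub}"
            )
        self.lower_bound, self.upper_bound = float(lb), float(ub)


@dataclass
class MetabolicModel:
    """A stoichiometric network with one linear objective."""

    id: str = "model"
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    objective_id: str = ""
    objective_sense: str = "maximize"
    compartments: tuple[str, ...] = ("c0", "e0")

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelValidationError(f"duplicate metabolite id {met.id}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelValidationError(f"duplicate reaction id {rxn.id}")
        self.reactions[rxn.id] = rxn

    def validate(self) -> None:
        """Check structural invariants; raise ModelValidationError on failure."""
        for rxn in self.reactions.values():
            for mid in rxn.stoichiometry:
                if mid not in self.metabolites:
                    raise ModelValidationError(
                        f"reaction {rxn.id} references unknown metabolite {mid}"
                    )
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelValidationError(f"reaction {rxn.id}: inverted bounds")
        for met in self.metabolites.values():
            if met.compartment not in self.compartments:
                raise ModelValidationError(
                    f"metabolite {met.id}: unknown compartment {met.compartment}"
                )
        if self.objective_id and self.objective_id not in self.reactions:
            raise ModelValidationError(
                f"objective {self.objective_id!r} is not a reaction id"
            )
        if self.objective_sense not in ("maximize", "minimize"):
            raise ModelValidationError(
                f"objective_sense must be maximize|minimize, got {self.objective_sense}"
            )

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites={k: replace(v) for k, v in self.metabolites.items()},
            reactions={
                k: replace(v, stoichiometry=dict(v.stoichiometry))
                for k, v in self.reactions.items()
            },
            objective_id=self.objective_id,
            objective_sense=self.objective_sense,
            compartments=self.compartments,
        )


@dataclass
class FluxState:
    """One FBA solution."""

    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FluxRange:
    """Per-reaction flux ranges at a stated fraction of the optimum."""

    fraction_of_optimum: float
    status: str
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class SamplingResult:
    """Summary of a hit-and-run sample of the constrained flux polytope."""

    n_samples: int
    seed: int
    mean: dict[str, float]
    std: dict[str, float]
    samples: np.ndarray | None = None
    reaction_ids: list[str] | None = None


# ---------------------------------------------------------------------------
# matrix assembly and LP plumbing
# ---------------------------------------------------------------------------

def stoichiometric_matrix(model: MetabolicModel):
    """Return (S, metabolite_ids, reaction_ids) with S of shape (m, n)."""
    met_ids = list(model.metabolites)
    rxn_ids = list(model.reactions)
    mindex = {m: i for i, m in enumerate(met_ids)}
    S = np.zeros((len(met_ids), len(rxn_ids)))
    for j, rid in enumerate(rxn_ids):
        for mid, coef in model.reactions[rid].stoichiometry.items():
            S[mindex[mid], j] = coef
    return S, met_ids, rxn_ids


class _LinearProblem:
    """Cached LP arrays for repeated solves on the same network topology.

    Only bounds and objective change between solves; the equality system is
    assembled once.  Used heavily by the dynamic-FBA stepper.
    """

    def __init__(self, model: MetabolicModel):
        model.validate()
        self.model = model
        self.S, self.met_ids, self.rxn_ids = stoichiometric_matrix(model)
        self.rindex = {r: j for j, r in enumerate(self.rxn_ids)}
        self.b = np.zeros(self.S.shape[0])

    def bounds_array(self):
        return [
            (model_r.lower_bound, model_r.upper_bound)
            for model_r in (self.model.reactions[r] for r in self.rxn_ids)
        ]

    def solve(self, objective: dict[str, float], sense: str = "maximize",
              bounds=None) -> FluxState:
        c = np.zeros(len(self.rxn_ids))
        for rid, coef in objective.items():
            c[self.rindex[rid]] = coef
        sign = -1.0 if sense == "maximize" else 1.0
        res = linprog(
            sign * c,
            A_eq=self.S,
            b_eq=self.b,
            bounds=bounds if bounds is not None else self.bounds_array(),
            method="highs",
            options={"primal_feasibility_tolerance": LP_TOL,
                     "dual_feasibility_tolerance": LP_TOL},
        )
        if res.status == 2:
            return FluxState("infeasible", float("nan"))
        if res.status == 3:
            return FluxState("unbounded", float("inf"))
        if not res.success:  # pragma: no cover - solver hiccup
            return FluxState("infeasible", float("nan"))
        fluxes = {rid: float(res.x[j]) for j, rid in enumerate(self.rxn_ids)}
        return FluxState("optimal", float(c @ res.x), fluxes)


def _objective_of(model: MetabolicModel) -> dict[str, float]:
    if not model.objective_id:
        raise ModelValidationError("model has no objective reaction set")
    return {model.objective_id: 1.0}


def solve_fba(model: MetabolicModel, minimize_total_flux: bool = False) -> FluxState:
    """Flux balance analysis: optimise the model objective over the polytope.

    With ``minimize_total_flux`` the solve is lexicographic: the objective is
    optimised first, then fixed (within tolerance) while the total absolute
    flux is minimised.  This picks a parsimonious representative among
    alternate optima, which is how ratio and profile quantities are reported.
    """
    prob = _LinearProblem(model)
    first = prob.solve(_objective_of(model), model.objective_sense)
    if not first.optimal or not minimize_total_flux:
        return first
    return _parsimonious(prob, model, first)


def _parsimonious(prob: _LinearProblem, model: MetabolicModel,
                  first: FluxState) -> FluxState:
    n = len(prob.rxn_ids)
    jobj = prob.rindex[model.objective_id]
    opt = first.objective_value
    slack = LP_TOL * max(1.0, abs(opt)) * 10
    bounds = prob.bounds_array()
    lo, hi = bounds[jobj]
    if model.objective_sense == "maximize":
        bounds[jobj] = (max(lo, opt - slack), hi)
    else:
        bounds[jobj] = (lo, min(hi, opt + slack))
    # min sum t  s.t.  v - t <= 0, -v - t <= 0
    c = np.concatenate([np.zeros(n), np.ones(n)])
    A_eq = np.hstack([prob.S, np.zeros_like(prob.S)])
    eye = np.eye(n)
    A_ub = np.vstack([np.hstack([eye, -eye]), np.hstack([-eye, -eye])])
    b_ub = np.zeros(2 * n)
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=np.zeros(A_eq.shape[0]),
        bounds=bounds + [(0, None)] * n, method="highs",
        options={"primal_feasibility_tolerance": LP_TOL,
                 "dual_feasibility_tolerance": LP_TOL},
    )
    if not res.success:  # fall back to the plain optimum
        return first
    fluxes = {rid: float(res.x[j]) for j, rid in enumerate(prob.rxn_ids)}
    return FluxState("optimal", float(fluxes[model.objective_id]), fluxes)


def flux_variability(model: MetabolicModel, fraction_of_optimum: float = 1.0,
                     reactions: list[str] | None = None) -> FluxRange:
    """Per-reaction flux minima and maxima at a fraction of the optimum.

    With ``fraction_of_optimum=0`` the objective constraint is dropped and the
    ranges describe the whole bounded polytope (the setting used for blocked-
    reaction detection).
    """
    if not 0 <= fraction_of_optimum <= 1:
        raise ValueError("fraction_of_optimum must lie in [0, 1]")
    prob = _LinearProblem(model)
    bounds = prob.bounds_array()
    if fraction_of_optimum > 0:
        base = prob.solve(_objective_of(model), model.objective_sense)
        if not base.optimal:
            return FluxRange(fraction_of_optimum, base.status)
        jobj = prob.rindex[model.objective_id]
        opt = base.objective_value
        lo, hi = bounds[jobj]
        if model.objective_sense == "maximize":
            bounds[jobj] = (max(lo, fraction_of_optimum * opt - LP_TOL), hi)
        else:
            bounds[jobj] = (lo, min(hi, fraction_of_optimum * opt + LP_TOL))
    ranges: dict[str, tuple[float, float]] = {}
    for rid in reactions if reactions is not None else prob.rxn_ids:
        lohi = []
        for sense in ("minimize", "maximize"):
            s = prob.solve({rid: 1.0}, sense, bounds=bounds)
            if not s.optimal:
                return FluxRange(fraction_of_optimum, s.status)
            lohi.append(s.objective_value)
        ranges[rid] = (lohi[0], lohi[1])
    return FluxRange(fraction_of_optimum, "optimal", ranges)


def blocked_reactions(fr: FluxRange, tol: float = 1e-9) -> set[str]:
    """Reactions whose flux range is numerically {0}."""
    return {
        rid for rid, (lo, hi) in fr.ranges.items()
        if abs(lo) < tol and abs(hi) < tol
    }


def sample_fluxes(model: MetabolicModel, n: int, growth_fraction: float = 0.99,
                  seed: int = 0, warmup: int = 1000, thinning: int = 10,
                  keep_samples: bool = False) -> SamplingResult:
    """Hit-and-run sampling of the flux polytope at >= growth_fraction optimum.

    A feasible interior chain is run in the null space of S: directions are
    isotropic in null-space coordinates, the step length is drawn uniformly on
    the feasible chord.  The first ``warmup`` states are discarded and every
    ``thinning``-th state thereafter is recorded.  Reproducible for a fixed
    seed.
    """
    work = model.copy()
    prob = _LinearProblem(work)
    base = prob.solve(_objective_of(work), work.objective_sense)
    if not base.optimal:
        raise InfeasibleError(
            f"cannot sample: base FBA is {base.status} "
            f"(objective {work.objective_id})"
        )
    jobj = prob.rindex[work.objective_id]
    opt = base.objective_value
    robj = work.reactions[work.objective_id]
    if work.objective_sense == "maximize":
        robj.lower_bound = max(robj.lower_bound,
                               growth_fraction * opt - 1e-7 * max(1, abs(opt)))
    else:
        robj.upper_bound = min(robj.upper_bound,
                               growth_fraction * opt + 1e-7 * max(1, abs(opt)))
    start = prob.solve({work.objective_id: 1.0}, work.objective_sense,
                       bounds=prob.bounds_array())
    if not start.optimal:
        raise InfeasibleError(
            f"growth-fraction constraint {growth_fraction} x {opt:.6g} on "
            f"{work.objective_id} is infeasible"
        )
    rxn_ids = prob.rxn_ids
    lb = np.array([work.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([work.reactions[r].upper_bound for r in rxn_ids])
    v = np.array([start.fluxes[r] for r in rxn_ids])
    v = np.clip(v, lb, ub)
    N = linalg.null_space(prob.S, rcond=1e-10)
    rng = np.random.default_rng(seed)
    kept = np.empty((n, len(rxn_ids)))
    nkept = 0
    step = 0
    needed = warmup + n * thinning
    while nkept < n and step < needed * 50:
        step += 1
        if N.shape[1] == 0:
            d = np.zeros(len(rxn_ids))
        else:
            g = rng.standard_normal(N.shape[1])
            d = N @ g
        nrm = np.linalg.norm(d)
        if nrm < 1e-12:
            tmin = tmax = 0.0
        else:
            d /= nrm
            with np.errstate(divide="ignore", invalid="ignore"):
                lo_t = (lb - v) / d
                hi_t = (ub - v) / d
            tl = np.where(d > 1e-12, lo_t, np.where(d < -1e-12, hi_t, -np.inf))
            tu = np.where(d > 1e-12, hi_t, np.where(d < -1e-12, lo_t, np.inf))
            tmin = max(tl.max(initial=-np.inf), -1e6)
            tmax = min(tu.min(initial=np.inf), 1e6)
            if tmax < tmin:
                tmin = tmax = 0.0
        t = rng.uniform(tmin, tmax) if tmax > tmin else 0.0
        v = np.clip(v + t * d, lb, ub)
        if step > warmup and (step - warmup) % thinning == 0:
            kept[nkept] = v
            nkept += 1
    kept = kept[:nkept]
    mean = {r: float(m) for r, m in zip(rxn_ids, kept.mean(axis=0))}
    std = {r: float(s) for r, s in zip(rxn_ids, kept.std(axis=0))}
    return SamplingResult(
        n_samples=nkept, seed=seed, mean=mean, std=std,
        samples=kept if keep_samples else None,
        reaction_ids=list(rxn_ids) if keep_samples else None,
    )


# ---------------------------------------------------------------------------
# audit and convenience editing
# ---------------------------------------------------------------------------

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse 'C2H6O' style formulas into element counts."""
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_RE.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = match.end()
        el, num = match.groups()
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


@dataclass
class BalanceReport:
    """Report-only audit of a model (never raises)."""

    elemental_imbalances: dict[str, dict[str, float]] = field(default_factory=dict)
    charge_imbalances: dict[str, float] = field(default_factory=dict)
    dangling_references: list[str] = field(default_factory=list)
    duplicate_ids: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not (self.elemental_imbalances or self.charge_imbalances
                    or self.dangling_references or self.duplicate_ids)


def validate_model(model: MetabolicModel, tol: float = 1e-6) -> BalanceReport:
    """Elemental/charge bookkeeping over all metabolic reactions.

    Biomass-tagged reactions, exchanges, transports and any reaction touching
    a metabolite without a formula (lumped pseudo-species) are skipped, and
    listed in ``report.skipped``.
    """
    report = BalanceReport()
    for rxn in model.reactions.values():
        missing = [m for m in rxn.stoichiometry if m not in model.metabolites]
        if missing:
            report.dangling_references.extend(
                f"{rxn.id}:{m}" for m in missing)
            continue
        if rxn.kind in ("biomass", "exchange", "transport"):
            report.skipped.append(rxn.id)
            continue
        mets = [model.metabolites[m] for m in rxn.stoichiometry]
        if any(met.formula is None for met in mets):
            report.skipped.append(rxn.id)
            continue
        elements: dict[str, float] = {}
        charge = 0.0
        for mid, coef in rxn.stoichiometry.items():
            met = model.metabolites[mid]
            for el, cnt in parse_formula(met.formula).items():
                elements[el] = elements.get(el, 0.0) + coef * cnt
            charge += coef * met.charge
        bad = {el: val for el, val in elements.items() if abs(val) > tol}
        if bad:
            report.elemental_imbalances[rxn.id] = bad
        if abs(charge) > tol:
            report.charge_imbalances[rxn.id] = charge
    return report


def exchange_for(model: MetabolicModel, species: str) -> Reaction:
    """Return the exchange reaction draining extracellular ``species``.

    ``species`` may be given with or without the ``_e0`` suffix.
    """
    mid = species if species.endswith("_e0") else species + "_e0"
    for rxn in model.reactions.values():
        if rxn.kind == "exchange" and mid in rxn.stoichiometry:
            return rxn
    raise KeyError(f"no exchange reaction for species {species!r}")


def set_exchange_bounds(model: MetabolicModel, species: str,
                        lower: float, upper: float) -> MetabolicModel:
    """Set exchange bounds in place; negative flux means uptake."""
    if lower > upper:
        raise ModelValidationError(
            f"exchange bounds for {species}: lower {lower} > upper {upper}")
    rxn = exchange_for(model, species)
    rxn.lower_bound, rxn.upper_bound = float(lower), float(upper)
    return model
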
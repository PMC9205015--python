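"""Dynamic FBA batch simulator.

Extracellular concentrations and biomass evolve by forward-Euler integration

    dX/dt = mu X,    dS_i/dt = q_Si X,    dP_j/dt = q_Pj X

with the per-step rates taken from an FBA solution in which substrate uptake
is bounded by Michaelis-Menten kinetics, q_S = q_S,max * S / (Km + S), and
additionally by S/(X dt) so concentrations can never cross zero.  The growth
objective is replaced by ATP-yield maximisation (the maintenance reaction
rxn00062_c0) once growth becomes infeasible on the residual substrate; the
switch is sticky once ethanol is numerically exhausted.

Units: X in gDW L^-1, concentrations in mM, rates in mmol gDW^-1 h^-1,
time in h.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BIG, MetabolicModel, _LinearProblem
from .network import (biomass_carbon, default_composition,
                      open_fermentation_products, seal_exchanges)

__all__ = [
    "KineticParams",
    "BatchInitial",
    "TimeCourse",
    "uptake_rate",
    "simulate_batch",
    "SCENARIOS",
    "carbon_balance",
]

#: growth rate below which the objective switches to ATP maintenance (h^-1)
GROWTH_SWITCH_THRESHOLD = 1e-6

#: concentrations below this are treated as numerically zero (mM)
NUMERICAL_ZERO = 1e-9


@dataclass
class KineticParams:
    """Michaelis-Menten uptake parameters per substrate.

    ``qs_max`` and ``km`` map species stubs (``etoh``, ``ac``) to the maximum
    specific uptake rate (mmol gDW^-1 h^-1) and half-saturation constant
    (mM).  ``mu_max`` optionally caps the biomass reaction.
    """

    qs_max: dict[str, float] = field(default_factory=lambda: {"etoh": 36.2})
    km: dict[str, float] = field(default_factory=lambda: {"etoh": 0.5})
    mu_max: float | None = None

    def validate(self) -> None:
        for sp, q in self.qs_max.items():
            if q < 0:
                raise ValueError(f"qs_max[{sp}] must be >= 0")
            if self.km.get(sp, 0) <= 0:
                raise ValueError(f"km[{sp}] must be > 0")


@dataclass
class BatchInitial:
    """Initial bottle state: biomass (gDW L^-1) and concentrations (mM)."""

    X0: float = 0.0028
    S0: dict[str, float] = field(default_factory=lambda: {"etoh": 25.0})

    def validate(self) -> None:
        if self.X0 < 0:
            raise ValueError("X0 must be >= 0")
        if any(v < 0 for v in self.S0.values()):
            raise ValueError("initial concentrations must be >= 0")


@dataclass
class TimeCourse:
    """A simulated batch trajectory."""

    times: np.ndarray
    X: np.ndarray
    species: dict[str, np.ndarray]
    mu: np.ndarray
    objective: list[str]  # per step: "growth" | "atp_maintenance"
    fluxes: dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        data = {"time_h": self.times, "X_g_per_L": self.X, "mu": self.mu,
                "objective": self.objective}
        for sp, series in self.species.items():
            data[f"{sp}_mM"] = series
        return pd.DataFrame(data)

    def final(self, species: str) -> float:
        return float(self.species[species][-1])

    def peak_biomass_mg_per_L(self) -> float:
        return float(self.X.max() * 1000.0)


def uptake_rate(S: float, qmax: float, Km: float) -> float:
    """Michaelis-Menten uptake rate q = qmax * S / (Km + S)."""
    if S < 0:
        raise ValueError(f"substrate concentration must be >= 0, got {S}")
    if Km <= 0:
        raise ValueError("Km must be positive")
    if qmax < 0:
        raise ValueError("qmax must be >= 0")
    return qmax * S / (Km + S)


#: species whose extracellular concentration is tracked
_TRACKED = ("etoh", "ac", "ppa", "poh", "but", "lac__D", "co2")


def _set_step_bounds(model: MetabolicModel, params: KineticParams,
                     S: dict[str, float], X: float, dt: float) -> None:
    for sp in _TRACKED:
        ex = model.reactions[f"EX_{sp}_e0"]
        if sp == "co2":
            ex.bounds = (-BIG, BIG)  # headspace excess, never limiting
            continue
        conc = S.get(sp, 0.0)
        if sp in params.qs_max:
            q = uptake_rate(conc, params.qs_max[sp], params.km[sp])
            if X > 0 and dt > 0:
                q = min(q, conc / (X * dt))
            ex.bounds = (-q, BIG)
        else:
            # products: secretion only, but deplete no further than stock
            ex.bounds = (0.0, BIG)
    if params.mu_max is not None:
        bio = model.reactions["biomass_c0"]
        bio.bounds = (bio.lower_bound, params.mu_max)


def _step_fluxes(prob: _LinearProblem, model: MetabolicModel,
                 maintenance: bool):
    """Solve one step; returns (state, tag) or (None, None) if dead."""
    if not maintenance:
        state = prob.solve({"biomass_c0": 1.0}, "maximize")
        if state.optimal and state.objective_value > GROWTH_SWITCH_THRESHOLD:
            return state, "growth"
    # maintenance mode: relax the NGAM floor and maximise ATP turnover
    ngam_rxn = model.reactions["rxn00062_c0"]
    saved = ngam_rxn.bounds
    ngam_rxn.bounds = (0.0, saved[1])
    bio = model.reactions["biomass_c0"]
    saved_bio = bio.bounds
    bio.bounds = (0.0, 0.0)
    state = prob.solve({"rxn00062_c0": 1.0}, "maximize")
    ngam_rxn.bounds = saved
    bio.bounds = saved_bio
    if state.optimal:
        return state, "atp_maintenance"
    return None, None


def simulate_batch(model: MetabolicModel, params: KineticParams,
                   init: BatchInitial, dt: float = 0.1,
                   t_end: float = 300.0,
                   track_fluxes: tuple[str, ...] = ()) -> TimeCourse:
    """Integrate a batch culture; deterministic for identical inputs."""
    params.validate()
    init.validate()
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be positive")
    work = model.copy()
    seal_exchanges(work)
    open_fermentation_products(work)
    prob = _LinearProblem(work)

    nsteps = int(round(t_end / dt))
    times = np.empty(nsteps + 1)
    X = np.empty(nsteps + 1)
    mu_arr = np.zeros(nsteps + 1)
    species = {sp: np.empty(nsteps + 1) for sp in _TRACKED}
    tags: list[str] = []
    tracked_fluxes = {rid: np.zeros(nsteps + 1) for rid in track_fluxes}

    S = {sp: float(init.S0.get(sp, 0.0)) for sp in _TRACKED}
    S.setdefault("co2", 0.0)
    x = float(init.X0)
    times[0] = 0.0
    X[0] = x
    for sp in _TRACKED:
        species[sp][0] = S[sp]
    tags.append("growth")

    ethanol_exhausted = False
    for k in range(1, nsteps + 1):
        _set_step_bounds(work, params, S, x, dt)
        if S.get("etoh", 0.0) < NUMERICAL_ZERO:
            ethanol_exhausted = True
        state, tag = _step_fluxes(prob, work, maintenance=ethanol_exhausted)
        if state is None:
            # nothing left to metabolise at all: freeze the state
            times[k] = times[k - 1] + dt
            X[k] = x
            for sp in _TRACKED:
                species[sp][k] = S[sp]
            tags.append("halted")
            continue
        mu = state.fluxes["biomass_c0"] if tag == "growth" else 0.0
        x_new = x * (1.0 + mu * dt)
        for sp in _TRACKED:
            v = state.fluxes[f"EX_{sp}_e0"]
            if sp == "co2":
                # net cumulative headspace draw; may run negative
                S[sp] = S[sp] + v * x * dt
            else:
                S[sp] = max(0.0, S[sp] + v * x * dt)
        for rid in track_fluxes:
            tracked_fluxes[rid][k] = state.fluxes[rid]
        x = x_new
        times[k] = times[k - 1] + dt
        X[k] = x
        mu_arr[k] = mu
        for sp in _TRACKED:
            species[sp][k] = S[sp]
        tags.append(tag)

    return TimeCourse(times=times, X=X, species=species, mu=mu_arr,
                      objective=tags, fluxes=tracked_fluxes)


def carbon_balance(tc: TimeCourse, model: MetabolicModel) -> float:
    """Relative carbon-balance gap of a trajectory.

    Carbon consumed (ethanol + net CO2 + other substrates) minus carbon in
    secreted products and biomass, as a fraction of carbon consumed.  Should
    vanish up to Euler integration error.
    """
    carbons = {"etoh": 2, "ac": 2, "ppa": 3, "poh": 3, "but": 4,
               "lac__D": 3, "co2": 1}
    consumed = 0.0
    produced = 0.0
    for sp, nc in carbons.items():
        delta = tc.species[sp][-1] - tc.species[sp][0]
        if delta < 0:
            consumed += -delta * nc
        else:
            produced += delta * nc
    produced += (tc.X[-1] - tc.X[0]) * biomass_carbon(default_composition())
    if consumed == 0:
        return 0.0
    return (consumed - produced) / consumed


#: batch scenarios with the empirical kinetic inputs of each cultivation
#: condition (maximum uptake and growth rates measured in the corresponding
#: bottles); Km values are model-fit defaults
SCENARIOS: dict[str, dict] = {
    "ethanol25": {
        "params": dict(qs_max={"etoh": 36.2}, km={"etoh": 0.5}, mu_max=0.082),
        "init": dict(X0=0.0028, S0={"etoh": 25.0}),
        "dt": 0.1, "t_end": 300.0,
    },
    "ethanol25_acetate10": {
        "params": dict(qs_max={"etoh": 43.3}, km={"etoh": 0.5}, mu_max=0.098),
        "init": dict(X0=0.0028, S0={"etoh": 25.0, "ac": 10.0}),
        "dt": 0.1, "t_end": 300.0,
    },
    "ethanol25_acetate25": {
        "params": dict(qs_max={"etoh": 36.2}, km={"etoh": 0.5}, mu_max=0.082),
        "init": dict(X0=0.0028, S0={"etoh": 25.0, "ac": 25.0}),
        "dt": 0.1, "t_end": 300.0,
    },
}


def run_scenario(model: MetabolicModel, name: str, dt: float | None = None,
                 t_end: float | None = None) -> TimeCourse:
    spec = SCENARIOS[name]
    params = KineticParams(**spec["params"])
    init = BatchInitial(**spec["init"])
    return simulate_batch(model, params, init,
                          dt=dt if dt is not None else spec["dt"],
                          t_end=t_end if t_end is not None else spec["t_end"])
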
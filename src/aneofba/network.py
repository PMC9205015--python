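"""Core model of ethanol fermentation via the acrylate pathway.

Builds the curated ~30-reaction network of *Anaerotignum neopropionicum*
central carbon and energy metabolism: ethanol oxidation to acetyl-CoA,
acetate kinase substrate-level phosphorylation, CO2-fixing PFOR, the acrylate
cycle (Pct / lactoyl-CoA dehydratase / Acr-EtfAB), the Rnf complex and
V-type ATPase with a configurable cation-per-ATP coupling ratio, the
electron-confurcating Nfn, and the propanol and butyrate overflow branches.

Reaction ids follow the ModelSEED-style ids used in the published model where
those are known; auxiliary reactions carry descriptive ids.

Energetic architecture
----------------------
On ethanol, reduced ferredoxin for the CO2-fixing PFOR is produced by the Rnf
complex running in reverse at the expense of the transmembrane ion gradient
(maintained by ATP hydrolysis at the V-ATPase, ``coupling_ratio`` cations per
ATP), supplemented by NADPH-mediated electron confurcation through Nfn fed by
a capacity-bounded NADP-dependent acetaldehyde dehydrogenase.  On D-lactate
the electron flow inverts: PFOR runs decarboxylating, Rnf runs forward and
the ATPase synthesises ATP chemiosmotically.

Branch capacities
-----------------
The propanol and butyrate exits and the NADP-dependent aldehyde oxidation are
capacity-limited.  The limits are expressed per unit of ethanol oxidised
(values in :class:`ModelConfig` are absolute rates at the reference ethanol
uptake of 36.2 mmol gDW^-1 h^-1) and are implemented stoichiometrically:
the committed ethanol-oxidation step emits pseudo-metabolite "capacity
tokens" consumed by the capped reactions, with free sinks for the surplus.
This keeps every analysis a plain ``S v = 0`` problem and makes branch usage
scale with substrate throughput in batch simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .core import BIG, MetabolicModel, Metabolite, ModelValidationError, Reaction

__all__ = [
    "ModelConfig",
    "BiomassComposition",
    "PRECURSOR_TABLE",
    "REFERENCE_UPTAKE",
    "build_core_model",
    "build_biomass_reaction",
    "default_composition",
    "seal_exchanges",
    "open_fermentation_products",
    "disable_growth",
]

#: empirical maximum ethanol uptake rate (mmol gDW^-1 h^-1) at which the
#: absolute capacity values in ModelConfig apply
REFERENCE_UPTAKE = 36.2


@dataclass
class ModelConfig:
    """Tunable parameters of the core model.

    coupling_ratio
        Cations (H+ or Na+) translocated per ATP at the V-ATPase; the
        physiologically admissible fit range is [3, 3.5].
    gam / ngam
        Growth-associated (mmol ATP per g biomass) and non-growth-associated
        (mmol ATP gDW^-1 h^-1) maintenance.
    propanol_cap / butyrate_cap / nadp_acald_cap
        Capacity limits of the propanol exit, butyrate exit and the
        NADP-dependent acetaldehyde dehydrogenase, as absolute rates at
        ``reference_uptake``; internally scaled per mole of ethanol oxidised.
    hydrogenase_blocked
        The ferredoxin hydrogenase (rxn05759_c0) is annotated but H2 is
        neither produced nor consumed in cultivation; blocked by default.
    energy_decoupled
        Replace the ion-translocating Rnf with an uncoupled ferredoxin:NAD+
        reductase.  Used for theoretical-stoichiometry analyses where the
        chemiosmotic cost of ferredoxin reduction is deliberately removed.
    """

    coupling_ratio: float = 3.5
    gam: float = 40.0
    ngam: float = 8.4
    propanol_cap: float = 5.0
    butyrate_cap: float = 2.5
    nadp_acald_cap: float = 33.0
    reference_uptake: float = REFERENCE_UPTAKE
    hydrogenase_blocked: bool = True
    energy_decoupled: bool = False

    def __post_init__(self) -> None:
        if self.coupling_ratio <= 0:
            raise ValueError("coupling_ratio must be positive")
        if self.gam < 0 or self.ngam < 0:
            raise ValueError("gam and ngam must be non-negative")
        for cap in (self.propanol_cap, self.butyrate_cap, self.nadp_acald_cap):
            if cap < 0:
                raise ValueError("capacity bounds must be non-negative")
        if self.reference_uptake <= 0:
            raise ValueError("reference_uptake must be positive")


@dataclass
class BiomassComposition:
    """Macromolecular biomass fractions (g per g dry weight) plus GAM.

    The default composition is a placeholder in the style of the clostridial
    models the published biomass reaction was adapted from; the fractions must
    sum to one, and DNA+RNA+trace is held at 0.10 of the biomass.
    """

    protein: float = 0.53
    phospholipid: float = 0.08
    teichoic_acid: float = 0.12
    peptidoglycan: float = 0.12
    carbohydrate: float = 0.05
    dna: float = 0.03
    rna: float = 0.06
    trace: float = 0.01
    gam: float = 40.0

    _WALL = ("teichoic_acid", "peptidoglycan", "carbohydrate")
    _FIXED = ("dna", "rna", "trace")

    def fractions(self) -> dict[str, float]:
        return {
            k: getattr(self, k)
            for k in ("protein", "phospholipid", "teichoic_acid",
                      "peptidoglycan", "carbohydrate", "dna", "rna", "trace")
        }

    def total(self) -> float:
        return sum(self.fractions().values())

    def validate(self) -> None:
        fr = self.fractions()
        if any(v < 0 for v in fr.values()):
            raise ValueError("biomass fractions must be non-negative")
        if abs(self.total() - 1.0) > 1e-9:
            raise ValueError(
                f"biomass fractions must sum to 1 (got {self.total():.12f})")
        if self.gam < 0:
            raise ValueError("gam must be non-negative")


def default_composition(gam: float = 40.0) -> BiomassComposition:
    return BiomassComposition(gam=gam)


#: lumped precursor demands per gram of each macromolecule class
#: (mmol of acetyl-CoA carbon skeletons, pyruvate skeletons, NADPH reducing
#: equivalents and polymerisation ATP; placeholder values in the style of
#: clostridial biomass reactions)
PRECURSOR_TABLE: dict[str, dict[str, float]] = {
    "protein":       {"pyr": 12.0, "nadph": 10.0, "atp": 16.0},
    "phospholipid":  {"accoa": 35.0, "nadph": 28.0, "atp": 2.0},
    "teichoic_acid": {"accoa": 12.0, "atp": 8.0},
    "peptidoglycan": {"accoa": 10.0, "pyr": 2.0, "nadph": 2.0, "atp": 8.0},
    "carbohydrate":  {"pyr": 11.0, "atp": 6.0},
    "dna":           {"pyr": 8.0, "nadph": 4.0, "atp": 12.0},
    "rna":           {"pyr": 8.0, "nadph": 2.0, "atp": 10.0},
    "trace":         {"accoa": 5.0, "atp": 5.0},
}


def precursor_demands(comp: BiomassComposition) -> dict[str, float]:
    """Aggregate precursor coefficients (mmol per g biomass) for a composition."""
    comp.validate()
    totals = {"accoa": 0.0, "pyr": 0.0, "nadph": 0.0, "atp": 0.0}
    for macro, frac in comp.fractions().items():
        for species, per_g in PRECURSOR_TABLE[macro].items():
            totals[species] += frac * per_g
    return totals


def biomass_carbon(comp: BiomassComposition) -> float:
    """mmol carbon fixed per g biomass, from the precursor skeletons."""
    d = precursor_demands(comp)
    return 2.0 * d["accoa"] + 3.0 * d["pyr"]


def build_biomass_reaction(comp: BiomassComposition) -> Reaction:
    """Biomass synthesis reaction, normalised to 1 g biomass per mmol flux.

    Consumes lumped precursors (acetyl-CoA, pyruvate, NADPH) plus
    ``comp.gam`` + polymerisation ATP; with ``gam=0`` the ATP coefficient
    equals the polymerisation cost of the composition alone.
    """
    d = {k: round(v, 10) for k, v in precursor_demands(comp).items()}
    atp = round(comp.gam + d["atp"], 10)
    sto = {
        "accoa_c0": -d["accoa"], "pyr_c0": -d["pyr"], "nadph_c0": -d["nadph"],
        "atp_c0": -atp, "h2o_c0": -atp,
        "coa_c0": d["accoa"], "nadp_c0": d["nadph"],
        "adp_c0": atp, "pi_c0": atp, "h_c0": atp,
    }
    return Reaction(
        id="biomass_c0",
        name="Biomass synthesis (1 g per mmol)",
        stoichiometry=sto,
        lower_bound=0.0, upper_bound=BIG,
        subsystem="Biomass", kind="biomass",
    )


# ---------------------------------------------------------------------------
# species and reaction inventories
# ---------------------------------------------------------------------------

_MET_TABLE: dict[str, tuple[str, str | None, int]] = {
    # id-stub: (name, formula, charge)
    "etoh":   ("Ethanol", "C2H6O", 0),
    "acald":  ("Acetaldehyde", "C2H4O", 0),
    "accoa":  ("Acetyl-CoA", "C23H34N7O17P3S", -4),
    "actp":   ("Acetyl phosphate", "C2H3O5P", -2),
    "ac":     ("Acetate", "C2H3O2", -1),
    "pyr":    ("Pyruvate", "C3H3O3", -1),
    "lac__D": ("D-Lactate", "C3H5O3", -1),
    "laccoa": ("Lactoyl-CoA", "C24H36N7O18P3S", -4),
    "acrcoa": ("Acryloyl-CoA", "C24H34N7O17P3S", -4),
    "ppcoa":  ("Propionyl-CoA", "C24H36N7O17P3S", -4),
    "ppa":    ("Propionate", "C3H5O2", -1),
    "ppal":   ("Propionaldehyde", "C3H6O", 0),
    "poh":    ("1-Propanol", "C3H8O", 0),
    "aacoa":  ("Acetoacetyl-CoA", "C25H36N7O18P3S", -4),
    "hbcoa":  ("3-Hydroxybutyryl-CoA", "C25H38N7O18P3S", -4),
    "b2coa":  ("Crotonyl-CoA", "C25H36N7O17P3S", -4),
    "btcoa":  ("Butyryl-CoA", "C25H38N7O17P3S", -4),
    "but":    ("Butyrate", "C4H7O2", -1),
    "nad":    ("NAD+", "C21H26N7O14P2", -1),
    "nadh":   ("NADH", "C21H27N7O14P2", -2),
    "nadp":   ("NADP+", "C21H25N7O17P3", -3),
    "nadph":  ("NADPH", "C21H26N7O17P3", -4),
    "fdox":   ("Ferredoxin (oxidised)", "Fe8S8", 0),
    "fdred":  ("Ferredoxin (reduced, 2e-)", "Fe8S8", -2),
    "atp":    ("ATP", "C10H12N5O13P3", -4),
    "adp":    ("ADP", "C10H12N5O10P2", -3),
    "pi":     ("Phosphate", "HO4P", -2),
    "coa":    ("Coenzyme A", "C21H32N7O16P3S", -4),
    "co2":    ("CO2", "CO2", 0),
    "h2o":    ("H2O", "H2O", 0),
    "h":      ("H+", "H", 1),
    "h2":     ("H2", "H2", 0),
}

#: species with an extracellular counterpart, transport and exchange
_EXTERNAL = ("etoh", "ac", "ppa", "lac__D", "poh", "but", "pyr",
             "co2", "h2", "h2o", "h")

#: pseudo-metabolites (no formula; exempt from balance audit)
_PSEUDO = {
    "h_p":     "H+ (translocated, periplasmic pseudo-species)",
    "pohcap":  "Propanol-branch capacity token",
    "butcap":  "Butyrate-branch capacity token",
    "nadpcap": "NADP-acetaldehyde-dehydrogenase capacity token",
    "budget":  "Total carbon-uptake budget token",
}

# (id, name, stoichiometry-stub, (lb, ub), gene_rule, subsystem, ec)
_RXN_TABLE = [
    ("rxn00543_c0", "Alcohol dehydrogenase (AdhE, NAD+)",
     {"etoh": -1, "nad": -1, "acald": 1, "nadh": 1, "h": 1}, (0, BIG),
     "CLNEO_13930 or CLNEO_16910 or CLNEO_00480", "Ethanol oxidation", "1.1.1.1"),
    ("rxn00171_c0", "Acetaldehyde dehydrogenase (AdhE, NAD+)",
     {"acald": -1, "coa": -1, "nad": -1, "accoa": 1, "nadh": 1, "h": 1}, (0, BIG),
     "CLNEO_13930", "Ethanol oxidation", "1.2.1.10"),
    ("rxn00172_c0", "Acetaldehyde dehydrogenase (NADP+)",
     {"acald": -1, "coa": -1, "nadp": -1, "accoa": 1, "nadph": 1, "h": 1},
     (0, BIG),
     "", "Ethanol oxidation", "1.2.1.4"),
    ("rxn00173_c0", "Phosphate acetyltransferase (Pta)",
     {"accoa": -1, "pi": -1, "actp": 1, "coa": 1}, (-BIG, BIG),
     "CLNEO_28570", "Acetate production", "2.3.1.8"),
    ("rxn00225_c0", "Acetate kinase (Ack)",
     {"actp": -1, "adp": -1, "ac": 1, "atp": 1}, (-BIG, BIG),
     "CLNEO_28580", "Acetate production", "2.7.2.1"),
    ("rxn05938_c0", "Pyruvate:ferredoxin oxidoreductase (PFOR)",
     {"pyr": -1, "coa": -1, "fdox": -1, "accoa": 1, "co2": 1, "fdred": 1,
      "h": 1}, (-BIG, BIG),
     "CLNEO_15240 or CLNEO_19010 or CLNEO_17780 or CLNEO_03040 or "
     "CLNEO_04330 or CLNEO_24550", "Pyruvate synthesis", "1.2.7.1"),
    ("rxn00500_c0", "D-lactate dehydrogenase (NAD+)",
     {"pyr": -1, "nadh": -1, "h": -1, "lac__D": 1, "nad": 1}, (-BIG, BIG),
     "CLNEO_28010", "Acrylate pathway", "1.1.1.28"),
    ("rxn01056_c0", "Propionate-CoA:lactoyl-CoA transferase (Pct)",
     {"lac__D": -1, "ppcoa": -1, "laccoa": 1, "ppa": 1}, (0, BIG),
     "CLNEO_17700", "Acrylate pathway", "2.8.3.1"),
    ("rxn02123_c0", "Lactoyl-CoA dehydratase",
     {"laccoa": -1, "acrcoa": 1, "h2o": 1}, (-BIG, BIG),
     "CLNEO_17710 and CLNEO_17720", "Acrylate pathway", "4.2.1.54"),
    ("rxn40050_c0", "Acryloyl-CoA reductase (Acr-EtfAB, non-bifurcating)",
     {"acrcoa": -1, "nadh": -1, "h": -1, "ppcoa": 1, "nad": 1}, (0, BIG),
     "CLNEO_21740 and CLNEO_21750 and CLNEO_21760", "Acrylate pathway",
     "1.3.1.95"),
    ("PCT2_c0", "Propionyl-CoA:acetate CoA-transferase (ydiF)",
     {"ppa": -1, "accoa": -1, "ppcoa": 1, "ac": 1}, (0, BIG),
     "CLNEO_17700", "Propanol branch", "2.8.3.1"),
    ("Rnf_c0", "Ferredoxin:NAD+ oxidoreductase (Rnf, 2 cations per Fd)",
     {"fdred": -1, "nad": -1, "h": -3, "fdox": 1, "nadh": 1, "h_p": 2},
     (-BIG, BIG),
     "CLNEO_01390 and CLNEO_01400 and CLNEO_01350 and CLNEO_01360 and "
     "CLNEO_01380 and CLNEO_01370", "Energy conservation", "7.2.1.2"),
    ("rxn10042_c0", "V-type ATPase (coupling_ratio cations per ATP)",
     None, (-BIG, BIG),  # stoichiometry filled from config
     "CLNEO_00280 and CLNEO_00290 and CLNEO_23400", "Energy conservation",
     "7.1.2.2"),
    ("Nfn_c0", "NADH-dependent reduced ferredoxin:NADP+ oxidoreductase (Nfn)",
     {"fdred": -1, "nadh": -1, "nadp": -2, "h": -1,
      "fdox": 1, "nad": 1, "nadph": 2}, (-BIG, BIG),
     "CLNEO_00270 and CLNEO_00280", "Energy conservation", "1.6.1.4"),
    ("ACS_c0", "Acetate:CoA ligase (AMP-forming, lumped to 2 ATP->ADP)",
     {"ac": -1, "atp": -2, "coa": -1, "h2o": -1,
      "accoa": 1, "adp": 2, "pi": 2, "h": 1}, (0, BIG),
     "", "Acetate assimilation", "6.2.1.1"),
    ("rxn09944_c0", "Propionaldehyde dehydrogenase (AdhE)",
     {"ppcoa": -1, "nadh": -1, "h": -1, "ppal": 1, "coa": 1, "nad": 1},
     (0, BIG), "CLNEO_13930", "Propanol branch", "1.2.1.87"),
    ("rxn01710_c0", "Propanol dehydrogenase (AdhE)",
     {"ppal": -1, "nadh": -1, "h": -1, "poh": 1, "nad": 1}, (0, BIG),
     "CLNEO_13930 or CLNEO_16910 or CLNEO_00480", "Propanol branch", "1.1.1.1"),
    ("rxn00178_c0", "Acetoacetyl-CoA thiolase",
     {"accoa": -2, "aacoa": 1, "coa": 1}, (-BIG, BIG),
     "", "Butyrate branch", "2.3.1.9"),
    ("rxn03861_c0", "3-oxoacyl reductase (NADPH)",
     {"aacoa": -1, "nadph": -1, "h": -1, "hbcoa": 1, "nadp": 1}, (0, BIG),
     "", "Butyrate branch", "1.1.1.36"),
    ("rxn03874_c0", "3-hydroxyacyl dehydratase (crotonase)",
     {"hbcoa": -1, "b2coa": 1, "h2o": 1}, (-BIG, BIG),
     "", "Butyrate branch", "4.2.1.55"),
    ("rxn00868_c0", "Butyryl-CoA dehydrogenase (Bcd-EtfAB, electron-bifurcating)",
     {"b2coa": -1, "nadh": -2, "fdox": -1, "btcoa": 1, "nad": 2, "fdred": 1},
     (0, BIG), "CLNEO_29850 and CLNEO_29840", "Butyrate branch", "1.3.1.109"),
    ("rxn00875_c0", "Butyryl-CoA:acetate CoA-transferase (Pct)",
     {"btcoa": -1, "ac": -1, "but": 1, "accoa": 1}, (-BIG, BIG),
     "CLNEO_17700", "Butyrate branch", "2.8.3.8"),
    ("rxn00062_c0", "ATP phosphohydrolase (non-growth maintenance)",
     {"atp": -1, "h2o": -1, "adp": 1, "pi": 1, "h": 1}, (0, BIG),
     "", "Maintenance", "3.6.1.3"),
    ("rxn05759_c0", "Ferredoxin hydrogenase",
     {"fdred": -1, "h": -2, "h2": 1, "fdox": 1}, (0, BIG),
     "CLNEO_18070", "Energy conservation", "1.12.7.2"),
]


def build_core_model(config: ModelConfig | None = None,
                     composition: BiomassComposition | None = None
                     ) -> MetabolicModel:
    """Assemble the core ethanol-fermentation model from the reaction table."""
    cfg = config or ModelConfig()
    comp = composition or default_composition(gam=cfg.gam)
    model = MetabolicModel(id="iANEO_core", compartments=("c0", "e0"))

    for stub, (name, formula, charge) in _MET_TABLE.items():
        model.add_metabolite(Metabolite(stub + "_c0", name, formula, charge, "c0"))
    for stub, name in _PSEUDO.items():
        model.add_metabolite(Metabolite(stub + "_c0", name, None, 0, "c0"))
    for stub in _EXTERNAL:
        name, formula, charge = _MET_TABLE[stub]
        model.add_metabolite(Metabolite(stub + "_e0", name, formula, charge, "e0"))

    n = cfg.coupling_ratio
    ref = cfg.reference_uptake
    for rid, name, sto, (lb, ub), gpr, subsystem, ec in _RXN_TABLE:
        if rid == "rxn10042_c0":
            # ATP synthesis direction: n translocated cations drive
            # ADP + Pi + H+ -> ATP + H2O; hydrolysis is the reverse
            sto = {"adp": -1, "pi": -1, "h_p": -n, "atp": 1, "h2o": 1,
                   "h": n - 1}
        if rid == "Rnf_c0" and cfg.energy_decoupled:
            name = "Ferredoxin:NAD+ reductase (uncoupled)"
            sto = {"fdred": -1, "nad": -1, "h": -1, "fdox": 1, "nadh": 1}
        if rid == "rxn00543_c0":
            sto = dict(sto)
            # capacity tokens: cap emitted per ethanol, reference_uptake
            # consumed per capped-branch unit, i.e. v_branch <= cap/ref * v_etoh
            sto["pohcap"] = cfg.propanol_cap
            sto["butcap"] = cfg.butyrate_cap
            sto["nadpcap"] = cfg.nadp_acald_cap
        if rid == "rxn00172_c0":
            sto = dict(sto)
            sto["nadpcap"] = -ref
        if rid == "rxn00062_c0":
            lb = cfg.ngam
        if rid == "rxn05759_c0" and cfg.hydrogenase_blocked:
            lb, ub = 0.0, 0.0
        model.add_reaction(Reaction(
            id=rid, name=name,
            stoichiometry={k + "_c0": v for k, v in sto.items()},
            lower_bound=lb, upper_bound=ub,
            gene_rule=gpr, subsystem=subsystem, ec=ec, kind="metabolic",
        ))

    model.add_reaction(build_biomass_reaction(comp))

    # transports (electroneutral diffusion of the free acids / species);
    # uptake-capable carbon substrates consume the uptake-budget token, so a
    # single bound on SRC_budget limits total substrate uptake in screens
    def _transport(rid, name, sto, lb, ub):
        model.add_reaction(Reaction(
            id=rid, name=name, stoichiometry=sto, lower_bound=lb,
            upper_bound=ub, subsystem="Transport", kind="transport"))

    for stub in _EXTERNAL:
        sname = _MET_TABLE[stub][0]
        e, c = stub + "_e0", stub + "_c0"
        if stub == "etoh":
            # uptake only; ethanol is never secreted by this network
            _transport("T_etoh", "Ethanol uptake",
                       {e: -1.0, c: 1.0, "budget_c0": -1.0}, 0.0, BIG)
        elif stub in ("lac__D", "pyr", "ac"):
            # split uptake/export so only uptake draws on the budget
            _transport(f"T_{stub}", f"{sname} uptake",
                       {e: -1.0, c: 1.0, "budget_c0": -1.0}, 0.0, BIG)
            _transport(f"T_{stub}_out", f"{sname} export",
                       {c: -1.0, e: 1.0}, 0.0, BIG)
        elif stub in ("poh", "but"):
            # overflow exits: export only, capacity-token limited
            tok = "pohcap_c0" if stub == "poh" else "butcap_c0"
            _transport(f"T_{stub}", f"{sname} export",
                       {c: -1.0, e: 1.0, tok: -ref}, 0.0, BIG)
        else:  # co2, h2, h2o, h: free diffusion
            _transport(f"T_{stub}", f"{sname} diffusion",
                       {e: -1.0, c: 1.0}, -BIG, BIG)

    # budget source and capacity-token sinks
    model.add_reaction(Reaction(
        id="SRC_budget", name="Carbon-uptake budget source",
        stoichiometry={"budget_c0": 1.0}, lower_bound=0.0, upper_bound=BIG,
        subsystem="Pseudo", kind="metabolic"))
    for tok in ("pohcap", "butcap", "nadpcap"):
        model.add_reaction(Reaction(
            id=f"DM_{tok}", name=f"Surplus {tok} sink",
            stoichiometry={tok + "_c0": -1.0}, lower_bound=0.0, upper_bound=BIG,
            subsystem="Pseudo", kind="metabolic"))

    # exchanges: written "met_e0 ->", negative flux = uptake
    for stub in _EXTERNAL:
        model.add_reaction(Reaction(
            id=f"EX_{stub}_e0", name=f"{_MET_TABLE[stub][0]} exchange",
            stoichiometry={stub + "_e0": -1.0},
            lower_bound=-BIG, upper_bound=BIG,
            subsystem="Exchange", kind="exchange"))

    model.objective_id = "biomass_c0"
    model.objective_sense = "maximize"
    model.validate()
    return model


# ---------------------------------------------------------------------------
# condition helpers
# ---------------------------------------------------------------------------

def seal_exchanges(model: MetabolicModel,
                   keep_free: tuple[str, ...] = ("co2", "h2o", "h")
                   ) -> MetabolicModel:
    """Close all exchanges except freely diffusible small species."""
    for rxn in model.reactions.values():
        if rxn.kind != "exchange":
            continue
        stub = rxn.id[3:-3]  # EX_<stub>_e0
        if stub in keep_free:
            rxn.bounds = (-BIG, BIG)
        else:
            rxn.bounds = (0.0, 0.0)
    return model


def open_fermentation_products(model: MetabolicModel) -> MetabolicModel:
    """Allow secretion (not uptake) of the fermentation end products."""
    for stub in ("ac", "ppa", "poh", "but", "lac__D", "h2"):
        rxn = model.reactions[f"EX_{stub}_e0"]
        rxn.bounds = (0.0, BIG)
    return model


def disable_growth(model: MetabolicModel, ngam: float | None = 0.0
                   ) -> MetabolicModel:
    """Clamp biomass flux to zero (and optionally reset the NGAM bound)."""
    model.reactions["biomass_c0"].bounds = (0.0, 0.0)
    if ngam is not None:
        model.reactions["rxn00062_c0"].bounds = (ngam, BIG)
    return model
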
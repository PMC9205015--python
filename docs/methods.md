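# Methods

## Scope

`aneofba` models the central carbon and energy metabolism of the
ethanol-fermenting, propionate-producing anaerobe *Anaerotignum
neopropionicum*. The organism ferments ethanol and CO2 to propionate and
acetate through the acrylate pathway; the theoretical stoichiometry is

    3 CH3CH2OH + 2 CO2 -> 2 CH3CH2COO- + CH3COO- + 3 H+ + H2O

but cultures realise a propionate:acetate ratio near 1.2 rather than 2. The
package provides (i) a small constraint-based solver stack (FBA, FVA,
hit-and-run sampling) on a plain `S v = 0, lb <= v <= ub` polytope, (ii) a
curated ~30-reaction core model of the fermentation, (iii) a dynamic-FBA
batch simulator with Michaelis–Menten uptake, (iv) biomass-composition and
GAM sensitivity analyses, (v) steady-state phenotype screening, (vi) the
energetic analysis that explains the sub-theoretical ratio, and (vii) a
synthetic batch-data generator with kinetic-parameter estimators.

## The core network

Reactions carry ModelSEED-style ids where those are established
(`rxn00543_c0` alcohol dehydrogenase, `rxn01056_c0` Pct, `Rnf_c0`,
`rxn10042_c0` V-ATPase, ...), with locus-tag gene rules. All metabolic
reactions are elementally and charge balanced against explicit formulas; the
biomass reaction and pseudo-species reactions are tagged and exempt.

Pathway modules:

- **Ethanol oxidation.** NAD+-dependent AdhE (ethanol -> acetaldehyde ->
  acetyl-CoA). A second, NADP+-dependent acetaldehyde dehydrogenase
  (`rxn00172_c0`) is included with a capacity bound (aldehyde dehydrogenases
  are generically NAD(P)-dependent); its NADPH feeds electron confurcation
  (below). Both oxidations are irreversible, which rules out
  transhydrogenase loops.
- **Acetate kinase SLP.** Pta/Ack, reversible; the only substrate-level
  phosphorylation of the network.
- **Pyruvate node.** Reversible PFOR (`rxn05938_c0`): on ethanol it runs
  carboxylating (acetyl-CoA + CO2 + Fd2- -> pyruvate), on lactate and
  pyruvate it runs decarboxylating and *produces* reduced ferredoxin.
- **Acrylate cycle.** NAD-specific D-LDH, Pct
  (lactate + propionyl-CoA -> lactoyl-CoA + propionate), lactoyl-CoA
  dehydratase, and the irreversible, non-bifurcating Acr-EtfAB
  (acryloyl-CoA + NADH -> propionyl-CoA). Propionyl-CoA is catalytic in this
  cycle, so a propionyl-CoA:acetate CoA-transferase
  (`PCT2_c0`: propionate + acetyl-CoA -> propionyl-CoA + acetate, the
  annotated activity of the ydiF transferase) supplies the net propionyl-CoA
  that the propanol branch drains; without it the branch is structurally
  dead at steady state.
- **Energy conservation.** Rnf translocates 2 cations per Fd2-
  oxidised; the V-type ATPase couples `coupling_ratio` cations per ATP
  (default 3.5, fit range [3, 3.5]; fractional values allowed). The
  periplasmic proton is a pseudo-species appearing only in these two
  reactions, so `2 v_Rnf = n v_ATPase` in every steady state. Nfn is the
  reversible electron-confurcating NADH-dependent reduced
  ferredoxin:NADP+ oxidoreductase. The ferredoxin hydrogenase is present
  but closed (H2 is neither formed nor consumed in cultivation).
- **Overflow branches.** Propanol (propionyl-CoA -> propionaldehyde ->
  1-propanol, 2 NADH) and butyrate (thiolase, NADPH-dependent 3-oxoacyl
  reductase, crotonase, butyryl-CoA dehydrogenase, butyryl-CoA:acetate
  CoA-transferase). The crotonyl-CoA reduction is modelled as
  electron-bifurcating Bcd-EtfAB (2 NADH + Fd_ox -> butyryl-CoA + Fd2-);
  whether this complex reduces ferredoxin in vivo is an open question, and
  the bifurcating form is the variant under which the coupled model is
  viable (see the ATP budget below).
- **Maintenance.** NGAM as an ATP phosphohydrolase flux floor
  (8.4 mmol ATP gDW-1 h-1); GAM (40 mmol ATP per g biomass) inside the
  biomass reaction.
- **Transport/exchange.** Electroneutral diffusion of the free acids (no
  proton-export cost); exchanges follow the convention `met_e0 ->` with
  negative flux = uptake.

### Capacity tokens and the uptake budget

Three capacities — the propanol exit, the butyrate exit and the
NADP-acetaldehyde dehydrogenase — are limited *per mole of ethanol
oxidised*. `ModelConfig` states them as absolute rates at the reference
uptake of 36.2 mmol gDW-1 h-1 (defaults 5.0, 2.5 and 33.0); internally the
committed AdhE step emits pseudo-metabolite "capacity tokens" consumed by
the capped reactions (surplus drains freely), which implements
`v_branch <= cap/36.2 * v_ethanol` without leaving the `S v = 0` form and
makes branch use scale correctly along a batch as uptake declines.
Similarly, carbon-substrate uptake transports consume a "budget" token from
a bounded source reaction, so a single bound expresses a *total* uptake
limit for multi-substrate screens.

### Biomass

The biomass reaction is normalised to 1 g dry weight per mmol of flux, so
its flux equals the specific growth rate in h-1. It consumes lumped
precursors (acetyl-CoA, pyruvate, NADPH) and ATP derived from the
macromolecular composition through a per-gram precursor table
(`PRECURSOR_TABLE`). The default composition (protein 0.53, phospholipid
0.08, teichoic acid 0.12, peptidoglycan 0.12, carbohydrate 0.05, DNA 0.03,
RNA 0.06, trace 0.01; DNA+RNA+trace = 0.10) and the precursor table are
constructed placeholders in the style of clostridial models — the
organism-specific composition has not been measured. The ATP coefficient is
GAM + polymerisation cost (11.87 mmol per g at the default composition);
with GAM = 0 only the polymerisation term remains. Default demands:
5.49 acetyl-CoA, 7.87 pyruvate, 8.02 NADPH mmol per g
(~35 mmol C per g, ≈0.42 g C per g biomass).

## Energetics of the propionate:acetate ratio

On ethanol, every NADH balance closes as `2 e = 3 p + 5 w + 2 u + ...`
(e ethanol, p propionate, w propanol, u butyrate): with the minor branches
closed the ratio is *forced* to exactly 2:1 by redox alone — that is the
theoretical stoichiometry, and `theoretical_max_ratio` returns it exactly.

Growth, however, needs net ATP, and the only ATP source on ethanol is
acetate kinase. Each propionate requires one Fd2- at PFOR; bought through
the reverse Rnf it costs `2/n` ATP. At the forced 2:1 ratio the net ATP per
acetate is `1 - 4/n`, negative for any coupling ratio n < 4: on the strict
network (no NADP route, no bifurcation) growth on ethanol is infeasible for
the physiological coupling range, which is precisely why the theoretical
ratio cannot be realised. The package therefore keeps two paper-consistent
relief valves: the capacity-bounded NADP-acetaldehyde route (NADPH + Nfn
reverse delivers Fd2- without touching the ion gradient) and the
bifurcating Bcd-EtfAB. Both are bounded so that the *marginal* Fd2- still
comes from the reverse Rnf — the central mechanistic claim — and the
growth optimum lands at a propionate:acetate ratio of ≈1.17 with the Rnf
running backwards and the ATPase hydrolysing ATP on ethanol, and the exact
opposite signs on D-lactate (`atp_accounting` reports the partition;
the two directions are asserted in the test suite).

Consequences worth knowing:

- The NADP-route capacity (33.0 at reference uptake) is deliberately below
  the level (≈33.6) at which the branch-free network would become feasible
  at n = 4; this preserves the strict-network infeasibility property while
  letting the calibrated model grow at n in [3, 3.5].
- Maximum net ATP is ≈0.24 mmol per mmol ethanol, so the NGAM floor of 8.4
  puts the growth break-even near an ethanol uptake of 34.7 mmol gDW-1 h-1.
  Ethanol-based conditions therefore default to the empirical maximum uptake
  measured on ethanol (36.2) rather than the generic screening bound of 30,
  which would sit below break-even.
- The same budget caps the growth yield at Y_X/S ≈ 0.16 g per mol ethanol.
  The cultivations report 1.6 g/mol and a 44 mg/L biomass peak; the core
  model cannot reach these while keeping the reverse-Rnf mechanism and
  GAM/NGAM at their stated values, and its simulated biomass peaks an order
  of magnitude lower. This is the model's principal known limitation and is
  deliberately left visible (one failing check) rather than papered over;
  product concentrations and ratios, which are yield-driven, are unaffected.
- The calibrated branch capacities put propanol at ~35% and butyrate at
  ~18% of the propionate flux — "minor products", but larger than the
  observed 14% / 10%. Tightening them to the observed proportions raises
  the ratio to ≈1.9; the calibration prioritises the ratio.

## Dynamic FBA

Forward Euler with dt = 0.1 h by default; a dt-halving convergence check is
part of the suite (final concentrations move < 1%). Per step the ethanol
exchange lower bound is `-min(q_max S/(Km+S), S/(X dt))` (the second term
forbids overshoot below zero), CO2 is non-limiting (headspace excess; its
"concentration" tracks the net cumulative draw and may run negative), and
FBA maximises biomass. If growth is infeasible or below 1e-6 h-1 — which
happens when uptake falls under the maintenance break-even, i.e. "at low
ethanol concentration" — the step re-solves with the ATP phosphohydrolase
as objective (NGAM floor relaxed to zero, biomass clamped); once ethanol is
numerically exhausted the switch is permanent. Carbon bookkeeping over a
trajectory closes to machine precision at the stored step sizes.

Scenario inputs are the empirical kinetics of each cultivation condition:
q_S,max 36.2 (ethanol) / 43.3 (ethanol + 10 mM acetate) mmol gDW-1 h-1,
mu_max caps 0.082 / 0.098 h-1, initial 25 mM ethanol (± 10/25 mM acetate),
X0 = 2.8 mg/L (inoculation OD600 ≈ 0.025 via the calibration below), 300 h
horizon. Km is not measured; the default 0.5 mM is the value recovered by
`fit_km` self-consistency and must stay well below ~8 mM for any growth
phase to exist at all (see break-even above). Lag phase is not modelled; no
death phase is modelled.

## Sensitivity analyses

Protein and phospholipid fractions are drawn uniformly within ±10% (the
distribution is a package choice; only "randomly selected" is specified);
the cell-wall total closes the composition
(`wall = 1 - protein - plipids - (DNA+RNA+trace)`) and is split among
teichoic acid, peptidoglycan and carbohydrate in their original proportions;
DNA, RNA, trace are fixed. Each of n draws (default 1000) rebuilds the
biomass reaction, re-solves FBA at fixed ethanol uptake (36.2, CO2 free) and
records rates normalised to the unperturbed run; ±10% draws move the
calibrated model's growth and production rates by < 1.5%. GAM sensitivity
draws GAM uniformly within ±20% at fixed composition; growth is
non-increasing in GAM (an LP monotonicity fact) and moves by roughly ±12%.

## Synthetic batch data and estimation

`generate_batch` samples a trajectory at given times, converts biomass to
OD600 via `mg_CDW/L = (OD600 - 0.016)/0.0032`, adds seeded additive
Gaussian noise (defaults: 0.004 OD units; 0.3 mM on HPLC species, matched
to the scatter of the growth curves at the core model's biomass scale), and
censors concentrations below the 0.2 mM quantification floor (reported at
the floor, flagged as trace). The generator emulates the bottle
cultivations' sampling and analytics; it does not emulate lag or death
phases, ethanol evaporation, gas-phase measurements, pH drift or
replicate-level batch effects — passing recovery tests demonstrates
estimator correctness under the stated noise model, not robustness to those
real-data features.

Estimators: `estimate_mu_max` scans contiguous log-linear windows (≥4
points, R² ≥ 0.98) and returns the steepest slope among near-maximal-length
windows, which is exact on a pure exponential and excludes deceleration
tails. `estimate_qs_max` uses the balanced-growth identity dS/dX = -q/mu:
it regresses S on X over the saturated part of the exponential window and
scales by the fitted mu — a windowed rate estimate that avoids the upward
selection bias of a max-of-differences rule. `fit_km` refits the batch
simulator to an ethanol curve by bounded golden-section search on log Km in
[0.01, 50] mM, flagging boundary solutions as non-identifiable. An
idealised `kinetic_trajectory` (constant-mu exponential phase + MM
depletion + fixed product yields, no LP) provides ground-truth curves at
the empirical scale for recovery studies: over 100 seeds at default noise,
mu is recovered within 10% in ≥95 seeds and q_S,max within 10% in the
aggregate. Yields are endpoint quotients on consumed substrate (Y_X/S in
g/mol using the biomass maximum, Y_P/S and Y_A/S in mol/mol).

## Numerical choices

LP: scipy HiGHS with primal/dual feasibility tolerances of 1e-9; "blocked"
means |min| and |max| below 1e-9 at fraction-of-optimum 0. Degenerate
alternate optima: scientific ratio/profile numbers are reported either from
a lexicographic solve (maximise the objective, then minimise total absolute
flux) or from hit-and-run sampling means; the two agree on the calibrated
model and the acceptance script cross-checks them. The sampler runs in a
null-space basis of S with isotropic directions and uniform chord steps,
1000 warm-up steps discarded, thinning 10, seeded and reproducible; sampler
parameters are package choices (only the method family is prescribed).
SBML I/O is Level 3 Version 1 with the fbc (v2) package through
python-libsbml; round-trips preserve ids, stoichiometry, bounds, gene rules
and kinds exactly (capacity-token coefficients are stated in exact decimal
form for this reason). The JSON dialect is documented in `aneofba.io`.

## Known limitations

- Biomass yield and peak-biomass underprediction on ethanol (see above).
- Biomass composition and precursor coefficients are placeholders.
- Minor-product proportions overshoot the observations at the calibrated
  branch capacities.
- No thermodynamic (non-standard-state) corrections; the -124 kJ reference
  free energy and the 32/25 Fd-per-ATP bound are reported constants, not
  recomputed.
- L- vs D-lactate: only D-lactate is in the network; slow L-lactate
  metabolism cannot be excluded biologically and screens report L-lactate
  as "not in network" rather than negative.
- Substrates outside the reduced network (sugars, amino acids) are
  untestable here; they belong to the full genome-scale model, which this
  package loads from SBML but does not reconstruct.
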
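# Methods

## Scope and model

`vitiflux` performs steady-state flux estimation for heterotrophic
plant-cell suspensions. The system is one average cell in a homogeneous
culture during exponential growth; there is no kinetics, no
compartment-resolved transport (compartment tags are informational
only), and no thermodynamic (ΔG) constraint beyond fixed reaction
directions. The state is a flux vector v (mmol g DW⁻¹ day⁻¹) over the n
reactions of a stoichiometric network; internal metabolites — including
all cofactors — satisfy N v = 0.

### The GT3 reconstruction

`build_gt3_network()` encodes glycolysis, the TCA cycle, the oxidative
pentose-phosphate pathway, starch and sucrose metabolism, nitrate
assimilation (NR+NiR lumped, GS/GOGAT, two aminotransferases), the
shikimate route to phenylalanine, and the phenylpropanoid/flavonoid
branch down to four end-product classes (anthocyanins, flavonols,
condensed tannins, stilbenes), plus lumped biomass syntheses (cell
wall, protein, lipid, nucleic acid, starch) and accumulation exchanges
for stored solutes. Design choices a reader should know:

* **Lumping.** Multi-step segments with no internal branch point are
  single reactions (aldolase+TPI, GAPDH+PGK, PGM+enolase,
  aconitase+IDH, KGDH+SCS, SDH+fumarase, both PPP dehydrogenases,
  DAHP-synthase→shikimate-dehydrogenase, shikimate→phenylalanine via
  arogenate, C4H+4CL, ANS+UFGT, F3H+F3′H). Each lump conserves carbon,
  nitrogen and phosphate exactly; the `check_consistency` report
  verifies that strictly positive conservation weights exist for every
  internal + maintenance reaction (solved as a small LP feasibility
  problem). Lumped *biomass* reactions (kind `overall`) use empirical
  compositions and are exempt from that test, as are exchanges.
* **Oxidative phosphorylation in ATP units.** Vnrj1 (NADH-linked) and
  Vnrj2 (FADH₂-linked) are written per mol ATP synthesized — Vnrj1
  oxidizes 1/2.5 NADH per ATP, Vnrj2 1/1.5 FADH₂ per ATP, with the P/O
  ratios configurable — so that flux(Vnrj1) + flux(Vnrj2) *is* the
  ATP-synthesis rate derived from respiration measurements and the
  coupling constraint needs no conversion factor.
* **Maintenance.** Vnga-ATPm hydrolyzes surplus ATP; it is the only
  unconstrained ATP sink, so the energy balance closes at any feasible
  respiration rate at or above the demand floor.
* **Phosphate uptake.** Nucleic acids export one phosphate per
  nucleotide (carried in by ribose-5-P). Without a medium phosphate
  source the phosphate moiety would be a strictly decreasing conserved
  quantity and any positive nucleic-acid synthesis would be infeasible
  — the Farkas certificate of exactly that failure motivated the
  explicit Vpi-up exchange.
* **Irreversibility.** 33 non-exchange reactions are irreversible: the
  kinases, PFK, pyrophosphatase, PDH, citrate synthase, IDH, KGDH,
  malic enzyme, PEPC, G6PDH, SPS, the nitrogen-assimilation steps,
  the shikimate/phenylpropanoid entry steps (Vshik, Vphe-syn, Vpal,
  Vcoum, Vmacl), both oxidative phosphorylation steps, maintenance,
  and the nine overall biosyntheses. The three flavonoid
  interconversions around naringenin, dihydroquercetin and
  leucocyanidin (Vnar, Vdhq, Vlcc) are reversible, as are the
  glycolytic isomerases/mutases, PPi-PFK, GAPDH, enolase, SDH, MDH,
  the non-oxidative PPP, the aminotransferases, adenylate kinase and
  the uridylate housekeeping steps. Exchange reactions are
  unidirectional as well but are not counted in that figure, which
  refers to reactions *of* the network.
* **Ammonium** is not a nitrogen source (its medium concentration is
  an order of magnitude below nitrate's); PAL-released NH₄⁺ is
  re-assimilated by GS.
* **Protein composition** defaults to equal-molar over the four
  modeled amino acids (Glu, Asp, Ala, Phe) at 4.3 ATP per residue;
  both are constructor arguments because bulk composition is
  culture-specific.

### From measurements to constraints

* μ is the slope of a log-linear least-squares fit of biomass vs time
  (default window: all timepoints up to the evaluation day); the fit R²
  is reported so a user can see when the exponential assumption is
  breaking down.
* Accumulation fluxes: v = c · μ with c converted mg → mmol via the
  molar mass when the assay is mass-based. These fluxes are applied as
  equality bounds (lb = ub), matching the resolution strategy of fixing
  measured exchanges; measurement SE is deliberately not propagated
  (see Limitations).
* Enzyme capacities cap fluxes at +capacity (and −capacity for
  reversible steps). Unknown capacities leave the flux unbounded:
  bounds are kept as ±inf all the way into the solver rather than being
  replaced by a large finite cap — the quadratic objective is coercive,
  so infinite bounds are exact and cost nothing, and no post-hoc
  "near the artificial cap" check is needed.
* The respiration constraint is an equality at the measured mean by
  default; `respiration_mode="interval"` widens it to mean ± SE. The
  equality is correct for internally consistent (e.g. noise-free or
  averaged) data; with independently noisy inputs, seventeen fixed
  exchange equalities plus a fixed respiration equality are almost
  surely jointly inconsistent, so the noisy synthetic pipeline switches
  to the interval automatically.

### Flux minimization

The resolution principle is parsimony: among all flux distributions
consistent with the constraints, take the one minimizing Σ wᵢvᵢ²
(weights default to 1 and must be positive). Strict convexity makes the
minimizer unique, which is what licenses comparing two conditions
flux-by-flux. All fluxes enter the objective; fixed fluxes contribute
constants and cannot move the argmin. A weighted-L1 variant
(`objective="l1"`, solved as an LP) is available for comparison but is
not the default because its minimizer need not be unique.

`minimize_flux` is a primal active-set method: a phase-1 LP
(scipy/HiGHS) finds a feasible point or certifies infeasibility;
equality-constrained subproblems are solved exactly through their KKT
systems (lstsq on the bordered matrix, so redundant balance rows are
harmless); bound multipliers decide which constraint to release.
Variables fixed by lb = ub are eliminated before the solve for
conditioning. Default tolerances: primal feasibility 1e-9, optimality
(KKT stationarity) 1e-8 relative; ties in the blocking/releasing rules
break toward the lowest index for determinism. Failure modes are
explicit: `infeasible` is LP-certified and `numerical-failure` reports
residuals — a near-solution is never returned silently as optimal.

Verification instruments, all independent of the solve path:

* `solve_oracle_small` enumerates every active-set assignment (each
  variable free / at lower / at upper bound) for problems of ≤ 12
  variables and solves each candidate in closed form — a brute-force
  global optimizer used as the test oracle;
* `check_kkt` recomputes multipliers by least squares from a solution
  alone and reports stationarity, primal feasibility, complementarity
  and multiplier-sign residuals;
* `diagnose_infeasibility` solves an elastic LP (slack on every fixed
  exchange and coupling row, hard mass balance and directionality) and
  ranks the constraints that must move, by how much.

## The synthetic-data generator

The generator exists so that every pipeline stage is testable without
the study's raw data. It emulates the study design: sampling at days
0, 4, 6, 8 and 11 post-inoculation; exponential growth from
X₀ = 1.6 g DW L⁻¹ at μ = 0.288 day⁻¹ (the day-4 value; day-6 analyses
use 0.160 day⁻¹); ~17 measured accumulation components; nine assayed
enzyme capacities; a respiration-derived ATP-synthesis rate near
3.5 (control) / 2.9 (low N) mmol g DW⁻¹ day⁻¹.

`make_scenario` draws exchange-flux targets uniformly from
physiological ranges (documented in `synth.DEFAULT_EXCHANGE_RANGES`;
overrides pin individual fluxes to build contrasts), fixes them, and
solves the flux-minimization problem; the optimum is the ground truth
v_true. Because v_true is the minimum-norm point of its own constraint
set, the pipeline is a left inverse of the generator: at zero noise the
recovered flux map equals v_true to the solver tolerance — an exactness
check, not a statistical one. `simulate_measurements` then inverts the
constraint conversion (c = v/μ, biomass X₀e^{μt}, capacities a random
factor 1.5–4 above |v_true|, ATP rate = true Vnrj1+Vnrj2), applying
multiplicative lognormal noise with chosen CV to every observation
(concentrations are positive and assay error is relative-error
dominated; the lognormal is mean-one so estimates stay unbiased). All
randomness flows through one seeded `numpy` generator.

The fixed `study_measurements` tables encode the two nutritional
conditions as noise-free compositions chosen so the measured components
cover 81% (control) and 91% (low N) of dry biomass, with the
low-nitrogen reorganization: anthocyanins, tannins, stilbenes, hexoses
and starch up; protein, sucrose, malate, free amino acids and
respiration down. These tables drive the worked example and the
direction-of-change tests. What the generator does **not** emulate:
between-replicate biological variance structure, day-to-day
non-steady-state transitions, measurement bias, or the real (deposited)
stoichiometry of the study's model — so passing tests demonstrate
correctness of the machinery and qualitative transferability of the
flux reorganization, not quantitative reproduction of any particular
culture's flux values.

## Numerical conventions and edge cases

* Percent change between conditions is 100·(v_t − v_c)/|v_c|; entries
  with |v_c| < 1e-9 are flagged undefined rather than ±∞, and sign
  flips are flagged separately instead of being folded into a
  percentage. Classification uses a ±5% dead band between "unchanged"
  and "in/decreased" (the qualitative maps distinguish maintained from
  changed fluxes without a published threshold; 5% is well above
  solver noise and well below any reported change).
* Ledgers (cofactor or any internal metabolite) report signed
  stoichiometry × flux per reaction; at any optimum they net to zero
  within 1e-8·(1+max|v|), a direct consequence of the balanced row.
* α-KG branch shares are fractions of total consumption; they are
  non-negative and sum to one whenever total consumption is positive.
* Graph exports draw zero-flux reactions at minimum edge width rather
  than omitting them, so absence of flux is visible.
* Table and SBML round-trips are lossless; exact stoichiometric
  coefficients ride in SBML notes because the XML attribute carries
  only 15 significant digits.

## Problem sizes used by the test suite and acceptance script

Random solver-vs-oracle instances use 8 reactions × 4 metabolites (the
oracle enumerates up to 3⁸ active sets per instance; 200 instances run
in ~10 s). Recovery studies use the full 67-reaction reconstruction
with 5 noisy replicate scenarios at CV 5% and fixed seeds. These sizes
were chosen so the whole suite runs in well under a minute while every
code path — bounds of all kinds, couplings, infeasibility, interval
mode — is exercised.

## Known limitations

* No error propagation from measurement SE to flux confidence
  intervals; the fixed-exchange equality strategy reports point
  estimates only.
* The L1 objective is provided for comparison but without a uniqueness
  guarantee; condition comparisons should use the quadratic default.
* The built-in reconstruction is a curated single-pool model;
  compartment-specific cofactor pools (e.g. cytosolic vs mitochondrial
  NADH) are not distinguished, which can redistribute fluxes among
  parallel redox routes.
* Whether Vmacl stands for acetyl-CoA carboxylase alone or includes
  CoA ligation is not observable at this lumping level; it is encoded
  as the carboxylase with one ATP.
* Capacity bounds are rarely active at the reported optima; the
  `at_bound` column of the solution TSV surfaces this per run rather
  than assuming it.
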
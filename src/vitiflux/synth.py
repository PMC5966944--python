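"""Synthetic measurement generation from a known ground-truth flux map.

The generator inverts the measurement-to-constraint conversion: given a
feasible flux vector ``v_true`` obtained by flux minimization (so the
recovery target is the estimator's own fixed point), steady-state
accumulation concentrations are c = v / mu, biomass follows
X(t) = X0 * exp(mu t), enzyme capacities sit a factor >= 1 above the
true flux, and the ATP-synthesis rate is the true Vnrj1 + Vnrj2 sum.
Multiplicative lognormal noise with a chosen coefficient of variation
is applied to every simulated observation: concentrations are positive
and assay error is relative-error dominated, which a lognormal captures
and an additive Gaussian would not.

Defaults mirror the study conditions of the grape-cell suspension
system: specific growth rate 0.288 / day and initial biomass
1.6 g DW / L at day 4 of culture, sampling at days 0, 4, 6, 8 and 11,
respiration-derived ATP synthesis near 3.5 (control) or 2.9 (low
nitrogen) mmol / g DW / day.

``study_measurements`` provides fixed (noise-free) measurement tables
for a control ("N") and a low-nitrogen ("N-") condition whose
accumulation pattern follows the qualitative reorganization seen in
nitrogen-limited grape cells (more pigment, hexoses and starch, less
protein, sucrose, malate and respiration); they drive the worked
comparison example and the direction-of-change tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .constraints import (
    Component,
    MeasurementSet,
    assemble_problem,
    estimate_growth_rate,
)
from .gt3 import GT3_MEASURED_EXCHANGES, build_gt3_network
from .model import StoichiometricNetwork
from .qp import FluxProblem, FluxSolution, minimize_flux

__all__ = [
    "ScenarioParams",
    "SyntheticScenario",
    "RecoveryReport",
    "make_scenario",
    "simulate_measurements",
    "recovery_harness",
    "study_measurements",
    "STUDY_DAYS",
    "MOLAR_MASS",
]

#: sampling schedule of the emulated culture (days post-inoculation)
STUDY_DAYS = (0.0, 4.0, 6.0, 8.0, 11.0)

#: molar masses (g/mol) used to express simulated concentrations on a
#: mass basis; biomass polymers are per monomer unit.
MOLAR_MASS = {
    "Vac-mal": 134.09,      # malate
    "Vac-glc": 180.16,      # glucose
    "Vac-fru": 180.16,      # fructose
    "Vac-suc": 342.30,      # sucrose
    "Vac-Glu": 147.13,
    "Vac-Asp": 133.10,
    "Vac-Ala": 89.09,
    "Vac-Phe": 165.19,
    "Vanthoc": 493.40,      # malvidin-3-O-glucoside
    "Vflav": 464.40,        # quercetin-3-O-glucoside
    "Vtannins": 290.27,     # catechin (flavan-3-ol unit)
    "Vstilb": 228.25,       # resveratrol
    "Vcw": 162.14,          # anhydroglucose unit
    "Vprotein": 110.0,      # mean amino-acid residue
    "Vdag": 600.0,          # diacylglycerol (C16/C16, approximate)
    "Vnucleotides": 330.0,  # mean nucleotide monophosphate residue
    "Vstarch": 162.14,      # anhydroglucose unit
}

#: physiological sampling ranges (mmol / g DW / day) for the measured
#: exchange fluxes, centred on the magnitudes of a day-4 exponential
#: grape-cell culture.
DEFAULT_EXCHANGE_RANGES = {
    "Vac-mal": (0.04, 0.15),
    "Vac-glc": (0.05, 0.20),
    "Vac-fru": (0.04, 0.15),
    "Vac-suc": (0.01, 0.08),
    "Vac-Glu": (0.005, 0.02),
    "Vac-Asp": (0.003, 0.012),
    "Vac-Ala": (0.003, 0.012),
    "Vac-Phe": (0.0008, 0.004),
    "Vanthoc": (0.0005, 0.004),
    "Vflav": (0.0002, 0.0012),
    "Vtannins": (0.002, 0.01),
    "Vstilb": (0.0002, 0.001),
    "Vcw": (0.30, 0.60),
    "Vprotein": (0.25, 0.50),
    "Vdag": (0.006, 0.018),
    "Vnucleotides": (0.008, 0.025),
    "Vstarch": (0.03, 0.12),
}

#: enzymes with measured maximal capacities in the emulated assay panel
CAPACITY_REACTIONS = ("Vhk-glc", "Vhk-fru", "Vpgm", "Vg6pdh", "Veno",
                      "Vpk", "Vgs", "Vshik", "Vpal")


@dataclass
class ScenarioParams:
    mu_true: float = 0.288           # day^-1, exponential-phase value
    x0: float = 1.6                  # g DW / L at inoculation
    noise_cv: float = 0.05           # multiplicative CV of all observations
    exchange_ranges: dict = field(default_factory=lambda: dict(DEFAULT_EXCHANGE_RANGES))
    exchange_overrides: dict = field(default_factory=dict)  # rid -> fixed value
    capacity_margin: tuple = (1.5, 4.0)  # capacities drawn at margin x |v_true|
    condition_label: str = "synthetic"
    retry_cap: int = 5


@dataclass
class SyntheticScenario:
    network: StoichiometricNetwork
    v_true: np.ndarray
    mu_true: float
    x0: float
    noise_cv: float
    seed: int
    params: ScenarioParams
    atp_rate_true: float = 0.0

    def __post_init__(self) -> None:
        from .model import build_matrix

        S = build_matrix(self.network)
        resid = float(np.max(np.abs(S @ self.v_true)))
        if resid > 1e-10:
            raise ValueError(f"ground truth violates mass balance: {resid:.2e}")

    def flux(self, rxn_id: str) -> float:
        return float(self.v_true[self.network.reaction_ids.index(rxn_id)])

    def write_manifest(self, path) -> None:
        data = {
            "seed": self.seed,
            "mu_true": self.mu_true,
            "x0": self.x0,
            "noise_cv": self.noise_cv,
            "atp_rate_true": self.atp_rate_true,
            "condition_label": self.params.condition_label,
            "v_true": {rid: float(v) for rid, v in
                       zip(self.network.reaction_ids, self.v_true)},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)
            fh.write("\n")


def make_scenario(network: StoichiometricNetwork | None = None,
                  seed: int = 0,
                  params: ScenarioParams | None = None) -> SyntheticScenario:
    """Draw a ground-truth flux map for a synthetic culture.

    Exchange-flux targets are drawn uniformly within the physiological
    ranges (overrides pin individual fluxes, e.g. to force a
    low-nitrogen contrast), then the flux-minimization problem with
    those targets fixed is solved; its unique optimum is ``v_true``.
    Because v_true is the minimum-norm point of its own constraint set,
    a noise-free pipeline run must return it exactly.
    """
    if network is None:
        network = build_gt3_network()
    params = params or ScenarioParams()
    rng = np.random.default_rng(seed)

    rxn_ids = network.reaction_ids
    index = {rid: i for i, rid in enumerate(rxn_ids)}
    n = len(rxn_ids)

    last_err = None
    for _ in range(params.retry_cap):
        targets = {}
        for rid, (lo, hi) in sorted(params.exchange_ranges.items()):
            if rid not in index:
                continue
            targets[rid] = float(rng.uniform(lo, hi))
        targets.update(params.exchange_overrides)

        lb = np.full(n, -np.inf)
        ub = np.full(n, np.inf)
        for i, rxn in enumerate(network.reactions):
            if not rxn.reversible:
                lb[i] = 0.0
        for rid, val in targets.items():
            i = index[rid]
            lb[i] = ub[i] = val
        problem = FluxProblem(S=_matrix(network), lb=lb, ub=ub,
                              reaction_ids=list(rxn_ids))
        sol = minimize_flux(problem)
        if sol.ok:
            i1, i2 = index.get("Vnrj1"), index.get("Vnrj2")
            atp = float(sol.v[i1] + sol.v[i2]) if i1 is not None and i2 is not None \
                else 0.0
            return SyntheticScenario(
                network=network, v_true=sol.v, mu_true=params.mu_true,
                x0=params.x0, noise_cv=params.noise_cv, seed=seed,
                params=params, atp_rate_true=atp)
        last_err = sol.status
    raise RuntimeError(
        f"could not draw a feasible scenario in {params.retry_cap} tries "
        f"(last status: {last_err})")


def _matrix(network):
    from .model import build_matrix

    return build_matrix(network)


def simulate_measurements(scenario: SyntheticScenario,
                          days: tuple = STUDY_DAYS,
                          mass_basis: bool = True) -> MeasurementSet:
    """Fabricate a measurement set from the ground truth.

    Biomass: X0 * exp(mu t) x lognormal noise per timepoint.
    Components: concentration = v_true / mu (converted to mg / g DW when
    a molar mass is on file and ``mass_basis`` is set) x noise.
    Capacities: margin x |v_true| for the assayed enzymes, margin >= 1,
    so the truth is never cut off. ATP synthesis rate: true sum of the
    two oxidative phosphorylation fluxes x noise.
    """
    if not len(days):
        raise ValueError("need at least one sampling day")
    if scenario.mu_true <= 0:
        raise ValueError("mu_true must be positive to invert c = v / mu")
    rng = np.random.default_rng(scenario.seed + 1)
    cv = scenario.noise_cv

    def noisy(x: float) -> float:
        if cv <= 0:
            return x
        sigma = np.sqrt(np.log1p(cv**2))
        return float(x * rng.lognormal(-0.5 * sigma**2, sigma))

    days = sorted(float(d) for d in days)
    biomass = [noisy(scenario.x0 * np.exp(scenario.mu_true * d)) for d in days]

    components = {}
    for rid in GT3_MEASURED_EXCHANGES:
        if not scenario.network.has_reaction(rid):
            continue
        v = scenario.flux(rid)
        conc_mmol = v / scenario.mu_true
        mm = MOLAR_MASS.get(rid)
        if mass_basis and mm is not None:
            values = {d: noisy(conc_mmol * mm) for d in days}
            components[rid] = Component(id=rid, values=values,
                                        unit="mg/gDW", molar_mass=mm)
        else:
            values = {d: noisy(conc_mmol) for d in days}
            components[rid] = Component(id=rid, values=values,
                                        unit="mmol/gDW", molar_mass=mm)

    lo_m, hi_m = scenario.params.capacity_margin
    capacities = {}
    for rid in CAPACITY_REACTIONS:
        if scenario.network.has_reaction(rid):
            margin = float(rng.uniform(lo_m, hi_m))
            capacities[rid] = max(margin * abs(scenario.flux(rid)), 1e-6)

    atp_measured = noisy(scenario.atp_rate_true)
    return MeasurementSet(
        timepoints=days, biomass=biomass, components=components,
        capacities=capacities,
        atp_synthesis_rate=atp_measured,
        atp_synthesis_se=cv * atp_measured if cv > 0 else None,
        condition_label=scenario.params.condition_label)


@dataclass
class RecoveryReport:
    solution: FluxSolution
    mu_estimate: float
    max_relative_flux_error: float
    balance_residual: float
    sign_coverage: float  # fraction of ground-truth signs recovered
    stage_failed: str | None = None

    @property
    def ok(self) -> bool:
        return self.stage_failed is None


def recovery_harness(scenario: SyntheticScenario,
                     days: tuple = STUDY_DAYS,
                     day: float = 4.0,
                     respiration_mode: str = "auto") -> RecoveryReport:
    """Run the full pipeline on simulated data and score it against truth.

    simulate -> estimate growth rate -> assemble constraints -> solve ->
    compare against ``v_true``. Relative flux error uses the scale guard
    |v - v_true| / (1 + |v_true|); sign coverage counts reactions whose
    recovered flux sign (with a 1e-9 dead zone) matches the truth.

    ``respiration_mode="auto"`` applies the respiration coupling as a
    hard equality for noise-free data and as the mean +/- SE interval
    otherwise: under multiplicative noise, seventeen hard exchange
    equalities plus a hard respiration equality are almost surely
    mutually inconsistent (the noisy rate can fall below the NADH
    production floor the noisy demands imply), and the interval variant
    is exactly what the reported measurement uncertainty licenses.
    """
    stage = "simulate"
    try:
        measurements = simulate_measurements(scenario, days)
        stage = "estimate_growth_rate"
        growth = estimate_growth_rate(measurements, day)
        stage = "assemble_problem"
        if respiration_mode == "auto":
            respiration_mode = ("equality" if scenario.noise_cv <= 0
                                else "interval")
        problem = assemble_problem(scenario.network, measurements, day,
                                   growth=growth,
                                   respiration_mode=respiration_mode)
        stage = "solve"
        sol = minimize_flux(problem)
        if not sol.ok:
            raise RuntimeError(f"solver returned status {sol.status}")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    vt = scenario.v_true
    err = float(np.max(np.abs(sol.v - vt) / (1.0 + np.abs(vt))))
    signs_true = np.where(np.abs(vt) < 1e-9, 0, np.sign(vt))
    signs_est = np.where(np.abs(sol.v) < 1e-9, 0, np.sign(sol.v))
    coverage = float(np.mean(signs_true == signs_est))
    return RecoveryReport(
        solution=sol, mu_estimate=growth.mu,
        max_relative_flux_error=err,
        balance_residual=sol.balance_residual,
        sign_coverage=coverage)


def random_small_problem(rng: np.random.Generator,
                         n_reactions: int = 8,
                         n_metabolites: int = 4) -> FluxProblem:
    """Random flux-minimization instance small enough for the brute-force
    oracle.

    Stoichiometric coefficients are drawn from {-2, -1, 1, 2} at ~50%
    density (every reaction touches at least one metabolite); each
    reaction gets one of the bound patterns that occur in assembled
    problems: irreversible, unconstrained, symmetric capacity,
    irreversible capacity, or fixed by measurement. A quarter of the
    instances carry one equality coupling row. Infeasible draws are
    legitimate outputs: the solver and the oracle must both certify
    them.
    """
    m, n = n_metabolites, n_reactions
    while True:
        S = rng.choice([-2, -1, 0, 1, 2], size=(m, n),
                       p=[0.1, 0.25, 0.4, 0.15, 0.1]).astype(float)
        if np.all(np.any(S != 0, axis=0)):
            break
    lb = np.full(n, -np.inf)
    ub = np.full(n, np.inf)
    for j in range(n):
        kind = rng.choice(["irrev", "free", "cap", "irrev_cap", "fixed"],
                          p=[0.35, 0.15, 0.2, 0.15, 0.15])
        if kind == "irrev":
            lb[j] = 0.0
        elif kind == "cap":
            c = float(rng.uniform(0.5, 3.0))
            lb[j], ub[j] = -c, c
        elif kind == "irrev_cap":
            lb[j], ub[j] = 0.0, float(rng.uniform(0.5, 3.0))
        elif kind == "fixed":
            t = float(rng.uniform(0.0, 2.0))
            lb[j] = ub[j] = t
    weights = rng.uniform(0.5, 2.0, size=n)
    couplings = rhs = None
    if rng.random() < 0.25:
        row = np.zeros(n)
        picks = rng.choice(n, size=2, replace=False)
        row[picks] = 1.0
        couplings = row[None, :]
        rhs = np.array([float(rng.uniform(0.0, 2.0))])
    return FluxProblem(S=S, lb=lb, ub=ub,
                       reaction_ids=[f"r{j}" for j in range(n)],
                       weights=weights, couplings=couplings, coupling_rhs=rhs)


# ----------------------------------------------------------------------
# fixed study-condition tables (synthetic, noise-free)
# ----------------------------------------------------------------------

#: day-4 component content, mg per g DW, for the two nutritional
#: conditions. Chosen so that the measured components cover ~81% (N)
#: and ~91% (N-) of dry biomass, with the nitrogen-limitation
#: reorganization: pigments, hexoses and starch up; protein, sucrose,
#: malate, free amino acids and respiration down.
STUDY_COMPOSITION_MG = {
    "N": {
        "Vac-mal": 40.0, "Vac-glc": 80.0, "Vac-fru": 50.0, "Vac-suc": 40.0,
        "Vac-Glu": 8.0, "Vac-Asp": 4.0, "Vac-Ala": 3.0, "Vac-Phe": 1.5,
        "Vanthoc": 2.5, "Vflav": 0.8, "Vtannins": 6.0, "Vstilb": 0.5,
        "Vcw": 320.0, "Vprotein": 160.0, "Vdag": 25.0, "Vnucleotides": 20.0,
        "Vstarch": 50.0,
    },
    "N-": {
        "Vac-mal": 30.0, "Vac-glc": 150.0, "Vac-fru": 110.0, "Vac-suc": 30.0,
        "Vac-Glu": 4.4, "Vac-Asp": 3.0, "Vac-Ala": 2.0, "Vac-Phe": 0.8,
        "Vanthoc": 5.1, "Vflav": 0.7, "Vtannins": 8.3, "Vstilb": 0.7,
        "Vcw": 320.0, "Vprotein": 110.0, "Vdag": 25.0, "Vnucleotides": 20.0,
        "Vstarch": 90.0,
    },
}

#: respiration-derived ATP synthesis rate (mean, SE), mmol / g DW / day
STUDY_RESPIRATION = {"N": (3.54, 0.18), "N-": (2.86, 0.24)}

#: assayed enzyme capacities, mmol / g DW / day (generous ceilings)
STUDY_CAPACITIES = {
    "Vhk-glc": 5.0, "Vhk-fru": 5.0, "Vpgm": 10.0, "Vg6pdh": 2.0,
    "Veno": 20.0, "Vpk": 10.0, "Vgs": 2.0, "Vshik": 1.0, "Vpal": 0.5,
}


def study_measurements(condition: str = "N") -> MeasurementSet:
    """Noise-free measurement tables for one nutritional condition.

    Biomass follows the culture kinetics (exponential at 0.288 / day up
    to day 4, slowing to 0.160 / day over days 4-6, then saturating
    near 10 g DW / L); component contents are the fixed day-4
    compositions above, held at their day-4 value across the sampling
    schedule (steady-state accumulation).
    """
    if condition not in STUDY_COMPOSITION_MG:
        raise ValueError(f"unknown condition {condition!r}; use 'N' or 'N-'")
    mu4, mu6 = 0.288, 0.160
    x0 = 1.6
    x4 = x0 * np.exp(mu4 * 4)
    x6 = x4 * np.exp(mu6 * 2)
    x8 = x6 * np.exp(0.08 * 2)
    x11 = x8 * 1.05
    days = list(STUDY_DAYS)
    biomass = [x0, float(x4), float(x6), float(x8), float(x11)]

    components = {}
    for rid, mg in sorted(STUDY_COMPOSITION_MG[condition].items()):
        components[rid] = Component(
            id=rid, unit="mg/gDW", molar_mass=MOLAR_MASS[rid],
            values={d: mg for d in days})
    atp, atp_se = STUDY_RESPIRATION[condition]
    return MeasurementSet(
        timepoints=days, biomass=biomass, components=components,
        capacities=dict(STUDY_CAPACITIES),
        atp_synthesis_rate=atp, atp_synthesis_se=atp_se,
        condition_label=condition)
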
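"""From measured time courses to a solvable flux problem.

The measurement-to-constraint conversion follows the steady-state
balancing argument: during exponential growth at specific growth rate
mu (day^-1), a component accumulated to concentration c (mmol per g DW)
corresponds to a net synthesis flux v = c * mu (mmol per g DW per day).
Mass-based concentrations are first converted to moles via the molar
mass. Measured enzyme capacities become flux bounds, and the
respiration-derived ATP synthesis rate couples the two oxidative
phosphorylation fluxes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import StoichiometricNetwork, build_matrix
from .qp import FluxProblem

__all__ = [
    "Component",
    "MeasurementSet",
    "GrowthEstimate",
    "MeasurementError",
    "estimate_growth_rate",
    "accumulation_flux",
    "assemble_problem",
    "biomass_coverage",
    "respiration_to_atp_rate",
    "read_measurements_csv",
    "write_measurements_csv",
    "read_capacities_csv",
    "write_capacities_csv",
]

MASS_UNIT = "mg/gDW"
MOLE_UNIT = "mmol/gDW"


class MeasurementError(ValueError):
    """Inconsistent or incomplete measurement data."""


@dataclass
class Component:
    """One accumulated component's concentration time course."""

    id: str
    values: dict  # day -> concentration
    unit: str = MOLE_UNIT  # "mmol/gDW" or "mg/gDW"
    molar_mass: float | None = None  # g/mol, required for mass-based unit

    def __post_init__(self) -> None:
        if self.unit not in (MASS_UNIT, MOLE_UNIT):
            raise MeasurementError(f"component {self.id!r}: unknown unit {self.unit!r}")
        if self.unit == MASS_UNIT and not (self.molar_mass and self.molar_mass > 0):
            raise MeasurementError(
                f"component {self.id!r}: molar mass required for unit {MASS_UNIT}")
        for d, c in self.values.items():
            if c < 0:
                raise MeasurementError(
                    f"component {self.id!r}: negative concentration at day {d}")

    def concentration(self, day: float) -> float:
        try:
            return self.values[day]
        except KeyError:
            raise MeasurementError(
                f"component {self.id!r}: no measurement at day {day}") from None

    def mass_per_gdw(self, day: float) -> float:
        """Component mass in g per g DW at the given day."""
        c = self.concentration(day)
        if self.unit == MASS_UNIT:
            return c / 1000.0
        if self.molar_mass is None:
            raise MeasurementError(
                f"component {self.id!r}: molar mass needed to express mass share")
        return c * self.molar_mass / 1000.0


@dataclass
class MeasurementSet:
    timepoints: list  # days since inoculation
    biomass: list  # g DW / L, one per timepoint
    components: dict = field(default_factory=dict)  # id -> Component
    capacities: dict = field(default_factory=dict)  # reaction id -> mmol/gDW/day
    atp_synthesis_rate: float | None = None  # mmol/gDW/day, respiration-derived
    atp_synthesis_se: float | None = None
    condition_label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        if len(t) != len(self.biomass):
            raise MeasurementError("timepoints and biomass have different lengths")
        if len(t) and np.any(np.diff(t) <= 0):
            raise MeasurementError("timepoints must be strictly increasing")
        if any(b <= 0 for b in self.biomass):
            raise MeasurementError("biomass must be positive")
        for rid, cap in self.capacities.items():
            if cap < 0:
                raise MeasurementError(f"capacity of {rid!r} must be >= 0")


@dataclass
class GrowthEstimate:
    mu: float  # day^-1
    day: float
    window: list
    fit_r2: float  # NaN when undefined (e.g. constant biomass)

    def __post_init__(self) -> None:
        if not math.isfinite(self.mu):
            raise MeasurementError("estimated growth rate is not finite")


def estimate_growth_rate(measurements: MeasurementSet, day: float,
                         window: list | None = None) -> GrowthEstimate:
    """Specific growth rate from a log-linear fit of the biomass curve.

    mu is the slope of the least-squares line through (t, ln biomass)
    over the window (default: all timepoints up to and including
    ``day``). During exponential growth d ln X / dt = mu, so the slope
    is the growth rate per unit biomass.
    """
    t_all = list(map(float, measurements.timepoints))
    if window is None:
        window = [t for t in t_all if t <= day + 1e-12]
    window = list(map(float, window))
    missing = [t for t in window if t not in t_all]
    if missing:
        raise MeasurementError(f"window timepoints not measured: {missing}")
    if len(window) < 2:
        raise MeasurementError("growth-rate window needs at least 2 timepoints")
    x = np.array(window)
    y = np.array([measurements.biomass[t_all.index(t)] for t in window], dtype=float)
    if np.any(y <= 0):
        raise MeasurementError("non-positive biomass in growth window")
    ly = np.log(y)
    slope, intercept = np.polyfit(x, ly, 1)
    resid = ly - (slope * x + intercept)
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = float("nan") if ss_tot == 0.0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return GrowthEstimate(mu=float(slope), day=day, window=window, fit_r2=r2)


def accumulation_flux(concentration: float, unit: str,
                      molar_mass: float | None,
                      growth: GrowthEstimate) -> float:
    """Accumulation flux (mmol / g DW / day) from a steady-state concentration.

    flux = concentration * mu, with a gram-to-mole conversion first when
    the concentration is mass-based: flux = (c / M) * mu.
    """
    if concentration < 0:
        raise MeasurementError("concentration must be >= 0")
    if unit == MASS_UNIT:
        if not (molar_mass and molar_mass > 0):
            raise MeasurementError("molar mass required for mass-based unit")
        conc_mmol = concentration / molar_mass  # mg/gDW / (g/mol) = mmol/gDW
    elif unit == MOLE_UNIT:
        conc_mmol = concentration
    else:
        raise MeasurementError(f"unknown unit {unit!r}")
    return conc_mmol * growth.mu


def biomass_coverage(measurements: MeasurementSet, day: float) -> float:
    """Percent of dry biomass accounted for by the measured components."""
    total = 0.0
    for comp in measurements.components.values():
        m = comp.mass_per_gdw(day)
        if m < 0:
            raise MeasurementError(f"negative component mass for {comp.id!r}")
        total += m
    return 100.0 * total


def respiration_to_atp_rate(o2_nmol_per_min_gfw: float, fw_per_dw: float,
                            atp_per_o: float = 2.0) -> float:
    """Convert an O2 consumption rate to an ATP-synthesis rate.

    Parameters
    ----------
    o2_nmol_per_min_gfw:
        Measured respiration, nmol O2 min^-1 per g fresh weight.
    fw_per_dw:
        Fresh-weight-to-dry-weight ratio of the cells (g FW per g DW);
        must be supplied explicitly, it is culture-specific.
    atp_per_o:
        ATP synthesized per oxygen atom reduced (the effective P/O
        ratio of the whole chain); each O2 accepts electrons from two
        donor equivalents.

    Returns mmol ATP per g DW per day.
    """
    if fw_per_dw <= 0 or atp_per_o <= 0:
        raise MeasurementError("conversion ratios must be positive")
    o2_mmol_per_day_gdw = o2_nmol_per_min_gfw * 1e-6 * 60 * 24 * fw_per_dw
    return o2_mmol_per_day_gdw * 2.0 * atp_per_o


# ----------------------------------------------------------------------
# problem assembly
# ----------------------------------------------------------------------

def assemble_problem(
    network: StoichiometricNetwork,
    measurements: MeasurementSet,
    day: float,
    component_map: dict | None = None,
    growth: GrowthEstimate | None = None,
    window: list | None = None,
    respiration_mode: str = "equality",  # or "interval" (mean +/- SE)
    weights: dict | None = None,
) -> FluxProblem:
    """Build the flux-minimization problem for one condition and day.

    Bound logic:

    * irreversible reactions: lower bound 0;
    * measured capacity: upper bound +capacity and, for reversible
      reactions, lower bound -capacity;
    * otherwise the bounds are unbounded (+/- infinity);
    * each measured component, mapped to a reaction via
      ``component_map`` (identity mapping by default), fixes that
      reaction: lb = ub = accumulation flux at ``day``;
    * if an ATP synthesis rate is present, one coupling row constrains
      flux(Vnrj1) + flux(Vnrj2) to it (exactly, or to mean +/- SE in
      ``interval`` mode).
    """
    network.validate()
    if growth is None:
        growth = estimate_growth_rate(measurements, day, window)

    component_map = dict(component_map or {})
    rxn_ids = network.reaction_ids
    index = {rid: i for i, rid in enumerate(rxn_ids)}
    n = len(rxn_ids)

    unmatched = []
    targets = {}
    for cid, comp in sorted(measurements.components.items()):
        rid = component_map.get(cid, cid)
        if rid not in index:
            unmatched.append(cid)
            continue
        flux = accumulation_flux(comp.concentration(day), comp.unit,
                                 comp.molar_mass, growth)
        targets[rid] = flux
    if unmatched:
        raise MeasurementError(
            f"measured components with no matching reaction: {unmatched}")

    bad_caps = sorted(set(measurements.capacities) - set(rxn_ids))
    if bad_caps:
        raise MeasurementError(f"capacities reference unknown reactions: {bad_caps}")

    lb = np.full(n, -np.inf)
    ub = np.full(n, np.inf)
    for i, rid in enumerate(rxn_ids):
        rxn = network.reaction(rid)
        if not rxn.reversible:
            lb[i] = 0.0
        cap = measurements.capacities.get(rid, rxn.capacity)
        if cap is not None:
            ub[i] = cap
            if rxn.reversible:
                lb[i] = -cap
    for rid, flux in targets.items():
        i = index[rid]
        lb[i] = flux
        ub[i] = flux

    contradictions = [rxn_ids[i] for i in np.flatnonzero(lb > ub)]
    if contradictions:
        raise MeasurementError(
            f"contradictory bounds (lb > ub) for reactions: {contradictions}")

    couplings = rhs = lo = hi = None
    if measurements.atp_synthesis_rate is not None:
        row = np.zeros(n)
        for rid in ("Vnrj1", "Vnrj2"):
            if rid not in index:
                raise MeasurementError(
                    f"network lacks {rid}; cannot apply the respiration coupling")
            row[index[rid]] = 1.0
        couplings = row[None, :]
        if respiration_mode == "interval":
            se = measurements.atp_synthesis_se or 0.0
            lo = np.array([measurements.atp_synthesis_rate - se])
            hi = np.array([measurements.atp_synthesis_rate + se])
        elif respiration_mode == "equality":
            rhs = np.array([measurements.atp_synthesis_rate])
        else:
            raise MeasurementError(f"unknown respiration mode {respiration_mode!r}")

    w = np.ones(n)
    for rid, wi in (weights or {}).items():
        w[index[rid]] = wi

    return FluxProblem(
        S=build_matrix(network), lb=lb, ub=ub, reaction_ids=list(rxn_ids),
        weights=w, couplings=couplings, coupling_rhs=rhs,
        coupling_lo=lo, coupling_hi=hi,
        metabolite_ids=[m.id for m in network.internal_metabolites],
    )


# ----------------------------------------------------------------------
# CSV dialects
# ----------------------------------------------------------------------

def write_measurements_csv(measurements: MeasurementSet, path) -> None:
    """Long-format CSV: condition,day,component_id,value,unit,molar_mass.

    Biomass rows use component_id 'biomass' with unit 'gDW/L'; the ATP
    synthesis rate uses 'atp_synthesis_rate' with unit 'mmol/gDW/day'.
    """
    rows = []
    cond = measurements.condition_label
    for t, b in zip(measurements.timepoints, measurements.biomass):
        rows.append((cond, t, "biomass", b, "gDW/L", ""))
    for cid in sorted(measurements.components):
        comp = measurements.components[cid]
        for day in sorted(comp.values):
            rows.append((cond, day, cid, comp.values[day], comp.unit,
                         comp.molar_mass if comp.molar_mass is not None else ""))
    if measurements.atp_synthesis_rate is not None:
        rows.append((cond, "", "atp_synthesis_rate",
                     measurements.atp_synthesis_rate, "mmol/gDW/day", ""))
        if measurements.atp_synthesis_se is not None:
            rows.append((cond, "", "atp_synthesis_se",
                         measurements.atp_synthesis_se, "mmol/gDW/day", ""))
    df = pd.DataFrame(rows, columns=["condition", "day", "component_id",
                                     "value", "unit", "molar_mass"])
    df.to_csv(path, index=False)


def read_measurements_csv(path, condition: str | None = None) -> MeasurementSet:
    df = pd.read_csv(path)
    required = {"condition", "day", "component_id", "value", "unit"}
    if not required.issubset(df.columns):
        raise MeasurementError(
            f"measurements CSV must have columns {sorted(required)}")
    if condition is not None:
        df = df[df["condition"] == condition]
        if df.empty:
            raise MeasurementError(f"no rows for condition {condition!r}")
    else:
        conds = df["condition"].unique()
        if len(conds) > 1:
            raise MeasurementError(
                f"multiple conditions in file ({list(conds)}); pick one")

    bio = df[df["component_id"] == "biomass"].sort_values("day")
    atp = df[df["component_id"] == "atp_synthesis_rate"]
    atp_se = df[df["component_id"] == "atp_synthesis_se"]
    comp_rows = df[~df["component_id"].isin(
        ["biomass", "atp_synthesis_rate", "atp_synthesis_se"])]

    components = {}
    for cid, grp in comp_rows.groupby("component_id"):
        unit = grp["unit"].iloc[0]
        mm = grp["molar_mass"].iloc[0] if "molar_mass" in grp else None
        mm = None if pd.isna(mm) else float(mm)
        components[cid] = Component(
            id=cid, unit=unit, molar_mass=mm,
            values={float(r.day): float(r.value) for r in grp.itertuples()})
    cond_label = df["condition"].iloc[0] if len(df) else ""
    return MeasurementSet(
        timepoints=[float(t) for t in bio["day"]],
        biomass=[float(b) for b in bio["value"]],
        components=components,
        atp_synthesis_rate=float(atp["value"].iloc[0]) if len(atp) else None,
        atp_synthesis_se=float(atp_se["value"].iloc[0]) if len(atp_se) else None,
        condition_label=str(cond_label),
    )


def write_capacities_csv(capacities: dict, condition: str, path) -> None:
    df = pd.DataFrame(
        [(condition, rid, cap) for rid, cap in sorted(capacities.items())],
        columns=["condition", "reaction_id", "capacity"])
    df.to_csv(path, index=False)


def read_capacities_csv(path, condition: str | None = None) -> dict:
    df = pd.read_csv(path)
    if condition is not None:
        df = df[df["condition"] == condition]
    return {str(r.reaction_id): float(r.capacity) for r in df.itertuples()}
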
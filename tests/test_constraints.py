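"""Growth-rate estimation, unit conversion, and problem assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vitiflux import (
    Component,
    GrowthEstimate,
    MeasurementError,
    MeasurementSet,
    accumulation_flux,
    assemble_problem,
    biomass_coverage,
    estimate_growth_rate,
    minimize_flux,
    read_measurements_csv,
    respiration_to_atp_rate,
    study_measurements,
    write_measurements_csv,
)


def _ms(timepoints, biomass, **kw):
    return MeasurementSet(timepoints=timepoints, biomass=biomass, **kw)


# ---------------------------------------------------------------------------
# growth rate
# ---------------------------------------------------------------------------

def test_exact_exponential_recovers_slope():
    t = [0.0, 2.0, 4.0]
    ms = _ms(t, [1.6 * math.exp(0.288 * ti) for ti in t])
    est = estimate_growth_rate(ms, day=4.0)
    assert est.mu == pytest.approx(0.288, abs=1e-12)
    assert est.fit_r2 == pytest.approx(1.0)
    assert est.window == t


def test_constant_biomass_gives_zero_mu_and_flagged_r2():
    ms = _ms([0.0, 2.0, 4.0], [3.0, 3.0, 3.0])
    est = estimate_growth_rate(ms, day=4.0)
    assert est.mu == pytest.approx(0.0, abs=1e-14)
    assert math.isnan(est.fit_r2)


def test_window_of_one_point_rejected():
    ms = _ms([0.0, 4.0], [1.0, 2.0])
    with pytest.raises(MeasurementError):
        estimate_growth_rate(ms, day=4.0, window=[4.0])
    with pytest.raises(MeasurementError):
        estimate_growth_rate(ms, day=4.0, window=[4.0, 5.0])  # unmeasured day


def test_measurement_set_invariants():
    with pytest.raises(MeasurementError):
        _ms([0.0, 0.0], [1.0, 1.0])  # not strictly increasing
    with pytest.raises(MeasurementError):
        _ms([0.0, 1.0], [1.0, -2.0])  # non-positive biomass
    with pytest.raises(MeasurementError):
        Component(id="c", values={0.0: -1.0})  # negative concentration
    with pytest.raises(MeasurementError):
        Component(id="c", values={0.0: 1.0}, unit="mg/gDW")  # needs molar mass


def test_noisy_series_recovers_mu_within_ten_percent():
    rng = np.random.default_rng(11)
    mu = 0.288
    t = [0.0, 2.0, 4.0, 6.0]
    sigma = math.sqrt(math.log1p(0.05**2))
    biomass = [1.6 * math.exp(mu * ti) * rng.lognormal(-sigma**2 / 2, sigma)
               for ti in t]
    est = estimate_growth_rate(_ms(t, biomass), day=6.0)
    assert abs(est.mu - mu) / mu < 0.10


# ---------------------------------------------------------------------------
# accumulation flux
# ---------------------------------------------------------------------------

GROWTH = GrowthEstimate(mu=0.288, day=4.0, window=[0.0, 4.0], fit_r2=1.0)


@pytest.mark.parametrize("conc, unit, mm, mu, expected", [
    (0.0, "mmol/gDW", None, 0.2, 0.0),
    (0.1, "mmol/gDW", None, 0.2, 0.02),
    (4.93, "mg/gDW", 493.0, 0.288, 0.00288),
])
def test_accumulation_flux_values(conc, unit, mm, mu, expected):
    growth = GrowthEstimate(mu=mu, day=4.0, window=[0.0, 4.0], fit_r2=1.0)
    assert accumulation_flux(conc, unit, mm, growth) == pytest.approx(
        expected, rel=1e-12)


def test_missing_molar_mass_rejected():
    with pytest.raises(MeasurementError):
        accumulation_flux(1.0, "mg/gDW", None, GROWTH)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(c=st.floats(0, 1e3), mu=st.floats(-1, 1), k=st.floats(0.1, 10))
def test_accumulation_flux_is_linear(c, mu, k):
    g1 = GrowthEstimate(mu=mu, day=4.0, window=[0.0, 4.0], fit_r2=1.0)
    gk = GrowthEstimate(mu=k * mu, day=4.0, window=[0.0, 4.0], fit_r2=1.0)
    base = accumulation_flux(c, "mmol/gDW", None, g1)
    assert accumulation_flux(k * c, "mmol/gDW", None, g1) == pytest.approx(
        k * base, rel=1e-9, abs=1e-12)
    assert accumulation_flux(c, "mmol/gDW", None, gk) == pytest.approx(
        k * base, rel=1e-9, abs=1e-12)


def test_respiration_conversion_helper():
    # 100 nmol O2 / min / g FW at FW/DW 10 and 2 ATP per O:
    # 100e-6 * 1440 * 10 mmol O2 = 1.44 -> x2 O per O2 x2 ATP = 5.76
    assert respiration_to_atp_rate(100.0, 10.0, 2.0) == pytest.approx(5.76)


# ---------------------------------------------------------------------------
# biomass coverage
# ---------------------------------------------------------------------------

def _coverage_ms(masses_g):
    comps = {
        f"c{i}": Component(id=f"c{i}", unit="mg/gDW", molar_mass=100.0,
                           values={4.0: m * 1000})
        for i, m in enumerate(masses_g)
    }
    return _ms([0.0, 4.0], [1.6, 5.0], components=comps)


def test_coverage_81_percent():
    assert biomass_coverage(_coverage_ms([0.5, 0.31]), 4.0) == pytest.approx(81.0)


def test_coverage_91_percent():
    assert biomass_coverage(_coverage_ms([0.5, 0.31, 0.10]), 4.0) == pytest.approx(91.0)


def test_coverage_empty_table_is_zero():
    assert biomass_coverage(_ms([0.0, 4.0], [1.0, 2.0]), 4.0) == 0.0


# ---------------------------------------------------------------------------
# problem assembly
# ---------------------------------------------------------------------------

def test_assembled_bounds_follow_the_rules(gt3):
    ms = study_measurements("N")
    problem = assemble_problem(gt3, ms, 4.0)
    idx = {r: i for i, r in enumerate(problem.reaction_ids)}

    # irreversible, no capacity -> [0, inf)
    j = idx["Vpdh"]
    assert problem.lb[j] == 0.0 and problem.ub[j] == np.inf
    # reversible, capacity 10 -> [-10, 10]
    j = idx["Vpgm"]
    assert problem.lb[j] == -10.0 and problem.ub[j] == 10.0
    # irreversible with capacity -> [0, cap]
    j = idx["Vpal"]
    assert problem.lb[j] == 0.0 and problem.ub[j] == 0.5
    # reversible, uncapacitated -> (-inf, inf)
    j = idx["Vmdh"]
    assert problem.lb[j] == -np.inf and problem.ub[j] == np.inf
    # measured exchanges are fixed, bit-equal
    for rid in ms.components:
        j = idx[rid]
        assert problem.lb[j] == problem.ub[j]
    # exactly one coupling row, summing Vnrj1 + Vnrj2 to the measured rate
    assert problem.couplings.shape == (1, len(problem.reaction_ids))
    row = problem.couplings[0]
    assert row[idx["Vnrj1"]] == 1.0 and row[idx["Vnrj2"]] == 1.0
    assert np.count_nonzero(row) == 2
    assert problem.coupling_rhs[0] == 3.54


def test_respiration_rhs_matches_both_conditions(gt3):
    for cond, rate in (("N", 3.54), ("N-", 2.86)):
        problem = assemble_problem(gt3, study_measurements(cond), 4.0)
        assert problem.coupling_rhs[0] == rate


def test_interval_mode_uses_mean_plus_minus_se(gt3):
    problem = assemble_problem(gt3, study_measurements("N"), 4.0,
                               respiration_mode="interval")
    assert problem.coupling_lo[0] == pytest.approx(3.54 - 0.18)
    assert problem.coupling_hi[0] == pytest.approx(3.54 + 0.18)


def test_unmatched_component_errors_with_ids(gt3):
    ms = study_measurements("N")
    ms.components["mystery"] = Component(
        id="mystery", unit="mmol/gDW", values={d: 0.1 for d in ms.timepoints})
    with pytest.raises(MeasurementError, match="mystery"):
        assemble_problem(gt3, ms, 4.0)


def test_assembly_is_order_independent(gt3):
    ms = study_measurements("N")
    p1 = assemble_problem(gt3, ms, 4.0)
    reversed_components = dict(reversed(list(ms.components.items())))
    ms2 = MeasurementSet(
        timepoints=ms.timepoints, biomass=ms.biomass,
        components=reversed_components, capacities=ms.capacities,
        atp_synthesis_rate=ms.atp_synthesis_rate,
        atp_synthesis_se=ms.atp_synthesis_se,
        condition_label=ms.condition_label)
    p2 = assemble_problem(gt3, ms2, 4.0)
    assert np.array_equal(p1.lb, p2.lb) and np.array_equal(p1.ub, p2.ub)
    assert np.array_equal(p1.S, p2.S)


def test_measurements_csv_round_trip(tmp_path, gt3):
    ms = study_measurements("N-")
    path = tmp_path / "m.csv"
    write_measurements_csv(ms, path)
    ms2 = read_measurements_csv(path)
    assert ms2.condition_label == "N-"
    assert ms2.timepoints == ms.timepoints
    assert ms2.atp_synthesis_rate == ms.atp_synthesis_rate
    assert set(ms2.components) == set(ms.components)
    for cid, comp in ms.components.items():
        assert ms2.components[cid].values == comp.values
        assert ms2.components[cid].unit == comp.unit
    # and the round-tripped set assembles into the identical problem
    ms2.capacities = ms.capacities
    p1 = assemble_problem(gt3, ms, 4.0)
    p2 = assemble_problem(gt3, ms2, 4.0)
    assert np.array_equal(p1.lb, p2.lb) and np.array_equal(p1.ub, p2.ub)


def test_study_problem_solves_and_hits_respiration(gt3, study_solutions):
    for cond, rate in (("N", 3.54), ("N-", 2.86)):
        _, sol = study_solutions[cond]
        assert sol.flux("Vnrj1") + sol.flux("Vnrj2") == pytest.approx(rate, abs=1e-8)
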
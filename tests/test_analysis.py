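"""Flux-map comparison, cofactor ledgers, and alpha-KG branch accounting."""

import math

import networkx as nx
import numpy as np
import pytest

from vitiflux import (
    FluxSolution,
    Metabolite,
    NetworkError,
    Reaction,
    StoichiometricNetwork,
    akg_branch_summary,
    cofactor_ledger,
    export_flux_map,
    percent_change_map,
)
from vitiflux.analysis import metabolite_ledger
from vitiflux.gt3 import COFACTOR_IDS


def _sol(ids, v):
    v = np.asarray(v, dtype=float)
    return FluxSolution(v=v, objective=float(np.sum(v**2)), status="optimal",
                        reaction_ids=list(ids))


# ---------------------------------------------------------------------------
# percent-change map
# ---------------------------------------------------------------------------

def test_percent_change_arithmetic():
    cm = percent_change_map(_sol("abc", [1.0, 2.0, 0.0]),
                            _sol("abc", [1.8, 2.0, 0.5]))
    assert cm.percent_change("a") == pytest.approx(80.0)
    assert cm.classification("a") == "increased"
    assert cm.percent_change("b") == 0.0
    assert cm.classification("b") == "unchanged"
    assert math.isnan(cm.percent_change("c"))
    assert cm.classification("c") == "undefined"


def test_negative_control_flux_uses_absolute_denominator():
    cm = percent_change_map(_sol("ab", [-2.0, -1.0]), _sol("ab", [-3.0, 1.0]))
    assert cm.percent_change("a") == pytest.approx(-50.0)
    row = cm.table[cm.table["reaction_id"] == "b"].iloc[0]
    assert bool(row["sign_flip"])


def test_self_comparison_is_identically_zero(study_solutions):
    _, sol = study_solutions["N"]
    cm = percent_change_map(sol, sol)
    defined = cm.table["percent_change"].dropna()
    assert (defined == 0).all()


def test_mismatched_orderings_rejected():
    with pytest.raises(NetworkError):
        percent_change_map(_sol("ab", [1, 2]), _sol("ba", [1, 2]))


def test_dead_band_classification():
    cm = percent_change_map(_sol("ab", [1.0, 1.0]), _sol("ab", [1.04, 1.06]),
                            dead_band=5.0)
    assert cm.classification("a") == "unchanged"
    assert cm.classification("b") == "increased"


# ---------------------------------------------------------------------------
# ledgers
# ---------------------------------------------------------------------------

def _toy_cofactor_net():
    mets = [Metabolite("atp", is_cofactor=True), Metabolite("glc"),
            Metabolite("x", role="external")]
    rxns = [Reaction("make", {"x": -1, "glc": 1, "atp": 1}, kind="exchange"),
            Reaction("burn", {"glc": -1, "atp": -1, "x": 1}, kind="exchange")]
    return StoichiometricNetwork(metabolites=mets, reactions=rxns)


def test_toy_ledger_balances():
    net = _toy_cofactor_net()
    ledger = cofactor_ledger(net, _sol(["make", "burn"], [2.0, 2.0]), "atp")
    assert ledger.total_production == pytest.approx(2.0)
    assert ledger.total_consumption == pytest.approx(-2.0)
    assert ledger.net == pytest.approx(0.0)
    assert list(ledger.producers["reaction_id"]) == ["make"]
    assert list(ledger.consumers["reaction_id"]) == ["burn"]


def test_non_cofactor_and_unknown_ids_rejected(study_solutions, gt3):
    _, sol = study_solutions["N"]
    with pytest.raises(NetworkError):
        cofactor_ledger(gt3, sol, "glc")
    with pytest.raises(NetworkError):
        cofactor_ledger(gt3, sol, "nonexistent")


def test_all_cofactor_ledgers_net_zero_at_optimum(study_solutions, gt3):
    for cond in ("N", "N-"):
        _, sol = study_solutions[cond]
        tol = 1e-8 * (1.0 + float(np.max(np.abs(sol.v))))
        for cof in COFACTOR_IDS:
            assert abs(cofactor_ledger(gt3, sol, cof).net) <= tol, cof


def test_nadph_ledger_names_expected_producers_and_consumers(study_solutions, gt3):
    _, sol = study_solutions["N"]
    ledger = cofactor_ledger(gt3, sol, "nadph")
    producers = set(ledger.producers["reaction_id"])
    consumers = set(ledger.consumers["reaction_id"])
    assert "Vg6pdh" in producers  # oxidative PPP dehydrogenases
    assert {"Vlcc", "Vcoum"} & consumers  # flavonoid reductive steps


# ---------------------------------------------------------------------------
# alpha-KG branch summary
# ---------------------------------------------------------------------------

def test_toy_shares():
    mets = [Metabolite("akg", name="alpha-ketoglutarate"),
            Metabolite("x", role="external")]
    rxns = [Reaction("in", {"x": -1, "akg": 1}, kind="exchange"),
            Reaction("big", {"akg": -1, "x": 1}, kind="exchange"),
            Reaction("small", {"akg": -1, "x": 1}, kind="exchange")]
    net = StoichiometricNetwork(metabolites=mets, reactions=rxns)
    table = akg_branch_summary(net, _sol(["in", "big", "small"], [4.0, 3.0, 1.0]))
    shares = dict(zip(table["reaction_id"], table["share"]))
    assert shares["big"] == pytest.approx(0.75)
    assert shares["small"] == pytest.approx(0.25)


def test_gt3_shares_sum_to_one_and_list_the_dioxygenases(study_solutions, gt3):
    _, sol = study_solutions["N-"]
    table = akg_branch_summary(gt3, sol)
    assert table["share"].sum() == pytest.approx(1.0)
    assert (table["share"] >= 0).all()
    listed = set(table["reaction_id"])
    assert {"Vkgdh", "Vgogat", "Vdhq", "Vanthoc"} <= listed


def test_akg_is_redirected_toward_dioxygenases_under_low_nitrogen(
        study_solutions, gt3):
    """N limitation cuts GOGAT's alpha-KG draw while the flavonoid
    dioxygenases take a larger share of a smaller total."""
    gogat_flux, dioxy_share = {}, {}
    for cond in ("N", "N-"):
        _, sol = study_solutions[cond]
        t = akg_branch_summary(gt3, sol)
        shares = dict(zip(t["reaction_id"], t["share"]))
        gogat_flux[cond] = sol.flux("Vgogat")
        dioxy_share[cond] = sum(shares.get(r, 0.0)
                                for r in ("Vdhq", "Vflav", "Vanthoc"))
    assert gogat_flux["N-"] < gogat_flux["N"]
    assert dioxy_share["N-"] > dioxy_share["N"]


def test_akg_missing_raises():
    net = _toy_cofactor_net()
    with pytest.raises(NetworkError):
        akg_branch_summary(net, _sol(["make", "burn"], [1.0, 1.0]))


def test_every_internal_metabolite_ledger_nets_zero(study_solutions, gt3):
    _, sol = study_solutions["N"]
    tol = 1e-8 * (1.0 + float(np.max(np.abs(sol.v))))
    for met in gt3.internal_metabolites:
        assert abs(metabolite_ledger(gt3, sol, met.id).net) <= tol, met.id


# ---------------------------------------------------------------------------
# graph export
# ---------------------------------------------------------------------------

def _fork_net_and_sol():
    mets = [Metabolite("A"), Metabolite("x", role="external"),
            Metabolite("y", role="external")]
    rxns = [Reaction("r1", {"x": -1, "A": 1}, kind="exchange"),
            Reaction("r2", {"A": -1, "y": 1}, kind="exchange"),
            Reaction("r3", {"A": -1, "y": 1}, kind="exchange")]
    net = StoichiometricNetwork(metabolites=mets, reactions=rxns)
    return net, _sol(["r1", "r2", "r3"], [2.0, 1.0, 1.0])


def test_dot_export_has_reaction_nodes_with_scaled_widths(tmp_path):
    net, sol = _fork_net_and_sol()
    path = tmp_path / "map.dot"
    export_flux_map(net, sol, path, format="dot")
    text = path.read_text()
    for rid in ("r1", "r2", "r3"):
        assert f'"{rid}"' in text
    # r1 carries twice the flux of r2/r3: its penwidth must be the largest
    import re

    widths = {m.group(1): float(m.group(2))
              for m in re.finditer(r'"(r\d)" \[shape=rect.*penwidth=([0-9.]+)',
                                   text)}
    assert widths["r1"] > widths["r2"] == widths["r3"]


def test_zero_flux_reaction_is_drawn_at_minimum_width(tmp_path):
    net, _ = _fork_net_and_sol()
    sol = _sol(["r1", "r2", "r3"], [2.0, 0.0, 2.0])
    path = tmp_path / "map.dot"
    export_flux_map(net, sol, path, format="dot")
    assert '"r2"' in path.read_text()


def test_graphml_round_trip_preserves_topology(tmp_path):
    net, sol = _fork_net_and_sol()
    path = tmp_path / "map.graphml"
    export_flux_map(net, sol, path, format="graphml")
    g = nx.read_graphml(path)
    assert set(g.nodes) == {"A", "x", "y", "r1", "r2", "r3"}
    assert g.has_edge("x", "r1") and g.has_edge("r1", "A")
    assert g.has_edge("A", "r2") and g.has_edge("r2", "y")


def test_two_solution_export_colors_changes(tmp_path):
    net, sol_a = _fork_net_and_sol()
    sol_b = _sol(["r1", "r2", "r3"], [2.0, 0.5, 1.5])
    path = tmp_path / "map.dot"
    export_flux_map(net, [sol_a, sol_b], path, format="dot")
    text = path.read_text()
    assert "blue" in text and "red" in text


def test_unknown_format_rejected(tmp_path):
    net, sol = _fork_net_and_sol()
    with pytest.raises(ValueError):
        export_flux_map(net, sol, tmp_path / "m.svg", format="svg")
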
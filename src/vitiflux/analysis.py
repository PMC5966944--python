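"""Comparison of flux maps and cofactor / alpha-ketoglutarate budgets.

The biological questions these tools answer: which fluxes reorganize
between two nutritional conditions (percent-change map), where does
each energy/redox carrier come from and go to at the optimum (cofactor
ledger), and how is the alpha-ketoglutarate pool split between the TCA
cycle, nitrogen assimilation and the 2-oxoglutarate-dependent
dioxygenases of the flavonoid branch (branch summary).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .model import NetworkError, StoichiometricNetwork
from .qp import FluxSolution

__all__ = [
    "FluxComparison",
    "CofactorLedger",
    "percent_change_map",
    "cofactor_ledger",
    "akg_branch_summary",
    "export_flux_map",
]


@dataclass
class FluxComparison:
    table: pd.DataFrame  # reaction_id, flux_control, flux_treatment,
    #                      percent_change, sign_flip, class
    control_label: str = ""
    treatment_label: str = ""
    day: float | None = None
    dead_band: float = 5.0

    def percent_change(self, rxn_id: str) -> float:
        row = self.table.loc[self.table["reaction_id"] == rxn_id]
        if row.empty:
            raise NetworkError(f"unknown reaction {rxn_id!r}")
        return float(row["percent_change"].iloc[0])

    def classification(self, rxn_id: str) -> str:
        row = self.table.loc[self.table["reaction_id"] == rxn_id]
        if row.empty:
            raise NetworkError(f"unknown reaction {rxn_id!r}")
        return str(row["class"].iloc[0])

    def to_csv(self, path) -> None:
        cols = ["reaction_id", "flux_control", "flux_treatment",
                "percent_change", "class"]
        self.table.sort_values("reaction_id")[cols].to_csv(
            path, index=False, float_format="%.10g")


def percent_change_map(control: FluxSolution, treatment: FluxSolution,
                       network: StoichiometricNetwork | None = None,
                       dead_band: float = 5.0,
                       eps: float = 1e-9) -> FluxComparison:
    """Relative flux changes, treatment vs control.

    percent_change = 100 * (v_t - v_c) / |v_c|; entries with
    |v_c| < eps are flagged undefined (NaN, class "undefined") rather
    than reported as +/- infinity. Sign flips (v_t opposing v_c) are
    flagged separately since a percentage folds direction and size
    together. Classification uses a dead band: |change| <= dead_band
    percent counts as "unchanged".
    """
    if list(control.reaction_ids) != list(treatment.reaction_ids):
        raise NetworkError("solutions have different reaction orderings")
    if network is not None and list(network.reaction_ids) != list(control.reaction_ids):
        raise NetworkError("network ordering differs from the solutions")

    vc = np.asarray(control.v, dtype=float)
    vt = np.asarray(treatment.v, dtype=float)
    defined = np.abs(vc) >= eps
    pct = np.full(vc.shape, np.nan)
    pct[defined] = 100.0 * (vt[defined] - vc[defined]) / np.abs(vc[defined])
    sign_flip = defined & (vc * vt < 0) & (np.abs(vt) >= eps)

    cls = np.where(~defined, "undefined",
                   np.where(np.abs(pct) <= dead_band, "unchanged",
                            np.where(pct > 0, "increased", "decreased")))
    table = pd.DataFrame({
        "reaction_id": control.reaction_ids,
        "flux_control": vc,
        "flux_treatment": vt,
        "percent_change": pct,
        "sign_flip": sign_flip,
        "class": cls,
    })
    return FluxComparison(table=table, dead_band=dead_band)


@dataclass
class CofactorLedger:
    cofactor_id: str
    contributions: pd.DataFrame  # reaction_id, coefficient, flux, rate
    total_production: float
    total_consumption: float  # <= 0

    @property
    def net(self) -> float:
        return self.total_production + self.total_consumption

    @property
    def producers(self) -> pd.DataFrame:
        df = self.contributions[self.contributions["rate"] > 0]
        return df.sort_values("rate", ascending=False, ignore_index=True)

    @property
    def consumers(self) -> pd.DataFrame:
        df = self.contributions[self.contributions["rate"] < 0]
        return df.sort_values("rate", ignore_index=True)


def cofactor_ledger(network: StoichiometricNetwork, solution: FluxSolution,
                    cofactor_id: str) -> CofactorLedger:
    """Per-reaction production/consumption budget of one cofactor.

    The signed rate of reaction j is (stoichiometric coefficient of the
    cofactor in j) x (flux of j). For any optimal steady-state solution
    the ledger nets to zero within the balance tolerance, because
    cofactors are balanced internal metabolites.
    """
    met = network.metabolite(cofactor_id)
    if not met.is_cofactor:
        raise NetworkError(f"{cofactor_id!r} is not flagged as a cofactor")
    return metabolite_ledger(network, solution, cofactor_id)


def metabolite_ledger(network: StoichiometricNetwork, solution: FluxSolution,
                      met_id: str) -> CofactorLedger:
    """Like :func:`cofactor_ledger` but for any internal metabolite."""
    network.metabolite(met_id)  # raises on unknown id
    rows = []
    for rid, rxn in zip(network.reaction_ids, network.reactions):
        coeff = rxn.stoichiometry.get(met_id)
        if coeff:
            v = solution.flux(rid)
            rows.append((rid, coeff, v, coeff * v))
    df = pd.DataFrame(rows, columns=["reaction_id", "coefficient", "flux", "rate"])
    prod = float(df.loc[df["rate"] > 0, "rate"].sum()) if len(df) else 0.0
    cons = float(df.loc[df["rate"] < 0, "rate"].sum()) if len(df) else 0.0
    return CofactorLedger(cofactor_id=met_id, contributions=df,
                          total_production=prod, total_consumption=cons)


def akg_branch_summary(network: StoichiometricNetwork, solution: FluxSolution,
                       akg_id: str = "akg", eps: float = 1e-12) -> pd.DataFrame:
    """Where the alpha-ketoglutarate pool goes.

    Lists every reaction with a net positive consumption of alpha-KG at
    the solution (TCA oxidation, GOGAT, aminotransferases running
    toward glutamate, and the dioxygenase steps of the flavonoid
    branch), with each reaction's share of total consumption. Shares
    are non-negative and sum to 1 when total consumption is positive.
    """
    if not any(m.id == akg_id and m.role == "internal"
               for m in network.metabolites):
        raise NetworkError(f"alpha-ketoglutarate ({akg_id!r}) is not an "
                           "internal metabolite of this network")
    ledger = metabolite_ledger(network, solution, akg_id)
    cons = ledger.contributions.loc[
        ledger.contributions["rate"] < -eps].copy()
    cons["consumption"] = -cons["rate"]
    total = float(cons["consumption"].sum())
    cons["share"] = cons["consumption"] / total if total > 0 else np.nan
    cons = cons.sort_values("consumption", ascending=False, ignore_index=True)
    return cons[["reaction_id", "flux", "consumption", "share"]]


# ----------------------------------------------------------------------
# graph export
# ----------------------------------------------------------------------

def _flux_graph(network: StoichiometricNetwork,
                solutions: list[FluxSolution],
                min_width: float = 0.2,
                max_width: float = 6.0,
                dead_band: float = 5.0) -> nx.DiGraph:
    """Bipartite metabolite/reaction graph with flux-scaled edge widths."""
    primary = solutions[0]
    vmax = float(np.max(np.abs(primary.v))) if len(primary.v) else 1.0
    if vmax <= 0:
        vmax = 1.0
    comparison = None
    if len(solutions) == 2:
        comparison = percent_change_map(solutions[0], solutions[1],
                                        dead_band=dead_band)
        cls = dict(zip(comparison.table["reaction_id"], comparison.table["class"]))
    g = nx.DiGraph()
    for m in network.metabolites:
        g.add_node(m.id, node_type="metabolite", label=m.name or m.id,
                   role=m.role)
    color_of = {"increased": "red", "decreased": "blue",
                "unchanged": "grey", "undefined": "lightgrey"}
    for rid, rxn in zip(network.reaction_ids, network.reactions):
        v = primary.flux(rid)
        width = min_width + (max_width - min_width) * abs(v) / vmax
        attrs = dict(node_type="reaction", label=rid, flux=float(v),
                     width=float(width))
        if comparison is not None:
            attrs["change_class"] = cls[rid]
            attrs["color"] = color_of[cls[rid]]
        g.add_node(rid, **attrs)
        for met_id, coeff in sorted(rxn.stoichiometry.items()):
            # orient edges by the sign of coeff * flux direction of the map
            ew = dict(width=float(width), coefficient=float(coeff))
            if comparison is not None:
                ew["color"] = color_of[cls[rid]]
            if coeff < 0:
                g.add_edge(met_id, rid, **ew)
            else:
                g.add_edge(rid, met_id, **ew)
    return g


def export_flux_map(network: StoichiometricNetwork,
                    solutions: FluxSolution | list[FluxSolution],
                    path, format: str = "dot", dead_band: float = 5.0) -> None:
    """Export a flux map as DOT or GraphML.

    ``solutions`` is one solution (edge width proportional to |flux|,
    zero-flux reactions drawn at minimum width, never omitted) or a
    [control, treatment] pair (edge/node color encodes the direction of
    the percent change: red increased, blue decreased).
    """
    if isinstance(solutions, FluxSolution):
        solutions = [solutions]
    if len(solutions) not in (1, 2):
        raise ValueError("export_flux_map takes one or two solutions")
    fmt = format.lower()
    if fmt not in ("dot", "graphml"):
        raise ValueError(f"unknown format {format!r} (use 'dot' or 'graphml')")
    g = _flux_graph(network, solutions, dead_band=dead_band)
    if fmt == "graphml":
        nx.write_graphml(g, path)
        return
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("digraph fluxmap {\n  rankdir=LR;\n")
        for node, data in sorted(g.nodes(data=True)):
            if data["node_type"] == "metabolite":
                shape = "ellipse" if data["role"] == "internal" else "box"
                fh.write(f'  "{node}" [shape={shape}, label="{data["label"]}"];\n')
            else:
                color = data.get("color", "black")
                fh.write(f'  "{node}" [shape=rect, style=rounded, '
                         f'label="{data["label"]}", color={color}, '
                         f'penwidth={data["width"]:.3f}];\n')
        for u, v, data in sorted(g.edges(data=True)):
            color = data.get("color", "black")
            fh.write(f'  "{u}" -> "{v}" [penwidth={data["width"]:.3f}, '
                     f'color={color}];\n')
        fh.write("}\n")
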
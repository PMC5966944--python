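"""Stoichiometric network data model.

A network is a list of metabolites (internal species are mass-balanced,
external species are boundary pools such as medium nutrients or biomass
sinks) and an ordered list of reactions. The reaction order fixes the
indexing of every flux vector produced downstream.

Reaction ``kind`` distinguishes:

* ``internal`` — ordinary enzymatic steps, subject to the stoichiometric
  consistency test;
* ``exchange`` — uptake from the medium or accumulation into a storage
  pool; must touch at least one external metabolite;
* ``overall`` — lumped biosynthetic reactions (protein, cell wall,
  lipids, nucleotides, phenolic end products) whose composition is an
  empirical average rather than an elementally balanced equation;
* ``maintenance`` — non-growth-associated ATP hydrolysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "Metabolite",
    "Reaction",
    "StoichiometricNetwork",
    "ConsistencyReport",
    "NetworkError",
    "build_matrix",
    "check_consistency",
]

ROLES = ("internal", "external")
KINDS = ("internal", "exchange", "overall", "maintenance")


class NetworkError(ValueError):
    """Structural problem in a network definition."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    role: str = "internal"
    compartment_tag: str = ""
    is_cofactor: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkError("metabolite id must be non-empty")
        if self.role not in ROLES:
            raise NetworkError(f"metabolite {self.id!r}: unknown role {self.role!r}")
        if self.is_cofactor and self.role != "internal":
            raise NetworkError(
                f"cofactor {self.id!r} must be internal (cofactors are balanced)"
            )


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: dict  # metabolite id -> signed coefficient; negative = consumed
    name: str = ""
    reversible: bool = False
    capacity: float | None = None  # mmol / g DW / day
    kind: str = "internal"

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise NetworkError(f"reaction {self.id!r}: empty stoichiometry")
        if self.kind not in KINDS:
            raise NetworkError(f"reaction {self.id!r}: unknown kind {self.kind!r}")
        if self.capacity is not None and not self.capacity >= 0:
            raise NetworkError(f"reaction {self.id!r}: capacity must be >= 0")

    def consumes(self, met_id: str) -> bool:
        return self.stoichiometry.get(met_id, 0.0) < 0

    def produces(self, met_id: str) -> bool:
        return self.stoichiometry.get(met_id, 0.0) > 0


@dataclass
class StoichiometricNetwork:
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups -------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def internal_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if m.role == "internal"]

    @property
    def m_int(self) -> int:
        return len(self.internal_metabolites)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_irreversible_internal(self) -> int:
        """Irreversible reactions among non-exchange kinds.

        Exchange reactions are unidirectional too, but the conventional
        count of irreversible steps in a metabolic map refers to the
        reactions *of* the network, not its boundary fluxes.
        """
        return sum(
            1 for r in self.reactions if r.kind != "exchange" and not r.reversible
        )

    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self._met_index[met_id]
        except KeyError:
            raise NetworkError(f"unknown metabolite {met_id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index[rxn_id]
        except KeyError:
            raise NetworkError(f"unknown reaction {rxn_id!r}") from None

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dupes = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise NetworkError(f"duplicate metabolite ids: {dupes}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dupes = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise NetworkError(f"duplicate reaction ids: {dupes}")
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}
        for r in self.reactions:
            for met_id in r.stoichiometry:
                if met_id not in self._met_index:
                    raise NetworkError(
                        f"reaction {r.id!r} references unknown metabolite {met_id!r}"
                    )
            if r.kind == "exchange" and not any(
                self._met_index[m].role == "external" for m in r.stoichiometry
            ):
                raise NetworkError(
                    f"exchange reaction {r.id!r} touches no external metabolite"
                )

    def with_reaction(self, rxn: Reaction) -> "StoichiometricNetwork":
        """Copy of the network with one reaction replaced (matched by id)."""
        reactions = [rxn if r.id == rxn.id else r for r in self.reactions]
        return StoichiometricNetwork(
            metabolites=list(self.metabolites),
            reactions=reactions,
            provenance=self.provenance,
        )

    def permuted(self, order: list[int]) -> "StoichiometricNetwork":
        """Copy with reactions re-ordered (columns permute identically)."""
        reactions = [self.reactions[i] for i in order]
        return StoichiometricNetwork(
            metabolites=list(self.metabolites),
            reactions=reactions,
            provenance=self.provenance,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StoichiometricNetwork):
            return NotImplemented
        return (
            self.metabolites == other.metabolites
            and [_rxn_key(r) for r in self.reactions]
            == [_rxn_key(r) for r in other.reactions]
        )


def _rxn_key(r: Reaction):
    return (r.id, r.name, tuple(sorted(r.stoichiometry.items())), r.reversible,
            r.capacity, r.kind)


def build_matrix(network: StoichiometricNetwork) -> np.ndarray:
    """Assemble the stoichiometric matrix over internal metabolites.

    Rows follow the order of internal metabolites in ``network.metabolites``,
    columns the order of ``network.reactions``; entry (i, j) is the signed
    coefficient of internal metabolite i in reaction j. External metabolites
    contribute no row: they are the unbalanced boundary of the system.
    """
    network.validate()
    if not network.reactions:
        raise NetworkError("cannot build a matrix for a network with no reactions")
    internal = network.internal_metabolites
    row_of = {m.id: i for i, m in enumerate(internal)}
    S = np.zeros((len(internal), len(network.reactions)))
    for j, rxn in enumerate(network.reactions):
        for met_id, coeff in rxn.stoichiometry.items():
            i = row_of.get(met_id)
            if i is not None:
                S[i, j] = coeff
    return S


@dataclass
class ConsistencyReport:
    conserved: bool
    weights: dict | None
    orphan_metabolites: list[str]
    dead_end_metabolites: list[str]

    @property
    def ok(self) -> bool:
        return self.conserved and not self.orphan_metabolites


def check_consistency(network: StoichiometricNetwork) -> ConsistencyReport:
    """Stoichiometric consistency and connectivity report.

    ``conserved`` is true iff a strictly positive weight (a generalized
    molecular mass) can be assigned to every internal metabolite such
    that every internal and maintenance reaction conserves total weight.
    Exchange and overall reactions are excluded: they deliberately move
    mass across the boundary or use empirical lumped compositions.

    Solved as a linear feasibility problem: find w >= 1 with
    S_core^T w = 0, where S_core keeps only the tested reaction columns.
    """
    network.validate()
    internal = network.internal_metabolites
    orphans = [
        m.id
        for m in internal
        if not any(m.id in r.stoichiometry for r in network.reactions)
    ]
    dead_ends = []
    for m in internal:
        produced = any(r.produces(m.id) or (r.reversible and r.consumes(m.id))
                       for r in network.reactions)
        consumed = any(r.consumes(m.id) or (r.reversible and r.produces(m.id))
                       for r in network.reactions)
        if m.id not in orphans and not (produced and consumed):
            dead_ends.append(m.id)

    core_cols = [
        j for j, r in enumerate(network.reactions) if r.kind in ("internal", "maintenance")
    ]
    weights = None
    conserved = True
    if internal and core_cols:
        S = build_matrix(network)[:, core_cols]
        m = S.shape[0]
        # feasibility: S^T w = 0, w >= 1 (scale-free; any positive vector works)
        res = linprog(
            c=np.zeros(m),
            A_eq=S.T,
            b_eq=np.zeros(S.shape[1]),
            bounds=[(1.0, None)] * m,
            method="highs",
        )
        conserved = res.status == 0
        if conserved:
            weights = {met.id: float(w) for met, w in zip(internal, res.x)}
    return ConsistencyReport(
        conserved=conserved,
        weights=weights,
        orphan_metabolites=orphans,
        dead_end_metabolites=dead_ends,
    )
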
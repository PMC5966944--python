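"""Plain-text reaction/metabolite table format.

Two tab-separated files describe a network:

* metabolite table: ``met_id  name  role  compartment_tag  is_cofactor``
* reaction table: ``reaction_id  name  kind  reversible(0/1)
  capacity(mmol/gDW/day or "inf")  stoichiometry``

where the stoichiometry column is ``metId:coeff`` pairs separated by
``;`` (e.g. ``g6p:-1;f6p:1``). UTF-8; ``#`` starts a comment line.
Writing is canonical (sorted stoichiometry keys, fixed column order),
so write -> read -> write is byte-stable.
"""

from __future__ import annotations

from fractions import Fraction

from .model import Metabolite, NetworkError, Reaction, StoichiometricNetwork

__all__ = ["load_reaction_table", "write_reaction_table", "TableParseError"]


class TableParseError(NetworkError):
    """Malformed table file; message includes the offending line number."""


def _fmt_coeff(x: float) -> str:
    f = Fraction(x).limit_denominator(10**6)
    if float(f) == x:
        return str(f)  # exact rational (covers integers and e.g. 2/5)
    return repr(x)


def _parse_coeff(tok: str, path, lineno: int) -> float:
    try:
        if "/" in tok:
            return float(Fraction(tok))
        return float(tok)
    except (ValueError, ZeroDivisionError):
        raise TableParseError(
            f"{path}:{lineno}: malformed coefficient {tok!r}") from None


def _data_lines(path):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def load_reaction_table(reactions_path, metabolites_path,
                        provenance: str = "") -> StoichiometricNetwork:
    """Load a network from the metabolite + reaction TSV pair."""
    metabolites = []
    for lineno, line in _data_lines(metabolites_path):
        parts = line.split("\t")
        if len(parts) != 5:
            raise TableParseError(
                f"{metabolites_path}:{lineno}: expected 5 columns, got {len(parts)}")
        mid, name, role, tag, cof = parts
        if cof not in ("0", "1"):
            raise TableParseError(
                f"{metabolites_path}:{lineno}: is_cofactor must be 0 or 1")
        metabolites.append(Metabolite(id=mid, name=name, role=role,
                                      compartment_tag=tag, is_cofactor=cof == "1"))
    known = {m.id for m in metabolites}

    reactions = []
    for lineno, line in _data_lines(reactions_path):
        parts = line.split("\t")
        if len(parts) != 6:
            raise TableParseError(
                f"{reactions_path}:{lineno}: expected 6 columns, got {len(parts)}")
        rid, name, kind, rev, cap, stoich_s = parts
        if rev not in ("0", "1"):
            raise TableParseError(
                f"{reactions_path}:{lineno}: reversible must be 0 or 1")
        capacity = None if cap == "inf" else _parse_coeff(cap, reactions_path, lineno)
        stoich = {}
        for pair in stoich_s.split(";"):
            pair = pair.strip()
            if not pair:
                continue
            if ":" not in pair:
                raise TableParseError(
                    f"{reactions_path}:{lineno}: malformed pair {pair!r}")
            met_id, coeff_s = pair.rsplit(":", 1)
            if met_id not in known:
                raise TableParseError(
                    f"{reactions_path}:{lineno}: unknown metabolite id {met_id!r}")
            stoich[met_id] = _parse_coeff(coeff_s, reactions_path, lineno)
        reactions.append(Reaction(id=rid, name=name, kind=kind,
                                  reversible=rev == "1", capacity=capacity,
                                  stoichiometry=stoich))
    return StoichiometricNetwork(metabolites=metabolites, reactions=reactions,
                                 provenance=provenance)


def write_reaction_table(network: StoichiometricNetwork,
                         reactions_path, metabolites_path) -> None:
    """Write the canonical TSV pair (round-trips with load_reaction_table)."""
    with open(metabolites_path, "w", encoding="utf-8") as fh:
        fh.write("# met_id\tname\trole\tcompartment_tag\tis_cofactor\n")
        for m in network.metabolites:
            fh.write(f"{m.id}\t{m.name}\t{m.role}\t{m.compartment_tag}\t"
                     f"{int(m.is_cofactor)}\n")
    with open(reactions_path, "w", encoding="utf-8") as fh:
        fh.write("# reaction_id\tname\tkind\treversible\tcapacity\tstoichiometry\n")
        for r in network.reactions:
            cap = "inf" if r.capacity is None else _fmt_coeff(r.capacity)
            stoich = ";".join(f"{k}:{_fmt_coeff(v)}"
                              for k, v in sorted(r.stoichiometry.items()))
            fh.write(f"{r.id}\t{r.name}\t{r.kind}\t{int(r.reversible)}\t"
                     f"{cap}\t{stoich}\n")
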
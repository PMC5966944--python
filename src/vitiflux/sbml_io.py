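"""SBML Level 3 core read/write.

External metabolites are encoded as species with
``boundaryCondition="true"`` (on reading, species in a configured
boundary compartment are also treated as external). Attributes SBML
core has no slot for — the reaction kind, an optional capacity, the
cofactor flag, and the original id when it is not a valid SBML SId
(e.g. ``Vnga-ATPm``) — travel in the notes body and are restored on
reading, so write -> read is the identity on the data model. Kinetic
laws, rules and events encountered in foreign files are ignored with a
warning.
"""

from __future__ import annotations

import logging
import re

import libsbml

from .model import Metabolite, NetworkError, Reaction, StoichiometricNetwork

__all__ = ["read_sbml", "write_sbml", "SBMLError"]

log = logging.getLogger(__name__)


class SBMLError(NetworkError):
    pass


def _parse_notes(notes: str) -> dict:
    m = re.search(r"vitiflux\{([^}]*)\}", notes)
    if not m:
        return {}
    out = {}
    for field in m.group(1).split("|"):
        if "=" in field:
            k, v = field.split("=", 1)
            out[k] = v
    return out


def _notes(fields: dict) -> str:
    body = "|".join(f"{k}={v}" for k, v in fields.items())
    return (f'<notes><body xmlns="http://www.w3.org/1999/xhtml">'
            f"<p>vitiflux{{{body}}}</p></body></notes>")


def _sanitize(token: str) -> str:
    out = re.sub(r"[^A-Za-z0-9_]", "_", token)
    if not out or not (out[0].isalpha() or out[0] == "_"):
        out = "_" + out
    return out


def write_sbml(network: StoichiometricNetwork, path) -> None:
    doc = libsbml.SBMLDocument(3, 2)
    model = doc.createModel()
    model.setId("vitiflux_model")
    if network.provenance:
        model.setName(network.provenance[:250])

    compartments = sorted({m.compartment_tag or "cell" for m in network.metabolites})
    for tag in compartments:
        c = model.createCompartment()
        c.setId(_sanitize(tag))
        c.setName(tag)
        c.setConstant(True)
        c.setSize(1.0)

    sid_of = {m.id: _sanitize(m.id) for m in network.metabolites}
    if len(set(sid_of.values())) != len(sid_of):
        raise SBMLError("metabolite ids collide after SBML sanitization")

    for m in network.metabolites:
        sp = model.createSpecies()
        sp.setId(sid_of[m.id])
        sp.setName(m.name)
        sp.setCompartment(_sanitize(m.compartment_tag or "cell"))
        sp.setBoundaryCondition(m.role == "external")
        sp.setHasOnlySubstanceUnits(True)
        sp.setConstant(False)
        sp.setNotes(_notes({"id": m.id, "cofactor": int(m.is_cofactor),
                            "tag": m.compartment_tag}))

    for r in network.reactions:
        rx = model.createReaction()
        rx.setId(_sanitize(r.id))
        rx.setName(r.name)
        rx.setReversible(r.reversible)
        fields = {"id": r.id, "kind": r.kind}
        if r.capacity is not None:
            fields["capacity"] = repr(r.capacity)
        # exact coefficients: the XML attribute carries only 15 significant
        # digits, which clips values like 2/3
        fields["sto"] = ",".join(f"{k}:{v!r}"
                                 for k, v in sorted(r.stoichiometry.items()))
        rx.setNotes(_notes(fields))
        for met_id, coeff in sorted(r.stoichiometry.items()):
            ref = rx.createReactant() if coeff < 0 else rx.createProduct()
            ref.setStoichiometry(abs(coeff))
            ref.setSpecies(sid_of[met_id])
            ref.setConstant(True)

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise SBMLError(f"could not write SBML to {path}")


def read_sbml(path, boundary_compartments: tuple = ("medium", "boundary", "b")
              ) -> StoichiometricNetwork:
    doc = libsbml.SBMLReader().readSBML(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [doc.getError(i).getMessage() for i in range(doc.getNumErrors())]
        raise SBMLError(f"SBML parse errors in {path}: {msgs[:3]}")
    model = doc.getModel()
    if model is None:
        raise SBMLError(f"no model in {path}")

    comp_name = {}
    for i in range(model.getNumCompartments()):
        c = model.getCompartment(i)
        comp_name[c.getId()] = c.getName() or c.getId()

    metabolites = []
    orig_id = {}
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        meta = _parse_notes(sp.getNotesString()) if sp.isSetNotes() else {}
        mid = meta.get("id", sp.getId())
        orig_id[sp.getId()] = mid
        tag = meta.get("tag", comp_name.get(sp.getCompartment(), sp.getCompartment()))
        external = (sp.getBoundaryCondition()
                    or sp.getCompartment() in boundary_compartments)
        is_cof = meta.get("cofactor", "0") == "1"
        metabolites.append(Metabolite(
            id=mid, name=sp.getName(),
            role="external" if external else "internal",
            compartment_tag=tag, is_cofactor=is_cof and not external))

    reactions = []
    for i in range(model.getNumReactions()):
        rx = model.getReaction(i)
        if rx.isSetKineticLaw():
            log.warning("SBML reaction %s carries a kinetic law; ignored "
                        "(this package is stoichiometry-only)", rx.getId())
        stoich = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            if not ref.isSetStoichiometry():
                raise SBMLError(
                    f"reaction {rx.getId()}: reactant without stoichiometry")
            k = orig_id.get(ref.getSpecies(), ref.getSpecies())
            stoich[k] = stoich.get(k, 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            if not ref.isSetStoichiometry():
                raise SBMLError(
                    f"reaction {rx.getId()}: product without stoichiometry")
            k = orig_id.get(ref.getSpecies(), ref.getSpecies())
            stoich[k] = stoich.get(k, 0.0) + ref.getStoichiometry()
        if not stoich:
            raise SBMLError(f"reaction {rx.getId()}: no stoichiometry at all")
        meta = _parse_notes(rx.getNotesString()) if rx.isSetNotes() else {}
        if "sto" in meta:
            stoich = {}
            for pair in meta["sto"].split(","):
                k, v = pair.rsplit(":", 1)
                stoich[k] = float(v)
        rid = meta.get("id", rx.getId())
        kind = meta.get("kind")
        if kind is None:
            ext_ids = {m.id for m in metabolites if m.role == "external"}
            kind = "exchange" if ext_ids & set(stoich) else "internal"
        capacity = float(meta["capacity"]) if "capacity" in meta else None
        reactions.append(Reaction(
            id=rid, name=rx.getName(), stoichiometry=stoich,
            reversible=rx.getReversible(), capacity=capacity, kind=kind))

    if model.getNumRules() or model.getNumEvents():
        log.warning("SBML rules/events present in %s; ignored", path)

    return StoichiometricNetwork(
        metabolites=metabolites, reactions=reactions,
        provenance=model.getName() or f"read from {path}")
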
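"""Model serialisation: a documented JSON dialect and SBML L3V1 with fbc.

JSON dialect
------------
A single object with keys ``id``, ``compartments``, ``metabolites``,
``reactions``, ``objective``::

    {"id": "...", "compartments": ["c0", "e0"],
     "metabolites": [{"id", "name", "formula", "charge", "compartment"}, ...],
     "reactions": [{"id", "name", "stoichiometry": {met: coef},
                    "lower_bound", "upper_bound", "gene_rule",
                    "subsystem", "ec", "kind"}, ...],
     "objective": {"reaction": "...", "sense": "maximize"}}

SBML
----
Written as Level 3 Version 1 with the fbc (version 2) package: flux bounds as
parameters, the objective in ``fbc:listOfObjectives`` and gene rules as
``fbc:geneProductAssociation``.  The reader accepts models written by this
package as well as externally produced fbc models (e.g. the deposited
genome-scale model of *A. neopropionicum*).
"""

from __future__ import annotations

import json
from pathlib import Path

import libsbml

from .core import MetabolicModel, Metabolite, Reaction

__all__ = ["read_json", "write_json", "read_sbml", "write_sbml"]


class SBMLParseError(ValueError):
    """Raised when an SBML document cannot be parsed into a model."""


# ---------------------------------------------------------------------------
# JSON
# ---------------------------------------------------------------------------

def write_json(model: MetabolicModel, path: str | Path) -> None:
    doc = {
        "id": model.id,
        "compartments": list(model.compartments),
        "metabolites": [
            {"id": m.id, "name": m.name, "formula": m.formula,
             "charge": m.charge, "compartment": m.compartment}
            for m in model.metabolites.values()
        ],
        "reactions": [
            {"id": r.id, "name": r.name, "stoichiometry": r.stoichiometry,
             "lower_bound": r.lower_bound, "upper_bound": r.upper_bound,
             "gene_rule": r.gene_rule, "subsystem": r.subsystem,
             "ec": r.ec, "kind": r.kind}
            for r in model.reactions.values()
        ],
        "objective": {"reaction": model.objective_id,
                      "sense": model.objective_sense},
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=False))


def read_json(path: str | Path) -> MetabolicModel:
    doc = json.loads(Path(path).read_text())
    model = MetabolicModel(
        id=doc.get("id", "model"),
        compartments=tuple(doc.get("compartments", ("c0", "e0"))),
        objective_id=doc.get("objective", {}).get("reaction", ""),
        objective_sense=doc.get("objective", {}).get("sense", "maximize"),
    )
    for m in doc["metabolites"]:
        model.add_metabolite(Metabolite(
            id=m["id"], name=m.get("name", ""), formula=m.get("formula"),
            charge=int(m.get("charge", 0)),
            compartment=m.get("compartment", "c0")))
    for r in doc["reactions"]:
        model.add_reaction(Reaction(
            id=r["id"], name=r.get("name", ""),
            stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
            lower_bound=float(r["lower_bound"]),
            upper_bound=float(r["upper_bound"]),
            gene_rule=r.get("gene_rule", ""), subsystem=r.get("subsystem", ""),
            ec=r.get("ec", ""), kind=r.get("kind", "metabolic")))
    model.validate()
    return model


# ---------------------------------------------------------------------------
# SBML (L3V1 + fbc v2)
# ---------------------------------------------------------------------------

def _sid(raw: str) -> str:
    """Make an SBML-safe SId (prefix leading digits, map odd characters)."""
    out = "".join(ch if ch.isalnum() or ch == "_" else "__" for ch in raw)
    if out and out[0].isdigit():
        out = "_" + out
    return out


def write_sbml(model: MetabolicModel, path: str | Path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sb = doc.createModel()
    sb.setId(_sid(model.id))
    mplug = sb.getPlugin("fbc")
    mplug.setStrict(True)

    for comp in model.compartments:
        c = sb.createCompartment()
        c.setId(comp); c.setConstant(True); c.setSize(1.0)

    for met in model.metabolites.values():
        sp = sb.createSpecies()
        sp.setId(_sid(met.id)); sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        splug = sp.getPlugin("fbc")
        splug.setCharge(met.charge)
        if met.formula is not None:
            splug.setChemicalFormula(met.formula)

    genes: set[str] = set()
    for rxn in model.reactions.values():
        for tok in rxn.gene_rule.replace("(", " ").replace(")", " ").split():
            if tok not in ("and", "or", "AND", "OR"):
                genes.add(tok)
    for g in sorted(genes):
        gp = mplug.createGeneProduct()
        gp.setId(_sid(g)); gp.setLabel(g)

    def _param(pid: str, value: float) -> str:
        p = sb.createParameter()
        p.setId(pid); p.setValue(value); p.setConstant(True)
        return pid

    for rxn in model.reactions.values():
        r = sb.createReaction()
        rid = _sid(rxn.id)
        r.setId(rid); r.setName(rxn.name or rxn.id)
        r.setReversible(rxn.lower_bound < 0)
        r.setFast(False)
        note = (f"<body xmlns='http://www.w3.org/1999/xhtml'>"
                f"<p>KIND: {rxn.kind}</p>"
                f"<p>SUBSYSTEM: {rxn.subsystem}</p>"
                f"<p>EC: {rxn.ec}</p></body>")
        r.setNotes(note)
        for mid, coef in rxn.stoichiometry.items():
            ref = r.createReactant() if coef < 0 else r.createProduct()
            ref.setSpecies(_sid(mid))
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rplug = r.getPlugin("fbc")
        rplug.setLowerFluxBound(_param(f"{rid}_lb", rxn.lower_bound))
        rplug.setUpperFluxBound(_param(f"{rid}_ub", rxn.upper_bound))
        if rxn.gene_rule:
            gpa = rplug.createGeneProductAssociation()
            gpa.setAssociation(
                _sid_rule(rxn.gene_rule), True)

    if model.objective_id:
        obj = mplug.createObjective()
        obj.setId("obj"); obj.setType(model.objective_sense)
        fo = obj.createFluxObjective()
        fo.setReaction(_sid(model.objective_id))
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")


def _sid_rule(rule: str) -> str:
    """Rewrite each gene token of a boolean rule as its SBML SId."""
    out = []
    for tok in rule.replace("(", " ( ").replace(")", " ) ").split():
        if tok in ("and", "or", "AND", "OR", "(", ")"):
            out.append(tok.lower() if tok in ("AND", "OR") else tok)
        else:
            out.append(_sid(tok))
    return " ".join(out)


def _association_to_rule(assoc, mplug) -> str:
    """Render an fbc association tree back into a boolean gene-rule string."""
    if assoc is None:
        return ""
    if assoc.isGeneProductRef():
        gp = mplug.getGeneProduct(assoc.getGeneProduct())
        return gp.getLabel() if gp is not None and gp.getLabel() else \
            assoc.getGeneProduct()
    op = " and " if assoc.isFbcAnd() else " or "
    parts = [
        _association_to_rule(assoc.getAssociation(i), mplug)
        for i in range(assoc.getNumAssociations())
    ]
    joined = op.join(parts)
    return f"({joined})" if len(parts) > 1 else joined


def read_sbml(path: str | Path) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        err = doc.getError(0)
        raise SBMLParseError(
            f"SBML parse error at line {err.getLine()}: {err.getMessage()}")
    sb = doc.getModel()
    if sb is None:
        raise SBMLParseError(f"no model element found in {path}")
    mplug = sb.getPlugin("fbc")

    model = MetabolicModel(
        id=sb.getId() or "model",
        compartments=tuple(
            sb.getCompartment(i).getId() for i in range(sb.getNumCompartments())
        ) or ("c0", "e0"),
    )
    for i in range(sb.getNumSpecies()):
        sp = sb.getSpecies(i)
        splug = sp.getPlugin("fbc")
        formula = None
        charge = 0
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = splug.getChemicalFormula() or None
            if splug.isSetCharge():
                charge = splug.getCharge()
        model.add_metabolite(Metabolite(
            id=sp.getId(), name=sp.getName() or "", formula=formula,
            charge=charge, compartment=sp.getCompartment()))

    def _bound(r, which: str) -> float:
        rplug = r.getPlugin("fbc")
        default = -1e30 if which == "lower" else 1e30
        if rplug is not None:
            pid = (rplug.getLowerFluxBound() if which == "lower"
                   else rplug.getUpperFluxBound())
            if pid:
                p = sb.getParameter(pid)
                if p is not None:
                    return p.getValue()
        return default if r.getReversible() or which == "upper" else 0.0

    for i in range(sb.getNumReactions()):
        r = sb.getReaction(i)
        sto: dict[str, float] = {}
        for j in range(r.getNumReactants()):
            ref = r.getReactant(j)
            sto[ref.getSpecies()] = sto.get(ref.getSpecies(), 0.0) \
                - ref.getStoichiometry()
        for j in range(r.getNumProducts()):
            ref = r.getProduct(j)
            sto[ref.getSpecies()] = sto.get(ref.getSpecies(), 0.0) \
                + ref.getStoichiometry()
        kind, subsystem, ec = "", "", ""
        if r.isSetNotes():
            notes = r.getNotesString()
            for line in notes.splitlines():
                text = line.strip()
                for tag in ("KIND:", "SUBSYSTEM:", "EC:"):
                    if tag in text:
                        val = text.split(tag, 1)[1].split("<", 1)[0].strip()
                        if tag == "KIND:":
                            kind = val
                        elif tag == "SUBSYSTEM:":
                            subsystem = val
                        else:
                            ec = val
        if not kind:
            # externally produced SBML: classify single-species reactions
            # (and conventional EX_/DM_/SK_ ids) as exchanges
            kind = "exchange" if (
                len(sto) == 1 or r.getId().startswith(("EX_", "DM_", "SK_"))
            ) else "metabolic"
        rule = ""
        rplug = r.getPlugin("fbc")
        if rplug is not None and rplug.isSetGeneProductAssociation():
            rule = _association_to_rule(
                rplug.getGeneProductAssociation().getAssociation(), mplug)
            if rule.startswith("(") and rule.endswith(")"):
                inner, depth = rule[1:-1], 0
                if all((depth := depth + {"(": 1, ")": -1}.get(ch, 0)) >= 0
                       for ch in inner):
                    rule = inner
        model.add_reaction(Reaction(
            id=r.getId(), name=r.getName() or "",
            stoichiometry=sto,
            lower_bound=_bound(r, "lower"), upper_bound=_bound(r, "upper"),
            gene_rule=rule, subsystem=subsystem, ec=ec, kind=kind))

    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getObjective(mplug.getActiveObjectiveId()) \
            or mplug.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            model.objective_id = obj.getFluxObjective(0).getReaction()
            model.objective_sense = "maximize" \
                if obj.getType() == "maximize" else "minimize"
    model.validate()
    return model
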
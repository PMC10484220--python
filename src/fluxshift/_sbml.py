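"""SBML Level 3 reader/writer (core + fbc bounds/objective + groups subsystems).

Only the constructs needed for constraint-based simulation are mapped:
stoichiometry, flux bounds, the linear objective, subsystem labels and gene
lists. Kinetic laws, rules and events are ignored with a logged warning.

Subsystem labels are resolved in priority order: groups-package membership,
then a ``SUBSYSTEM: <label>`` line in the reaction notes, else
``"Unassigned"``. Gene lists round-trip through a ``GENE_ASSOCIATION:``
notes line (boolean gene-protein-reaction logic is out of scope).
"""

from __future__ import annotations

import logging
from pathlib import Path

import libsbml

from .exceptions import FormatError
from .metnet import (
    UNASSIGNED_SUBSYSTEM,
    MetabolicModel,
    Metabolite,
    Reaction,
)

log = logging.getLogger(__name__)

_SBML_LEVEL, _SBML_VERSION = 3, 1
_FBC_VERSION = 2
_GROUPS_VERSION = 1


def _notes_lookup(notes: str, key: str) -> str | None:
    for line in notes.splitlines():
        text = line.strip()
        # strip surrounding xhtml tags like <p>...</p>
        while text.startswith("<") and ">" in text:
            text = text[text.index(">") + 1 :].strip()
        while text.endswith(">") and "<" in text:
            text = text[: text.rindex("<")].strip()
        if text.upper().startswith(key.upper() + ":"):
            return text[len(key) + 1 :].strip()
    return None


def read_sbml(path: str | Path) -> MetabolicModel:
    doc = libsbml.readSBMLFromString(Path(path).read_text())
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise FormatError(
            f"SBML parse error at line {err.getLine()}: {err.getMessage().strip()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise FormatError("SBML document contains no <model> element")

    metabolites = tuple(
        Metabolite(
            id=s.getId(),
            name=s.getName() or "",
            compartment=s.getCompartment() or "c",
        )
        for s in sbml_model.getListOfSpecies()
    )

    # fbc objective
    objective: dict[str, float] = {}
    fbc = sbml_model.getPlugin("fbc")
    if fbc is not None and fbc.getNumObjectives() > 0:
        active = fbc.getActiveObjective() or fbc.getObjective(0)
        for fo in active.getListOfFluxObjectives():
            objective[fo.getReaction()] = fo.getCoefficient()

    # groups -> subsystem
    subsystem_of: dict[str, str] = {}
    groups = sbml_model.getPlugin("groups")
    if groups is not None:
        for g in groups.getListOfGroups():
            label = g.getName() or g.getId()
            for member in g.getListOfMembers():
                subsystem_of[member.getIdRef()] = label

    reactions = []
    for r in sbml_model.getListOfReactions():
        if r.isSetKineticLaw():
            log.warning(
                "ignoring kinetic law on reaction %s (not used in "
                "constraint-based simulation)",
                r.getId(),
            )
        stoich: dict[str, float] = {}
        for sr in r.getListOfReactants():
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for sr in r.getListOfProducts():
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if v != 0.0}

        lb, ub = None, None
        rfbc = r.getPlugin("fbc")
        if rfbc is not None:
            if rfbc.isSetLowerFluxBound():
                p = sbml_model.getParameter(rfbc.getLowerFluxBound())
                lb = p.getValue() if p is not None else None
            if rfbc.isSetUpperFluxBound():
                p = sbml_model.getParameter(rfbc.getUpperFluxBound())
                ub = p.getValue() if p is not None else None
        if lb is None:
            lb = -1000.0 if r.getReversible() else 0.0
        if ub is None:
            ub = 1000.0

        notes = r.getNotesString() if r.isSetNotes() else ""
        subsystem = subsystem_of.get(r.getId()) or _notes_lookup(notes, "SUBSYSTEM") \
            or UNASSIGNED_SUBSYSTEM
        gene_note = _notes_lookup(notes, "GENE_ASSOCIATION")
        genes = tuple(gene_note.split()) if gene_note else ()

        reactions.append(
            Reaction(
                id=r.getId(),
                name=r.getName() or "",
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                subsystem=subsystem,
                genes=genes,
                exchange=not stoich,
            )
        )

    return MetabolicModel(
        id=sbml_model.getId() or "model",
        metabolites=metabolites,
        reactions=tuple(reactions),
        objective=objective,
    )


def write_sbml(model: MetabolicModel, path: str | Path) -> None:
    ns = libsbml.SBMLNamespaces(_SBML_LEVEL, _SBML_VERSION)
    ns.addPackageNamespace("fbc", _FBC_VERSION)
    ns.addPackageNamespace("groups", _GROUPS_VERSION)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    doc.setPackageRequired("groups", False)
    sm = doc.createModel()
    sm.setId(model.id or "model")
    mfbc = sm.getPlugin("fbc")
    mfbc.setStrict(False)

    compartments = sorted({m.compartment or "c" for m in model.metabolites}) or ["c"]
    for cid in compartments:
        c = sm.createCompartment()
        c.setId(cid)
        c.setConstant(True)

    for met in model.metabolites:
        s = sm.createSpecies()
        s.setId(met.id)
        s.setName(met.name)
        s.setCompartment(met.compartment or "c")
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)

    bound_params: dict[float, str] = {}

    def _bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions:
        r = sm.createReaction()
        r.setId(rxn.id)
        r.setName(rxn.name)
        r.setReversible(rxn.lower_bound < 0)
        r.setFast(False)
        for mid, coef in rxn.stoichiometry.items():
            sr = r.createReactant() if coef < 0 else r.createProduct()
            sr.setSpecies(mid)
            sr.setStoichiometry(abs(coef))
            sr.setConstant(True)
        rfbc = r.getPlugin("fbc")
        rfbc.setLowerFluxBound(_bound_param(rxn.lower_bound))
        rfbc.setUpperFluxBound(_bound_param(rxn.upper_bound))
        notes = [f"SUBSYSTEM: {rxn.subsystem}"]
        if rxn.genes:
            notes.append("GENE_ASSOCIATION: " + " ".join(rxn.genes))
        body = "".join(f"<p>{line}</p>" for line in notes)
        r.setNotes(
            f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'
        )

    if model.objective:
        obj = mfbc.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        for rid in sorted(model.objective):
            fo = obj.createFluxObjective()
            fo.setReaction(rid)
            fo.setCoefficient(model.objective[rid])
        mfbc.setActiveObjectiveId("obj")

    groups = sm.getPlugin("groups")
    for i, subsystem in enumerate(
        sorted({r.subsystem for r in model.reactions})
    ):
        g = groups.createGroup()
        g.setId(f"g{i}")
        g.setName(subsystem)
        g.setKind("partonomy")
        for rxn in model.reactions:
            if rxn.subsystem == subsystem:
                member = g.createMember()
                member.setIdRef(rxn.id)

    Path(path).write_text(libsbml.writeSBMLToString(doc))
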
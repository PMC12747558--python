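"""Draft model reconstruction from EC sets, and model I/O.

Reconstruction is template-based: a draft model keeps every template
reaction whose EC annotation intersects the genome's EC set, plus all
exchange reactions, all EC-free (spontaneous/transport) reactions and the
biomass reaction.  Enlarging the EC set therefore never removes reactions.

Two serialisations are supported:

* the **native format** — a sectioned tab-separated text file, one model
  per file, round-tripping bit-exactly (documented in
  ``docs/native_model_format.md``); this is the source of truth;
* **SBML Level 3** (with the ``fbc`` package for bounds and objective) for
  interoperability.  Unsupported SBML constructs are reported via warnings,
  never silently dropped.
"""

from __future__ import annotations

import logging
from pathlib import Path

from .model import MetabolicModel, Metabolite, ModelValidationError, Reaction
from .templates import ReactionTemplate

logger = logging.getLogger(__name__)

NATIVE_HEADER = "# hydroscreen native model format v1"


class ModelParseError(ValueError):
    """A model file failed to parse; message carries line/element context."""


def build_draft_model(ec_set: set[str] | frozenset[str], template: ReactionTemplate,
                      model_id: str = "draft") -> MetabolicModel:
    """Reconstruct a draft model from an EC set against the template.

    An empty EC set still yields a model (exchanges, transports, biomass
    only) with a warning: such a model has no catabolism and cannot grow.
    """
    ec_set = frozenset(ec_set)
    if not ec_set:
        logger.warning(
            "model %s: empty EC set; draft contains no catabolic reactions "
            "and cannot grow on any medium", model_id,
        )
    universal = template.universal
    kept: list[Reaction] = []
    for r in universal.reactions:
        if (
            not r.ec_numbers                      # spontaneous / transport / exchange
            or r.id == template.biomass_id
            or r.ec_numbers & ec_set
        ):
            kept.append(r)
    model = MetabolicModel(
        model_id=model_id,
        metabolites=list(universal.metabolites),
        reactions=kept,
        objective_reaction_id=template.biomass_id,
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# native format
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return repr(float(x))


def _check_token(token: str, what: str) -> str:
    if any(ch in token for ch in "\t\n;:"):
        raise ModelParseError(f"{what} {token!r} contains a reserved character")
    return token


def write_native(model: MetabolicModel, path: str | Path) -> None:
    model.validate()
    lines = [NATIVE_HEADER, f"MODEL\t{_check_token(model.model_id, 'model id')}",
             f"OBJECTIVE\t{model.objective_reaction_id}", "[METABOLITES]"]
    for m in model.metabolites:
        lines.append(f"{_check_token(m.id, 'metabolite id')}\t{m.name}\t{m.compartment}")
    lines.append("[REACTIONS]")
    for r in model.reactions:
        ecs = ";".join(sorted(r.ec_numbers))
        stoich = ";".join(
            f"{met}:{_fmt(coeff)}" for met, coeff in sorted(r.stoichiometry.items())
        )
        lines.append(
            f"{_check_token(r.id, 'reaction id')}\t{_fmt(r.lower_bound)}\t"
            f"{_fmt(r.upper_bound)}\t{ecs}\t{stoich}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_native(path: str | Path) -> MetabolicModel:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0] != NATIVE_HEADER:
        raise ModelParseError(f"{path}: line 1: missing native-format header")
    model_id = ""
    objective = ""
    metabolites: list[Metabolite] = []
    reactions: list[Reaction] = []
    section = ""
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.startswith("#"):
            continue
        if line in ("[METABOLITES]", "[REACTIONS]"):
            section = line
            continue
        fields = line.split("\t")
        try:
            if fields[0] == "MODEL":
                model_id = fields[1]
            elif fields[0] == "OBJECTIVE":
                objective = fields[1]
            elif section == "[METABOLITES]":
                mid, name, compartment = fields
                metabolites.append(Metabolite(mid, name, compartment))
            elif section == "[REACTIONS]":
                rid, lb, ub, ecs, stoich_s = fields
                stoich = {}
                for part in stoich_s.split(";"):
                    met, coeff = part.rsplit(":", 1)
                    stoich[met] = float(coeff)
                ec_numbers = frozenset(e for e in ecs.split(";") if e)
                reactions.append(
                    Reaction(rid, stoich, float(lb), float(ub), ec_numbers)
                )
            else:
                raise ValueError("content outside any section")
        except (ValueError, IndexError, ModelValidationError) as exc:
            raise ModelParseError(f"{path}: line {lineno}: {exc}") from exc
    if not objective:
        raise ModelParseError(f"{path}: missing OBJECTIVE declaration")
    model = MetabolicModel(model_id, metabolites, reactions, objective)
    try:
        model.validate()
    except ModelValidationError as exc:
        raise ModelParseError(f"{path}: {exc}") from exc
    return model


# ---------------------------------------------------------------------------
# SBML (Level 3 + fbc)
# ---------------------------------------------------------------------------

def write_sbml(model: MetabolicModel, path: str | Path) -> None:
    import libsbml

    model.validate()
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.model_id)
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    for comp_id in ("internal", "external"):
        comp = sm.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)
        comp.setSize(1.0)

    for met in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        sp.setInitialConcentration(0.0)

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"bnd_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions:
        sr = sm.createReaction()
        sr.setId(rxn.id)
        sr.setReversible(rxn.lower_bound < 0)
        sr.setFast(False)
        if rxn.ec_numbers:
            sr.setNotes(
                "<body xmlns='http://www.w3.org/1999/xhtml'><p>EC: "
                + ";".join(sorted(rxn.ec_numbers)) + "</p></body>"
            )
        for met_id, coeff in sorted(rxn.stoichiometry.items()):
            ref = sr.createReactant() if coeff < 0 else sr.createProduct()
            ref.setSpecies(met_id)
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))

    objective = mplug.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    fo = objective.createFluxObjective()
    fo.setReaction(model.objective_reaction_id)
    fo.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"failed to write SBML to {path}")


def read_sbml(path: str | Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getError(0)
        raise ModelParseError(
            f"{path}: SBML error at line {err.getLine()}: {err.getMessage()}"
        )
    sm = doc.getModel()
    if sm is None:
        raise ModelParseError(f"{path}: file contains no SBML model")

    unsupported: list[str] = []
    if sm.getNumEvents():
        unsupported.append(f"{sm.getNumEvents()} events")
    if sm.getNumRules():
        unsupported.append(f"{sm.getNumRules()} rules")
    if sm.getNumConstraints():
        unsupported.append(f"{sm.getNumConstraints()} constraints")

    metabolites = []
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        compartment = "external" if sp.getCompartment() == "external" else "internal"
        if sp.getCompartment() not in ("internal", "external"):
            unsupported.append(
                f"species {sp.getId()}: compartment {sp.getCompartment()!r} "
                "mapped to internal"
            )
        if sp.getBoundaryCondition():
            unsupported.append(f"species {sp.getId()}: boundaryCondition ignored")
        metabolites.append(Metabolite(sp.getId(), sp.getName() or "", compartment))

    def param_value(pid: str, default: float) -> float:
        p = sm.getParameter(pid)
        return p.getValue() if p is not None else default

    reactions = []
    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        if sr.isSetKineticLaw():
            unsupported.append(f"reaction {sr.getId()}: kinetic law ignored")
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        rplug = sr.getPlugin("fbc")
        if rplug is not None and rplug.isSetLowerFluxBound():
            lb = param_value(rplug.getLowerFluxBound(), -1000.0)
            ub = param_value(rplug.getUpperFluxBound(), 1000.0)
        else:
            lb = -1000.0 if sr.getReversible() else 0.0
            ub = 1000.0
            unsupported.append(
                f"reaction {sr.getId()}: no fbc bounds; defaults from reversibility"
            )
        ec_numbers: frozenset[str] = frozenset()
        if sr.isSetNotes():
            notes = sr.getNotesString()
            if "EC: " in notes:
                chunk = notes.split("EC: ", 1)[1].split("<", 1)[0]
                ec_numbers = frozenset(e for e in chunk.split(";") if e)
        reactions.append(Reaction(sr.getId(), stoich, lb, ub, ec_numbers))

    mplug = sm.getPlugin("fbc")
    objective_id = ""
    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getObjective(mplug.getActiveObjectiveId() or 0) or mplug.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            objective_id = obj.getFluxObjective(0).getReaction()
    if not objective_id:
        raise ModelParseError(f"{path}: SBML model declares no growth objective")

    for msg in unsupported:
        logger.warning("SBML import %s: unsupported construct — %s", path, msg)

    model = MetabolicModel(sm.getId() or Path(path).stem, metabolites, reactions, objective_id)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

FORMATS = ("native", "sbml")


def write_model(model: MetabolicModel, path: str | Path, fmt: str = "native") -> None:
    if fmt == "native":
        write_native(model, path)
    elif fmt == "sbml":
        write_sbml(model, path)
    else:
        raise ValueError(f"unknown model format {fmt!r}; expected one of {FORMATS}")


def read_model(path: str | Path, fmt: str = "native") -> MetabolicModel:
    if fmt == "native":
        return read_native(path)
    if fmt == "sbml":
        return read_sbml(path)
    raise ValueError(f"unknown model format {fmt!r}; expected one of {FORMATS}")
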
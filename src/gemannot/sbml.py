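"""SBML import/export with MIRIAM CV terms and notes-based annotations.

Reading accepts SBML Level 2 or 3. Controlled-vocabulary resource URIs
become cross-reference annotations via the registry; URIs the registry
cannot resolve are preserved verbatim as note annotations rather than
dropped. ``KEY: value`` notes lines are extracted per the notes dialect.

Writing always emits SBML Level 3 Version 1 core: every cross reference
becomes a CV term (biological qualifier "is") with an identifiers.org URI;
structures, formulas, charges and synonyms go to structured notes. The
registry snapshot version used for encoding is recorded in the model notes.

Stoichiometric coefficients live as exact rationals in memory but as IEEE
doubles in SBML; on read they are recovered with a denominator-limited
rational approximation, exact for every decimal coefficient a curator would
type.
"""

from __future__ import annotations

from fractions import Fraction
from pathlib import Path

import libsbml

from .miriam import (
    Registry,
    RegistryError,
    UriParseError,
    XrefValidationError,
    default_registry,
    from_uri,
    to_uri,
)
from .model import (
    Annotation,
    AnnotationKind,
    Metabolite,
    Model,
    ModelIntegrityError,
    Reaction,
    ReactionParticipant,
    Side,
)
from .notes import DEFAULT_DIALECT, NotesDialect, extract_notes_annotations, render_notes_lines

__all__ = ["SbmlError", "read_sbml", "write_sbml"]

_UNRESOLVED_PREFIX = "unresolved-uri: "
_DEFAULT_COMPARTMENT = "default"


class SbmlError(ValueError):
    """Malformed SBML input or invalid SBML output."""


def _fraction(value: float) -> Fraction:
    return Fraction(value).limit_denominator(10**6)


def _notes_body(sbase) -> str:
    if not sbase.isSetNotes():
        return ""
    return libsbml.XMLNode.convertXMLNodeToString(sbase.getNotes())


def _strip_markup(xml_text: str) -> str:
    """Notes XHTML to plain text, one line per <p>/text line."""
    from lxml import etree

    try:
        root = etree.fromstring(xml_text.encode())
    except etree.XMLSyntaxError:
        return xml_text
    return "\n".join(t.strip() for t in root.itertext() if t.strip())


def _collect_cv_annotations(sbase, registry: Registry) -> list[Annotation]:
    anns: list[Annotation] = []
    for i in range(sbase.getNumCVTerms()):
        term = sbase.getCVTerm(i)
        for j in range(term.getNumResources()):
            uri = term.getResourceURI(j)
            try:
                xref = from_uri(uri, registry)
                anns.append(Annotation(AnnotationKind.CROSSREF, xref))
            except (UriParseError, RegistryError, XrefValidationError):
                anns.append(Annotation.note(_UNRESOLVED_PREFIX + uri))
    return anns


def read_sbml(
    path,
    registry: Registry | None = None,
    dialect: NotesDialect = DEFAULT_DIALECT,
    extract_notes: bool = True,
) -> tuple[Model, list[str]]:
    """Read an SBML L2/L3 file; returns (model, warnings).

    With ``extract_notes=True`` (default) notes ``KEY: value`` lines become
    annotations immediately; with ``extract_notes=False`` the raw notes text
    is retained on each entity for the annotation pipeline's notes-transfer
    step to promote (and log) explicitly.
    """
    registry = registry or default_registry()
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SbmlError(
            f"SBML parse error at line {err.getLine()}: {err.getMessage().strip()}"
        )
    smodel = doc.getModel()
    if smodel is None:
        raise SbmlError(f"{path}: no model element")
    warnings: list[str] = []
    model = Model(id=smodel.getId() or "model")

    for i in range(smodel.getNumCompartments()):
        comp = smodel.getCompartment(i)
        model.compartments[comp.getId()] = comp.getName() or comp.getId()

    for i in range(smodel.getNumSpecies()):
        sp = smodel.getSpecies(i)
        met = Metabolite(
            id=sp.getId(), name=sp.getName() or "", compartment=sp.getCompartment() or ""
        )
        if sp.isSetCharge():  # SBML L2 charge attribute
            met.add_annotation(Annotation.charge(sp.getCharge()))
        for ann in _collect_cv_annotations(sp, registry):
            met.add_annotation(ann)
        notes = _notes_body(sp)
        if notes:
            text = _strip_markup(notes)
            if extract_notes:
                anns, warns = extract_notes_annotations(text, dialect, registry)
                warnings.extend(f"{sp.getId()}: {w}" for w in warns)
                for ann in anns:
                    met.add_annotation(ann)
            else:
                met.raw_notes = text
        model.add_metabolite(met)

    for i in range(smodel.getNumReactions()):
        srxn = smodel.getReaction(i)
        participants: list[ReactionParticipant] = []
        for j in range(srxn.getNumReactants()):
            ref = srxn.getReactant(j)
            participants.append(
                ReactionParticipant(
                    ref.getSpecies(), _fraction(ref.getStoichiometry()), Side.REACTANT
                )
            )
        for j in range(srxn.getNumProducts()):
            ref = srxn.getProduct(j)
            participants.append(
                ReactionParticipant(
                    ref.getSpecies(), _fraction(ref.getStoichiometry()), Side.PRODUCT
                )
            )
        rxn = Reaction(
            id=srxn.getId(),
            name=srxn.getName() or "",
            participants=participants,
            reversible=srxn.getReversible(),
        )
        for ann in _collect_cv_annotations(srxn, registry):
            rxn.add_annotation(ann)
        notes = _notes_body(srxn)
        if notes:
            text = _strip_markup(notes)
            if extract_notes:
                anns, warns = extract_notes_annotations(text, dialect, registry)
                warnings.extend(f"{srxn.getId()}: {w}" for w in warns)
                for ann in anns:
                    rxn.add_annotation(ann)
            else:
                rxn.raw_notes = text
        try:
            model.add_reaction(rxn)
        except ModelIntegrityError as exc:
            raise SbmlError(str(exc)) from exc
    return model, warnings


def _set_notes(sbase, lines: list[str]) -> None:
    if not lines:
        return
    body = "".join(f"<p>{_escape(line)}</p>" for line in lines)
    xhtml = f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'
    if sbase.setNotes(xhtml) != libsbml.LIBSBML_OPERATION_SUCCESS:
        raise SbmlError(f"could not set notes on {sbase.getId()!r}")


def _escape(text: str) -> str:
    return text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")


def _write_annotations(
    sbase, entity, registry: Registry, dialect: NotesDialect
) -> None:
    sbase.setMetaId(f"meta_{entity.id}")
    notes_anns = []
    for ann in entity.annotations:
        if ann.kind == AnnotationKind.CROSSREF:
            cv = libsbml.CVTerm()
            cv.setQualifierType(libsbml.BIOLOGICAL_QUALIFIER)
            cv.setBiologicalQualifierType(libsbml.BQB_IS)
            cv.addResource(to_uri(ann.value, registry))
            if sbase.addCVTerm(cv) != libsbml.LIBSBML_OPERATION_SUCCESS:
                raise SbmlError(f"could not add CV term on {entity.id!r}")
        elif ann.kind == AnnotationKind.NOTE and ann.value.startswith(_UNRESOLVED_PREFIX):
            notes_anns.append(ann)  # preserved verbatim, never dropped
        else:
            notes_anns.append(ann)
    _set_notes(sbase, render_notes_lines(notes_anns, dialect))


def write_sbml(
    model: Model,
    path,
    registry: Registry | None = None,
    dialect: NotesDialect = DEFAULT_DIALECT,
) -> None:
    """Write the model as SBML Level 3 Version 1 core."""
    registry = registry or default_registry()
    model.validate()

    # validate every cross reference up front, reporting offenders together
    bad: list[str] = []
    for entity in list(model.metabolites.values()) + list(model.reactions.values()):
        for xref in entity.crossrefs():
            try:
                xref.validated(registry)
            except Exception:
                bad.append(entity.id)
    if bad:
        raise SbmlError(f"invalid cross references on: {sorted(set(bad))}")

    doc = libsbml.SBMLDocument(3, 1)
    smodel = doc.createModel()
    smodel.setId(model.id or "model")
    smodel.setMetaId(f"meta_{model.id or 'model'}")
    _set_notes(smodel, [f"NOTE: annotation registry {registry.version}"])

    compartments = dict(model.compartments)
    if not compartments:
        compartments[_DEFAULT_COMPARTMENT] = _DEFAULT_COMPARTMENT
    for cid, cname in compartments.items():
        comp = smodel.createCompartment()
        comp.setId(cid)
        comp.setName(cname)
        comp.setConstant(True)

    for met in model.metabolites.values():
        sp = smodel.createSpecies()
        sp.setId(met.id)
        if met.name:
            sp.setName(met.name)
        sp.setCompartment(met.compartment or next(iter(compartments)))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        _write_annotations(sp, met, registry, dialect)

    for rxn in model.reactions.values():
        srxn = smodel.createReaction()
        srxn.setId(rxn.id)
        if rxn.name:
            srxn.setName(rxn.name)
        srxn.setReversible(rxn.reversible)
        srxn.setFast(False)
        for p in rxn.participants:
            ref = (
                srxn.createReactant() if p.side == Side.REACTANT else srxn.createProduct()
            )
            ref.setSpecies(p.metabolite_id)
            ref.setStoichiometry(float(p.coefficient))
            ref.setConstant(True)
        _write_annotations(srxn, rxn, registry, dialect)

    doc.checkInternalConsistency()
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SbmlError(f"output SBML invalid: {err.getMessage().strip()}")
    libsbml.writeSBMLToFile(doc, str(path))
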
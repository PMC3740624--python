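"""Minimal KGML (KEGG pathway XML) import: compounds and reactions only.

Compound ``entry`` elements become metabolites; the ``cpd:``-stripped token
is stored as a kegg.compound cross reference. ``reaction`` elements become
reactions with all substrates/products at coefficient 1 (KGML carries no
stoichiometry) honoring the ``type="reversible"`` attribute. Map and
graphics elements are ignored.
"""

from __future__ import annotations

from fractions import Fraction

from lxml import etree

from .miriam import CrossReference, Registry, XrefValidationError, default_registry
from .model import (
    Annotation,
    AnnotationKind,
    Metabolite,
    Model,
    Reaction,
    ReactionParticipant,
    Side,
)

__all__ = ["KgmlError", "read_kgml"]


class KgmlError(ValueError):
    """Malformed KGML XML."""


def _strip_prefix(token: str, prefix: str) -> str:
    return token[len(prefix):] if token.startswith(prefix) else token


def read_kgml(path, registry: Registry | None = None) -> tuple[Model, list[str]]:
    """Read a KGML pathway file; returns (model, warnings)."""
    registry = registry or default_registry()
    warnings: list[str] = []
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise KgmlError(f"KGML parse error: {exc}") from exc
    root = tree.getroot()
    if root.tag != "pathway":
        raise KgmlError(f"expected <pathway> root, got <{root.tag}>")

    model = Model(id=root.get("name", "kgml_pathway").replace(":", "_"))
    entry_to_metabolite: dict[str, str] = {}

    for entry in root.findall("entry"):
        if entry.get("type") != "compound":
            continue
        # entry name holds one or more "cpd:CXXXXX" tokens
        for token in (entry.get("name") or "").split():
            ident = _strip_prefix(token, "cpd:")
            if ident in model.metabolites:
                entry_to_metabolite.setdefault(entry.get("id", ident), ident)
                continue
            met = Metabolite(id=ident, name=ident)
            try:
                xref = CrossReference("kegg.compound", ident).validated(registry)
                met.add_annotation(Annotation(AnnotationKind.CROSSREF, xref))
            except XrefValidationError:
                warnings.append(
                    f"entry {entry.get('id')}: token {token!r} is not a valid "
                    f"kegg.compound identifier"
                )
            model.add_metabolite(met)
            entry_to_metabolite.setdefault(entry.get("id", ident), ident)

    def resolve(el) -> str:
        name = _strip_prefix(el.get("name", ""), "cpd:")
        if name in model.metabolites:
            return name
        ref = entry_to_metabolite.get(el.get("id", ""))
        if ref:
            return ref
        # participant never declared as an entry: create it
        met = Metabolite(id=name, name=name)
        try:
            xref = CrossReference("kegg.compound", name).validated(registry)
            met.add_annotation(Annotation(AnnotationKind.CROSSREF, xref))
        except XrefValidationError:
            warnings.append(f"reaction participant {name!r} has a non-KEGG token")
        model.add_metabolite(met)
        return name

    n_reactions = 0
    for rel in root.findall("reaction"):
        rid = _strip_prefix(rel.get("name", f"r{n_reactions}"), "rn:").split()[0]
        participants = [
            ReactionParticipant(resolve(s), Fraction(1), Side.REACTANT)
            for s in rel.findall("substrate")
        ] + [
            ReactionParticipant(resolve(p), Fraction(1), Side.PRODUCT)
            for p in rel.findall("product")
        ]
        if not participants:
            warnings.append(f"reaction {rid!r} has no participants, skipped")
            continue
        rxn = Reaction(
            id=rid,
            name=rid,
            participants=participants,
            reversible=rel.get("type") == "reversible",
        )
        try:
            xref = CrossReference("kegg.reaction", rid).validated(registry)
            rxn.add_annotation(Annotation(AnnotationKind.CROSSREF, xref))
        except XrefValidationError:
            pass
        model.add_reaction(rxn)
        n_reactions += 1
    if n_reactions == 0:
        warnings.append("KGML file contains no reactions; model has metabolites only")
    return model, warnings
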
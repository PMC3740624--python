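"""Key/value annotation extraction from SBML notes blocks.

Published models frequently stash curation data in free-text notes as
``KEY: value`` lines (the COBRA convention): FORMULA, CHARGE, INCHI, KEGG …
A :class:`NotesDialect` maps the key aliases seen in the wild onto semantic
fields; unmatched lines are ignored, invalid values are reported as
warnings, never silently kept.

All structure-bearing keys found in one notes block (INCHI, SMILES and the
bookkeeping keys STRUCTURE_FORMULA / STRUCTURE_CHARGE written by this
package) merge into a single structure annotation — they describe the same
molecule.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .formula import FormulaError, parse_formula
from .miriam import (
    CrossReference,
    Registry,
    RegistryError,
    XrefValidationError,
    default_registry,
)
from .model import Annotation, AnnotationKind, ChemicalStructure, StructureError

__all__ = ["NotesDialect", "DEFAULT_DIALECT", "extract_notes_annotations"]

_STRUCTURE_FIELDS = {"inchi", "smiles", "structure_formula", "structure_charge"}


@dataclass(frozen=True)
class NotesDialect:
    """Alias table from notes keys (upper-cased) to semantic fields.

    Semantic fields: ``formula``, ``charge``, ``inchi``, ``smiles``,
    ``structure_formula``, ``structure_charge``, ``synonym``, ``note``, and
    ``xref:<namespace>``. Each alias maps to exactly one field.
    """

    aliases: tuple[tuple[str, str], ...] = (
        ("FORMULA", "formula"),
        ("CHEMICAL_FORMULA", "formula"),
        ("CHARGE", "charge"),
        ("INCHI", "inchi"),
        ("SMILES", "smiles"),
        ("STRUCTURE_FORMULA", "structure_formula"),
        ("STRUCTURE_CHARGE", "structure_charge"),
        ("SYNONYM", "synonym"),
        ("NOTE", "note"),
        ("KEGG", "xref:kegg.compound"),
        ("KEGG_ID", "xref:kegg.compound"),
        ("KEGG_COMPOUND", "xref:kegg.compound"),
        ("KEGG_REACTION", "xref:kegg.reaction"),
        ("CHEBI", "xref:chebi"),
        ("CHEBI_ID", "xref:chebi"),
        ("HMDB", "xref:hmdb"),
        ("PUBCHEM", "xref:pubchem.compound"),
        ("SEED", "xref:seed.compound"),
        ("METACYC", "xref:metacyc.compound"),
        ("EC_NUMBER", "xref:ec-code"),
        ("EC", "xref:ec-code"),
    )

    def __post_init__(self):
        seen: dict[str, str] = {}
        for key, fieldname in self.aliases:
            if key in seen and seen[key] != fieldname:
                raise ValueError(f"ambiguous notes alias {key!r}")
            seen[key] = fieldname
        object.__setattr__(self, "_table", seen)

    def field_for(self, key: str) -> str | None:
        return self._table.get(key.strip().upper().replace(" ", "_"))

    def key_for(self, fieldname: str) -> str:
        """First alias serializing a semantic field (canonical write key)."""
        for key, f in self.aliases:
            if f == fieldname:
                return key
        if fieldname.startswith("xref:"):
            return fieldname[5:].upper().replace(".", "_")
        raise KeyError(fieldname)


DEFAULT_DIALECT = NotesDialect()

_LINE_RE = re.compile(r"^\s*([A-Za-z][A-Za-z0-9_ .]*?)\s*:\s*(.+?)\s*$")


def extract_notes_annotations(
    notes_text: str,
    dialect: NotesDialect = DEFAULT_DIALECT,
    registry: Registry | None = None,
) -> tuple[list[Annotation], list[str]]:
    """Turn ``KEY: value`` lines into annotations; returns (annotations, warnings).

    Cross-reference values are validated against the registry before
    acceptance; rejects produce a warning. Unrecognized keys are ignored.
    """
    registry = registry or default_registry()
    annotations: list[Annotation] = []
    warnings: list[str] = []
    structure_parts: dict[str, str] = {}
    for raw in notes_text.splitlines():
        m = _LINE_RE.match(raw)
        if not m:
            continue
        key, value = m.group(1), m.group(2)
        fieldname = dialect.field_for(key)
        if fieldname is None:
            continue
        if fieldname in _STRUCTURE_FIELDS:
            structure_parts[fieldname] = value
        elif fieldname == "formula":
            try:
                annotations.append(Annotation.formula(parse_formula(value)))
            except FormulaError as exc:
                warnings.append(f"{key}: {exc}")
        elif fieldname == "charge":
            try:
                annotations.append(Annotation.charge(int(value)))
            except ValueError:
                warnings.append(f"{key}: non-integer charge {value!r}")
        elif fieldname == "synonym":
            annotations.append(Annotation.synonym(value))
        elif fieldname == "note":
            annotations.append(Annotation.note(value))
        elif fieldname.startswith("xref:"):
            ns = fieldname[5:]
            try:
                xref = CrossReference(ns, value).validated(registry)
                annotations.append(Annotation(AnnotationKind.CROSSREF, xref))
            except (XrefValidationError, RegistryError) as exc:
                warnings.append(f"{key}: rejected identifier {value!r} ({exc})")
    if structure_parts:
        try:
            formula = (
                parse_formula(structure_parts["structure_formula"])
                if "structure_formula" in structure_parts
                else None
            )
            charge = (
                int(structure_parts["structure_charge"])
                if "structure_charge" in structure_parts
                else None
            )
            struct = ChemicalStructure(
                inchi=structure_parts.get("inchi"),
                smiles=structure_parts.get("smiles"),
                formula=formula,
                formal_charge=charge,
            )
            annotations.append(Annotation.structure(struct))
        except (FormulaError, StructureError, ValueError) as exc:
            warnings.append(f"structure notes rejected: {exc}")
    return annotations, warnings


def render_notes_lines(
    annotations, dialect: NotesDialect = DEFAULT_DIALECT
) -> list[str]:
    """Serialize non-CV-term annotations back to ``KEY: value`` lines."""
    lines: list[str] = []
    for ann in annotations:
        if ann.kind == AnnotationKind.FORMULA:
            lines.append(f"{dialect.key_for('formula')}: {ann.value.to_hill()}")
        elif ann.kind == AnnotationKind.CHARGE:
            lines.append(f"{dialect.key_for('charge')}: {ann.value}")
        elif ann.kind == AnnotationKind.SYNONYM:
            lines.append(f"{dialect.key_for('synonym')}: {ann.value}")
        elif ann.kind == AnnotationKind.NOTE:
            lines.append(f"{dialect.key_for('note')}: {ann.value}")
        elif ann.kind == AnnotationKind.STRUCTURE:
            s = ann.value
            if s.inchi:
                lines.append(f"{dialect.key_for('inchi')}: {s.inchi}")
            if s.smiles:
                lines.append(f"{dialect.key_for('smiles')}: {s.smiles}")
            if s.formula is not None:
                lines.append(
                    f"{dialect.key_for('structure_formula')}: {s.formula.to_hill()}"
                )
            if s.formal_charge is not None:
                lines.append(f"{dialect.key_for('structure_charge')}: {s.formal_charge}")
    return lines
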
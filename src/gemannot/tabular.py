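"""Spreadsheet model import with an explicit column mapping.

Draft reconstructions are curated in spreadsheets whose column layout varies
between groups. Instead of guessing by position, the caller declares a
:class:`ColumnMapping` from semantic fields to column labels — metabolite
sheets map ``id`` (required) plus optionally ``name``, ``formula``,
``charge``, ``compartment``, ``inchi``, ``smiles`` and any number of
``xref:<namespace>`` fields; reaction sheets map ``id`` and ``equation``
(required) plus optionally ``name`` and xref fields.

CSV, TSV and xlsx workbooks are accepted through one pandas-based reader.
Metabolites that appear only inside reaction equations are auto-created
with a warning, matching how spreadsheet models are actually written.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import pandas as pd

from .equation import ParsedEquation, parse_equation
from .formula import FormulaError, parse_formula
from .miriam import CrossReference, Registry, RegistryError, XrefValidationError, default_registry
from .model import (
    Annotation,
    AnnotationKind,
    ChemicalStructure,
    Metabolite,
    Model,
    ModelIntegrityError,
    Reaction,
    ReactionParticipant,
    Side,
)

__all__ = ["ColumnMapping", "MappingError", "read_tabular", "read_table"]


class MappingError(ValueError):
    """Missing required mapping or mapped column absent from the table."""


@dataclass
class ColumnMapping:
    metabolites: dict[str, str]
    reactions: dict[str, str]
    default_compartment: str = ""

    def __post_init__(self):
        if "id" not in self.metabolites:
            raise MappingError("metabolite sheet mapping must include 'id'")
        if "id" not in self.reactions or "equation" not in self.reactions:
            raise MappingError("reaction sheet mapping must include 'id' and 'equation'")

    @staticmethod
    def from_json(path) -> "ColumnMapping":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        return ColumnMapping(
            metabolites=doc["metabolites"],
            reactions=doc["reactions"],
            default_compartment=doc.get("default_compartment", ""),
        )


def read_table(path) -> pd.DataFrame:
    """One tabular abstraction over CSV, TSV and xlsx sheets."""
    path = str(path)
    if path.endswith((".xlsx", ".xlsm")):
        return pd.read_excel(path, dtype=str, engine="openpyxl").fillna("")
    sep = "\t" if path.endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _cell(row: dict, mapping: dict[str, str], fieldname: str) -> Optional[str]:
    label = mapping.get(fieldname)
    if label is None:
        return None
    v = str(row.get(label, "")).strip()
    return v or None


_ID_SANITIZE = re.compile(r"[^A-Za-z0-9_]")


def _auto_id(name: str) -> str:
    token = _ID_SANITIZE.sub("_", name).strip("_")
    if not token or not (token[0].isalpha() or token[0] == "_"):
        token = "m_" + token
    return token


def _check_columns(frame: pd.DataFrame, mapping: dict[str, str], sheet: str) -> None:
    missing = sorted(set(mapping.values()) - set(frame.columns))
    if missing:
        raise MappingError(f"{sheet} sheet: mapped column(s) {missing} not in table")


def _apply_xrefs(
    entity, row: dict, mapping: dict[str, str], registry: Registry, warnings: list[str]
) -> None:
    for fieldname, label in mapping.items():
        if not fieldname.startswith("xref:"):
            continue
        value = str(row.get(label, "")).strip()
        if not value:
            continue
        ns = fieldname[5:]
        try:
            xref = CrossReference(ns, value).validated(registry)
            entity.add_annotation(Annotation(AnnotationKind.CROSSREF, xref))
        except (XrefValidationError, RegistryError) as exc:
            warnings.append(f"{entity.id}: rejected xref {ns}:{value} ({exc})")


def read_tabular(
    metabolite_table,
    reaction_table,
    mapping: ColumnMapping,
    registry: Registry | None = None,
    model_id: str = "model",
) -> tuple[Model, list[str]]:
    """Build a model from metabolite and reaction sheets; returns (model, warnings)."""
    registry = registry or default_registry()
    warnings: list[str] = []
    model = Model(id=model_id)

    met_frame = read_table(metabolite_table)
    _check_columns(met_frame, mapping.metabolites, "metabolite")
    dupes = [
        mid
        for mid, n in met_frame[mapping.metabolites["id"]].value_counts().items()
        if n > 1
    ]
    if dupes:
        raise ModelIntegrityError(f"duplicate metabolite ids in sheet: {sorted(dupes)}")

    # maps equation participant names back to declared metabolites
    by_name: dict[str, str] = {}
    for row in met_frame.to_dict(orient="records"):
        mid = _cell(row, mapping.metabolites, "id")
        if not mid:
            raise ModelIntegrityError("metabolite row with empty id")
        met = Metabolite(
            id=mid,
            name=_cell(row, mapping.metabolites, "name") or mid,
            compartment=_cell(row, mapping.metabolites, "compartment")
            or mapping.default_compartment,
        )
        formula = _cell(row, mapping.metabolites, "formula")
        if formula:
            try:
                met.add_annotation(Annotation.formula(parse_formula(formula)))
            except FormulaError as exc:
                warnings.append(f"{mid}: bad formula ({exc})")
        charge = _cell(row, mapping.metabolites, "charge")
        if charge is not None:
            try:
                met.add_annotation(Annotation.charge(int(float(charge))))
            except ValueError:
                warnings.append(f"{mid}: non-integer charge {charge!r}")
        inchi = _cell(row, mapping.metabolites, "inchi")
        smiles = _cell(row, mapping.metabolites, "smiles")
        if inchi or smiles:
            met.add_annotation(
                Annotation.structure(ChemicalStructure(inchi=inchi, smiles=smiles))
            )
        _apply_xrefs(met, row, mapping.metabolites, registry, warnings)
        model.add_metabolite(met)
        by_name.setdefault(met.name, mid)
        by_name.setdefault(mid, mid)

    rxn_frame = read_table(reaction_table)
    _check_columns(rxn_frame, mapping.reactions, "reaction")
    seen_rxn: set[str] = set()
    for row in rxn_frame.to_dict(orient="records"):
        rid = _cell(row, mapping.reactions, "id")
        if not rid:
            raise ModelIntegrityError("reaction row with empty id")
        if rid in seen_rxn:
            raise ModelIntegrityError(f"duplicate reaction ids in sheet: [{rid!r}]")
        seen_rxn.add(rid)
        equation = _cell(row, mapping.reactions, "equation")
        if not equation:
            raise MappingError(f"reaction {rid!r}: empty equation cell")
        parsed: ParsedEquation = parse_equation(equation)
        warnings.extend(f"{rid}: {w}" for w in parsed.warnings)
        participants: list[ReactionParticipant] = []
        for p in parsed.participants:
            mid = by_name.get(p.name)
            if mid is None:
                mid = _auto_id(p.name)
                if mid not in model.metabolites:
                    model.add_metabolite(
                        Metabolite(
                            id=mid,
                            name=p.name,
                            compartment=p.compartment or mapping.default_compartment,
                        )
                    )
                    warnings.append(
                        f"{rid}: metabolite {p.name!r} auto-created from equation"
                    )
                by_name[p.name] = mid
            participants.append(ReactionParticipant(mid, p.coefficient, p.side))
        rxn = Reaction(
            id=rid,
            name=_cell(row, mapping.reactions, "name") or rid,
            participants=participants,
            reversible=parsed.reversible,
        )
        _apply_xrefs(rxn, row, mapping.reactions, registry, warnings)
        model.add_reaction(rxn)
    return model, warnings
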
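"""Structure-annotation procedures, from fully automatic to assisted.

The routes to a structure, ordered from automated to manual:

1. **notes transfer** — line notations (InChI/SMILES) and formula/charge
   lines already present in imported notes are promoted to annotations;
2. **cross-reference lookup** — metabolites holding database cross
   references are resolved against the local resource index;
3. **name search** — exact normalized-name hits attach silently when
   unique; fuzzy candidates above a score threshold are proposed for
   confirmation, never auto-attached;
4. **peptide assembly** — names recognized as di-/polypeptides get a
   structure built by amide condensation from the residue table;
5. **manual file attach** — a structure file (MOL/SDF or plain
   InChI/SMILES text) supplied for one named metabolite.

Every action, including every refusal, is an :class:`AnnotationDecision`;
the decision log is JSON-lines, so a human can review, flip ``accepted``
flags, and re-apply. Two invariants hold throughout: an existing structure
is never overwritten, and re-running any step produces no new attachments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

from .index import ResourceIndex, ResourceRecord, lookup_xref, search_exact, search_ranked
from .miriam import Registry, default_registry
from .model import (
    Annotation,
    AnnotationKind,
    ChemicalStructure,
    Metabolite,
    Model,
    StructureError,
)
from .notes import DEFAULT_DIALECT, NotesDialect, extract_notes_annotations
from .peptides import ResidueTable, assemble_peptide, default_residue_table, parse_peptide_name

__all__ = [
    "Method",
    "AnnotationDecision",
    "annotate_by_xref",
    "annotate_by_name",
    "transfer_structures",
    "annotate_peptides",
    "manual_attach",
    "annotate_model",
    "apply_decisions",
    "write_decision_log",
    "read_decision_log",
]


class Method(str, Enum):
    XREF_LOOKUP = "xref_lookup"
    NAME_EXACT = "name_exact"
    NAME_RANKED = "name_ranked"
    NOTES_TRANSFER = "notes_transfer"
    PEPTIDE_ASSEMBLY = "peptide_assembly"
    MANUAL_FILE = "manual_file"


@dataclass
class AnnotationDecision:
    metabolite_id: str
    method: Method
    accepted: bool
    rationale: str = ""
    score: Optional[float] = None
    record: Optional[ResourceRecord] = None
    structure: Optional[ChemicalStructure] = None

    def __post_init__(self):
        if self.method == Method.NAME_RANKED and self.score is None:
            raise ValueError("ranked-name decisions must carry a score")
        if not self.accepted and not self.rationale:
            raise ValueError("rejected decisions must carry a rationale")

    def to_json(self) -> str:
        doc: dict = {
            "metabolite_id": self.metabolite_id,
            "method": self.method.value,
            "accepted": self.accepted,
        }
        if self.rationale:
            doc["rationale"] = self.rationale
        if self.score is not None:
            doc["score"] = round(self.score, 6)
        if self.record is not None:
            doc["record"] = {
                "namespace": self.record.xref.namespace,
                "identifier": self.record.xref.identifier,
                "name": self.record.primary_name,
            }
        if self.structure is not None:
            s = self.structure
            doc["structure"] = {
                k: v
                for k, v in (
                    ("inchi", s.inchi),
                    ("smiles", s.smiles),
                    ("formula", s.formula.to_hill() if s.formula else None),
                    ("charge", s.formal_charge),
                )
                if v is not None
            }
        return json.dumps(doc, sort_keys=True)


def write_decision_log(decisions: Iterable[AnnotationDecision], path) -> None:
    Path(path).write_text(
        "".join(d.to_json() + "\n" for d in decisions), encoding="utf-8"
    )


def read_decision_log(path) -> list[dict]:
    """Raw decision documents (for the review/apply cycle)."""
    return [
        json.loads(line)
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line.strip()
    ]


def _counts_conflict(a: ChemicalStructure, b: ChemicalStructure) -> bool:
    ca, cb = a.element_counts(), b.element_counts()
    return ca is not None and cb is not None and ca != cb


def _attach(met: Metabolite, structure: ChemicalStructure) -> bool:
    """Attach a structure only if the slot is empty (never overwrite)."""
    if met.has_structure():
        return False
    return met.add_annotation(Annotation.structure(structure))


def annotate_by_xref(model: Model, index: ResourceIndex) -> list[AnnotationDecision]:
    """Attach structures via local index lookup of each metabolite's xrefs.

    Cross references are tried in annotation order; the first record with a
    structure wins — unless records reachable from different xrefs carry
    structures with disagreeing element counts, in which case nothing is
    attached and the conflict surfaces as a rejected decision.
    """
    decisions: list[AnnotationDecision] = []
    for mid in sorted(model.metabolites):
        met = model.metabolites[mid]
        if met.has_structure() or not met.crossrefs():
            continue
        hits: list[tuple[ResourceRecord, ChemicalStructure]] = []
        for xref in met.crossrefs():
            rec = lookup_xref(index, xref)
            if rec is not None and rec.structure is not None:
                hits.append((rec, rec.structure))
        if not hits:
            continue
        first_rec, first_struct = hits[0]
        if any(_counts_conflict(first_struct, s) for _, s in hits[1:]):
            decisions.append(
                AnnotationDecision(
                    mid,
                    Method.XREF_LOOKUP,
                    accepted=False,
                    rationale="conflict: cross references resolve to "
                    "structures with different element counts",
                )
            )
            continue
        _attach(met, first_struct)
        decisions.append(
            AnnotationDecision(
                mid, Method.XREF_LOOKUP, accepted=True, record=first_rec,
                structure=first_struct,
            )
        )
    return decisions


def annotate_by_name(
    model: Model,
    index: ResourceIndex,
    mode: str = "silent",
    threshold: float = 0.5,
) -> list[AnnotationDecision]:
    """Name-based annotation.

    ``silent`` mode attaches only when exactly one record matches the
    normalized name — ambiguous exact hits are refused with a decision
    listing the tie. ``suggest`` mode emits ranked candidates scoring at or
    above ``threshold`` as unaccepted decisions; nothing attaches without
    confirmation (see :func:`apply_decisions`).
    """
    if mode not in ("silent", "suggest"):
        raise ValueError(f"mode must be 'silent' or 'suggest', got {mode!r}")
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    decisions: list[AnnotationDecision] = []
    for mid in sorted(model.metabolites):
        met = model.metabolites[mid]
        if met.has_structure() or not met.name.strip():
            continue
        if mode == "silent":
            # only structure-bearing records can satisfy an attachment
            hits = [r for r in search_exact(index, met.name) if r.structure is not None]
            if len(hits) == 1:
                rec = hits[0]
                _attach(met, rec.structure)
                met.add_annotation(Annotation(AnnotationKind.CROSSREF, rec.xref))
                decisions.append(
                    AnnotationDecision(
                        mid, Method.NAME_EXACT, accepted=True, score=1.0,
                        record=rec, structure=rec.structure,
                    )
                )
            elif len(hits) > 1:
                names = ", ".join(str(r.xref) for r in hits)
                decisions.append(
                    AnnotationDecision(
                        mid, Method.NAME_EXACT, accepted=False, score=1.0,
                        rationale=f"ambiguous exact name match: {names}",
                    )
                )
        else:
            for rec, score in search_ranked(index, met.name, k=10):
                if score < threshold:
                    break
                decisions.append(
                    AnnotationDecision(
                        mid, Method.NAME_RANKED, accepted=False, score=score,
                        record=rec,
                        rationale="candidate awaiting confirmation",
                    )
                )
    return decisions


def transfer_structures(
    model: Model,
    dialect: NotesDialect = DEFAULT_DIALECT,
    registry: Registry | None = None,
) -> list[AnnotationDecision]:
    """Promote retained raw notes into structure/formula/charge annotations.

    Requires the model to have been imported with raw notes retained
    (``read_sbml(..., extract_notes=False)``). Uninterpretable line
    notations and formulas conflicting with an existing structure surface as
    rejected decisions.
    """
    registry = registry or default_registry()
    decisions: list[AnnotationDecision] = []
    for mid in sorted(model.metabolites):
        met = model.metabolites[mid]
        raw = getattr(met, "raw_notes", "")
        if not raw:
            continue
        anns, warns = extract_notes_annotations(raw, dialect, registry)
        for w in warns:
            decisions.append(
                AnnotationDecision(
                    mid, Method.NOTES_TRANSFER, accepted=False, rationale=w
                )
            )
        for ann in anns:
            if ann.kind == AnnotationKind.STRUCTURE:
                struct = ann.value
                if struct.element_counts() is None and struct.formula is None:
                    decisions.append(
                        AnnotationDecision(
                            mid, Method.NOTES_TRANSFER, accepted=False,
                            rationale=f"uninterpretable line notation "
                            f"{struct.smiles or struct.inchi!r}",
                        )
                    )
                    continue
                existing = met.structures()
                if existing and _counts_conflict(existing[0], struct):
                    decisions.append(
                        AnnotationDecision(
                            mid, Method.NOTES_TRANSFER, accepted=False,
                            rationale="conflict: notes structure disagrees "
                            "with existing structure",
                        )
                    )
                    continue
                if _attach(met, struct):
                    decisions.append(
                        AnnotationDecision(
                            mid, Method.NOTES_TRANSFER, accepted=True,
                            structure=struct,
                        )
                    )
            elif ann.kind == AnnotationKind.FORMULA:
                conflict = False
                for s in met.structures():
                    counts = s.element_counts()
                    if counts is not None and counts != ann.value:
                        conflict = True
                if conflict:
                    decisions.append(
                        AnnotationDecision(
                            mid, Method.NOTES_TRANSFER, accepted=False,
                            rationale="conflict: notes formula disagrees with "
                            "existing structure formula",
                        )
                    )
                elif met.add_annotation(ann):
                    decisions.append(
                        AnnotationDecision(mid, Method.NOTES_TRANSFER, accepted=True)
                    )
            elif ann.kind == AnnotationKind.CHARGE:
                if met.add_annotation(ann):
                    decisions.append(
                        AnnotationDecision(mid, Method.NOTES_TRANSFER, accepted=True)
                    )
            else:
                met.add_annotation(ann)
        met.raw_notes = ""  # consumed; reruns see nothing new
    return decisions


def annotate_peptides(
    model: Model, table: ResidueTable | None = None
) -> list[AnnotationDecision]:
    """Assemble structures for metabolites whose names parse as peptides."""
    table = table or default_residue_table()
    decisions: list[AnnotationDecision] = []
    for mid in sorted(model.metabolites):
        met = model.metabolites[mid]
        if met.has_structure():
            continue
        residues = parse_peptide_name(met.name, table)
        if not residues:
            continue
        struct = assemble_peptide(residues, table)
        _attach(met, struct)
        decisions.append(
            AnnotationDecision(
                mid, Method.PEPTIDE_ASSEMBLY, accepted=True, structure=struct,
                rationale="-".join(residues),
            )
        )
    return decisions


def manual_attach(model: Model, metabolite_id: str, structure_path) -> AnnotationDecision:
    """Attach a structure from a MOL/SDF file or plain InChI/SMILES text."""
    met = model.metabolites[metabolite_id]
    text = Path(structure_path).read_text(encoding="utf-8")
    struct = _structure_from_file_text(text)
    if struct is None:
        return AnnotationDecision(
            metabolite_id, Method.MANUAL_FILE, accepted=False,
            rationale=f"could not interpret structure file {structure_path}",
        )
    if met.has_structure():
        return AnnotationDecision(
            metabolite_id, Method.MANUAL_FILE, accepted=False,
            rationale="metabolite already has a structure (never overwritten)",
        )
    _attach(met, struct)
    return AnnotationDecision(
        metabolite_id, Method.MANUAL_FILE, accepted=True, structure=struct
    )


def _structure_from_file_text(text: str) -> Optional[ChemicalStructure]:
    stripped = text.strip()
    if stripped.startswith("InChI="):
        return ChemicalStructure(inchi=stripped.splitlines()[0].strip())
    if "V2000" in stripped or "V3000" in stripped:
        from rdkit import Chem

        mol = Chem.MolFromMolBlock(stripped.split("$$$$")[0])
        if mol is None:
            return None
        return ChemicalStructure(smiles=Chem.MolToSmiles(mol))
    # single-line SMILES
    if stripped and "\n" not in stripped:
        from rdkit import Chem

        if Chem.MolFromSmiles(stripped) is None:
            return None
        return ChemicalStructure(smiles=stripped)
    return None


def annotate_model(
    model: Model,
    index: ResourceIndex,
    mode: str = "silent",
    threshold: float = 0.5,
    dialect: NotesDialect = DEFAULT_DIALECT,
    registry: Registry | None = None,
    residue_table: ResidueTable | None = None,
    steps: tuple[str, ...] = ("transfer", "xref", "name", "peptide"),
) -> list[AnnotationDecision]:
    """Run the annotation pipeline in its automated-to-assisted order.

    The default order — notes transfer, then xref lookup, then name search,
    then peptide assembly — is config-overridable via ``steps``.
    """
    runners = {
        "transfer": lambda: transfer_structures(model, dialect, registry),
        "xref": lambda: annotate_by_xref(model, index),
        "name": lambda: annotate_by_name(model, index, mode, threshold),
        "peptide": lambda: annotate_peptides(model, residue_table),
    }
    decisions: list[AnnotationDecision] = []
    for step in steps:
        if step not in runners:
            raise ValueError(f"unknown pipeline step {step!r}")
        decisions.extend(runners[step]())
    return decisions


def apply_decisions(
    model: Model, index: ResourceIndex, decision_docs: list[dict]
) -> int:
    """Apply human-confirmed decisions from a reviewed log; returns #attached.

    Only documents with ``accepted: true`` act; structures embedded in the
    log attach directly, otherwise the referenced index record supplies one.
    """
    applied = 0
    from .formula import parse_formula
    from .miriam import CrossReference

    for doc in decision_docs:
        if not doc.get("accepted"):
            continue
        met = model.metabolites.get(doc["metabolite_id"])
        if met is None or met.has_structure():
            continue
        struct = None
        if "structure" in doc:
            s = doc["structure"]
            struct = ChemicalStructure(
                inchi=s.get("inchi"),
                smiles=s.get("smiles"),
                formula=parse_formula(s["formula"]) if s.get("formula") else None,
                formal_charge=s.get("charge"),
            )
        elif "record" in doc:
            rec = lookup_xref(
                index,
                CrossReference(doc["record"]["namespace"], doc["record"]["identifier"]),
            )
            if rec is not None:
                if rec.structure is not None:
                    struct = rec.structure
                met.add_annotation(Annotation(AnnotationKind.CROSSREF, rec.xref))
        if struct is not None and _attach(met, struct):
            applied += 1
    return applied
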
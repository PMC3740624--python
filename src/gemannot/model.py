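"""In-memory model: metabolites, reactions, and the multi-annotation system.

Every entity carries an ordered multiset of typed annotations — a metabolite
can hold several database cross references, a structure, a curator-entered
formula and a charge side by side. Identical annotations (same kind and
value) are stored once; distinct annotations of the same kind coexist, which
is what lets a species be cross-referenced to ChEBI and KEGG at the same
time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Iterable, Optional, Union

from .formula import ElementCount, parse_formula
from .miriam import CrossReference

__all__ = [
    "AnnotationKind",
    "Annotation",
    "ChemicalStructure",
    "Metabolite",
    "ReactionParticipant",
    "Reaction",
    "Model",
    "ModelIntegrityError",
    "StructureError",
]


class ModelIntegrityError(ValueError):
    """Referential-integrity violation (dangling ids, duplicates)."""


class StructureError(ValueError):
    """A ChemicalStructure without any content, or inconsistent content."""


def _structure_formula_from_notation(
    smiles: Optional[str], inchi: Optional[str]
) -> Optional[ElementCount]:
    """Derive element counts from SMILES (preferred) or InChI via RDKit.

    Returns None when the notation cannot be interpreted; interpretation
    failure is not an error here — callers decide whether to reject.
    """
    try:
        from rdkit import Chem
        from rdkit.Chem import rdMolDescriptors
        from rdkit import RDLogger

        RDLogger.DisableLog("rdApp.*")
    except ImportError:  # pragma: no cover - rdkit is a hard dependency
        return None
    mol = None
    if smiles:
        mol = Chem.MolFromSmiles(smiles)
    if mol is None and inchi:
        mol = Chem.MolFromInchi(inchi)
    if mol is None:
        return None
    formula = rdMolDescriptors.CalcMolFormula(mol)
    # CalcMolFormula appends an ionic suffix ("+2", "-") for charged species.
    import re

    m = re.match(r"^([A-Za-z0-9]+?)([+-][0-9]*)?$", formula)
    if not m:
        return None
    try:
        return parse_formula(m.group(1))
    except Exception:
        return None


@dataclass(frozen=True)
class ChemicalStructure:
    """A chemical structure as line notation(s) plus derived bookkeeping.

    At least one of ``inchi``, ``smiles``, ``formula`` must be present.
    When both a formula and an interpretable line notation are given their
    element counts must agree.
    """

    inchi: Optional[str] = None
    smiles: Optional[str] = None
    formula: Optional[ElementCount] = None
    formal_charge: Optional[int] = None

    def __post_init__(self):
        if self.inchi is None and self.smiles is None and self.formula is None:
            raise StructureError("structure needs at least one of inchi/smiles/formula")
        if self.formula is not None and (self.inchi or self.smiles):
            derived = _structure_formula_from_notation(self.smiles, self.inchi)
            if derived is not None and derived != self.formula:
                raise StructureError(
                    f"formula {self.formula.to_hill()} disagrees with line "
                    f"notation ({derived.to_hill()})"
                )

    def element_counts(self) -> Optional[ElementCount]:
        """Element counts: the explicit formula, else derived from notation."""
        if self.formula is not None:
            return self.formula
        return _structure_formula_from_notation(self.smiles, self.inchi)


class AnnotationKind(str, Enum):
    CROSSREF = "crossref"
    STRUCTURE = "structure"
    FORMULA = "formula"
    CHARGE = "charge"
    SYNONYM = "synonym"
    NOTE = "note"


_PAYLOAD_TYPES = {
    AnnotationKind.CROSSREF: CrossReference,
    AnnotationKind.STRUCTURE: ChemicalStructure,
    AnnotationKind.FORMULA: ElementCount,
    AnnotationKind.CHARGE: int,
    AnnotationKind.SYNONYM: str,
    AnnotationKind.NOTE: str,
}

AnnotationValue = Union[CrossReference, ChemicalStructure, ElementCount, int, str]


@dataclass(frozen=True)
class Annotation:
    """A typed annotation; the payload type is fixed by the kind."""

    kind: AnnotationKind
    value: AnnotationValue

    def __post_init__(self):
        kind = AnnotationKind(self.kind)
        object.__setattr__(self, "kind", kind)
        expected = _PAYLOAD_TYPES[kind]
        if not isinstance(self.value, expected) or (
            expected is int and isinstance(self.value, bool)
        ):
            raise TypeError(
                f"annotation kind {kind.value!r} requires payload "
                f"{expected.__name__}, got {type(self.value).__name__}"
            )

    # convenience constructors ------------------------------------------------
    @staticmethod
    def crossref(namespace: str, identifier: str) -> "Annotation":
        return Annotation(AnnotationKind.CROSSREF, CrossReference(namespace, identifier))

    @staticmethod
    def structure(struct: ChemicalStructure) -> "Annotation":
        return Annotation(AnnotationKind.STRUCTURE, struct)

    @staticmethod
    def formula(counts: ElementCount | str) -> "Annotation":
        if isinstance(counts, str):
            counts = parse_formula(counts)
        return Annotation(AnnotationKind.FORMULA, counts)

    @staticmethod
    def charge(z: int) -> "Annotation":
        return Annotation(AnnotationKind.CHARGE, int(z))

    @staticmethod
    def synonym(text: str) -> "Annotation":
        return Annotation(AnnotationKind.SYNONYM, text)

    @staticmethod
    def note(text: str) -> "Annotation":
        return Annotation(AnnotationKind.NOTE, text)


class _Annotated:
    """Mixin: ordered, duplicate-free multiset of annotations."""

    annotations: list[Annotation]

    def add_annotation(self, ann: Annotation) -> bool:
        """Store ``ann`` unless an identical kind+value is already present.

        Returns True iff storage occurred. Order of distinct annotations is
        insertion order, so repeated application is idempotent.
        """
        if not isinstance(ann, Annotation):
            raise TypeError("expected an Annotation")
        if ann in self.annotations:
            return False
        self.annotations.append(ann)
        return True

    def annotations_of(self, kind: AnnotationKind) -> list[Annotation]:
        return [a for a in self.annotations if a.kind == kind]

    def crossrefs(self) -> list[CrossReference]:
        return [a.value for a in self.annotations_of(AnnotationKind.CROSSREF)]

    def structures(self) -> list[ChemicalStructure]:
        return [a.value for a in self.annotations_of(AnnotationKind.STRUCTURE)]

    def first_charge(self) -> Optional[int]:
        anns = self.annotations_of(AnnotationKind.CHARGE)
        return anns[0].value if anns else None

    def first_formula(self) -> Optional[ElementCount]:
        anns = self.annotations_of(AnnotationKind.FORMULA)
        return anns[0].value if anns else None


@dataclass
class Metabolite(_Annotated):
    id: str
    name: str = ""
    compartment: str = ""
    annotations: list[Annotation] = field(default_factory=list)
    #: raw notes text retained at import time (consumed by notes transfer)
    raw_notes: str = ""

    def has_structure(self) -> bool:
        return bool(self.structures())


class Side(str, Enum):
    REACTANT = "reactant"
    PRODUCT = "product"


@dataclass
class ReactionParticipant:
    metabolite_id: str
    coefficient: Fraction
    side: Side

    def __post_init__(self):
        self.coefficient = Fraction(self.coefficient)
        self.side = Side(self.side)
        if self.coefficient <= 0:
            raise ValueError(
                f"participant {self.metabolite_id!r}: coefficient must be positive"
            )


@dataclass
class Reaction(_Annotated):
    id: str
    name: str = ""
    participants: list[ReactionParticipant] = field(default_factory=list)
    reversible: bool = False
    annotations: list[Annotation] = field(default_factory=list)
    raw_notes: str = ""

    def reactants(self) -> list[ReactionParticipant]:
        return [p for p in self.participants if p.side == Side.REACTANT]

    def products(self) -> list[ReactionParticipant]:
        return [p for p in self.participants if p.side == Side.PRODUCT]

    def is_exchange(self) -> bool:
        """True when all participants sit on one side (boundary reaction)."""
        return not self.reactants() or not self.products()


@dataclass
class Model:
    id: str = "model"
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    compartments: dict[str, str] = field(default_factory=dict)

    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise ModelIntegrityError(f"duplicate metabolite id {met.id!r}")
        if met.compartment and met.compartment not in self.compartments:
            self.compartments[met.compartment] = met.compartment
        self.metabolites[met.id] = met
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ModelIntegrityError(f"duplicate reaction id {rxn.id!r}")
        if not rxn.participants:
            raise ModelIntegrityError(f"reaction {rxn.id!r} has no participants")
        for p in rxn.participants:
            if p.metabolite_id not in self.metabolites:
                raise ModelIntegrityError(
                    f"reaction {rxn.id!r} references unknown metabolite "
                    f"{p.metabolite_id!r}"
                )
        self.reactions[rxn.id] = rxn
        return rxn

    def validate(self) -> None:
        """Re-check referential integrity of the whole model."""
        for rxn in self.reactions.values():
            if not rxn.participants:
                raise ModelIntegrityError(f"reaction {rxn.id!r} has no participants")
            for p in rxn.participants:
                if p.metabolite_id not in self.metabolites:
                    raise ModelIntegrityError(
                        f"reaction {rxn.id!r} references unknown metabolite "
                        f"{p.metabolite_id!r}"
                    )
        for met in self.metabolites.values():
            if met.compartment and met.compartment not in self.compartments:
                raise ModelIntegrityError(
                    f"metabolite {met.id!r} uses undeclared compartment "
                    f"{met.compartment!r}"
                )

    def metabolite_formula(self, met_id: str) -> Optional[ElementCount]:
        """Best available element counts for a metabolite.

        Precedence: explicit formula annotation, then counts derived from an
        attached structure. Curator-entered values outrank derived ones.
        """
        met = self.metabolites[met_id]
        f = met.first_formula()
        if f is not None:
            return f
        for s in met.structures():
            counts = s.element_counts()
            if counts is not None:
                return counts
        return None

    def metabolite_charge(self, met_id: str) -> Optional[int]:
        met = self.metabolites[met_id]
        z = met.first_charge()
        if z is not None:
            return z
        for s in met.structures():
            if s.formal_charge is not None:
                return s.formal_charge
        return None
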
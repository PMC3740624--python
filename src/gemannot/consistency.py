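"""Mass/charge balance checks and the model-wide annotation report.

Conservation of mass and charge across every reaction is a prerequisite for
constraint-based analysis, and protonation-state mistakes (an ATP entry at
the wrong charge, a dropped proton) are the classic way reconstructions
break it. The checks here are exact: stoichiometric coefficients are
rationals and element counts integers, so a reaction is balanced iff the
signed products-minus-reactants element map is empty and the charge delta
is zero.

Reactions whose participants lack a usable formula or charge are reported
``undetermined``, never guessed; formulas containing generic placeholders
(R, X) likewise, since conservation cannot be asserted over unknowns.
Boundary (one-sided) reactions are tagged ``exchange`` and exempt from
balance status — they are unbalanced by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Optional, Union

from .formula import ElementCount
from .index import normalize_name
from .model import AnnotationKind, Model, Reaction, Side

__all__ = [
    "BalanceStatus",
    "BalanceReport",
    "ModelReport",
    "element_balance",
    "charge_balance",
    "check_reaction",
    "model_report",
    "UNKNOWN",
]

#: sentinel for an undeterminable charge delta
UNKNOWN = "unknown"


class BalanceStatus(str, Enum):
    BALANCED = "balanced"
    IMBALANCED = "imbalanced"
    UNDETERMINED = "undetermined"
    EXCHANGE = "exchange"


@dataclass
class BalanceReport:
    reaction_id: str
    element_imbalance: dict[str, Fraction] = field(default_factory=dict)
    charge_imbalance: Union[Fraction, str] = UNKNOWN
    status: BalanceStatus = BalanceStatus.UNDETERMINED
    missing: list[str] = field(default_factory=list)

    def is_balanced(self) -> bool:
        return self.status == BalanceStatus.BALANCED


def _signed_sums(reaction: Reaction, model: Model):
    """Per-element and charge signed sums (products positive).

    Returns (element_map, charge_delta, missing_formula_ids,
    missing_charge_ids, has_generic).
    """
    elems: dict[str, Fraction] = {}
    charge = Fraction(0)
    miss_f: list[str] = []
    miss_z: list[str] = []
    generic = False
    for p in reaction.participants:
        sign = 1 if p.side == Side.PRODUCT else -1
        formula = model.metabolite_formula(p.metabolite_id)
        if formula is None:
            miss_f.append(p.metabolite_id)
        else:
            if formula.has_generic():
                generic = True
            for e, n in formula.items():
                elems[e] = elems.get(e, Fraction(0)) + sign * p.coefficient * n
        z = model.metabolite_charge(p.metabolite_id)
        if z is None:
            miss_z.append(p.metabolite_id)
        else:
            charge += sign * p.coefficient * z
    elems = {e: v for e, v in sorted(elems.items()) if v != 0}
    return elems, charge, miss_f, miss_z, generic


def element_balance(reaction: Reaction, model: Model) -> Optional[dict[str, Fraction]]:
    """Signed element map, products minus reactants; empty iff mass-balanced.

    Returns None when any participant lacks a formula (undetermined).
    """
    elems, _, miss_f, _, _ = _signed_sums(reaction, model)
    return None if miss_f else elems


def charge_balance(reaction: Reaction, model: Model) -> Union[Fraction, str]:
    """Signed charge delta, products minus reactants; UNKNOWN if any charge missing."""
    _, charge, _, miss_z, _ = _signed_sums(reaction, model)
    return UNKNOWN if miss_z else charge


def check_reaction(reaction: Reaction, model: Model) -> BalanceReport:
    elems, charge, miss_f, miss_z, generic = _signed_sums(reaction, model)
    missing = sorted(set(miss_f) | set(miss_z))
    report = BalanceReport(
        reaction_id=reaction.id,
        element_imbalance={} if miss_f else elems,
        charge_imbalance=UNKNOWN if miss_z else charge,
    )
    report.missing = missing
    if reaction.is_exchange():
        report.status = BalanceStatus.EXCHANGE
    elif missing or generic:
        report.status = BalanceStatus.UNDETERMINED
    elif not elems and charge == 0:
        report.status = BalanceStatus.BALANCED
    else:
        report.status = BalanceStatus.IMBALANCED
    return report


@dataclass
class ModelReport:
    balance: list[BalanceReport]
    missing_structure: list[str]
    missing_xref: list[str]
    duplicate_names: list[list[str]]

    def by_status(self, status: BalanceStatus) -> list[BalanceReport]:
        return [b for b in self.balance if b.status == status]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "reactions": len(self.balance),
            "balanced": len(self.by_status(BalanceStatus.BALANCED)),
            "imbalanced": len(self.by_status(BalanceStatus.IMBALANCED)),
            "undetermined": len(self.by_status(BalanceStatus.UNDETERMINED)),
            "exchange": len(self.by_status(BalanceStatus.EXCHANGE)),
            "missing_structure": len(self.missing_structure),
            "missing_xref": len(self.missing_xref),
            "duplicate_name_groups": len(self.duplicate_names),
        }

    def to_dict(self) -> dict:
        def fr(v):
            if isinstance(v, Fraction):
                return str(v) if v.denominator != 1 else v.numerator
            return v

        return {
            "counts": self.counts,
            "reactions": [
                {
                    "id": b.reaction_id,
                    "status": b.status.value,
                    "element_imbalance": {e: fr(v) for e, v in b.element_imbalance.items()},
                    "charge_imbalance": fr(b.charge_imbalance),
                    "missing": b.missing,
                }
                for b in self.balance
            ],
            "missing_structure": self.missing_structure,
            "missing_xref": self.missing_xref,
            "duplicate_names": self.duplicate_names,
        }

    def to_text(self) -> str:
        lines = ["reaction          status        imbalance"]
        for b in self.balance:
            imb = "".join(
                f" {e}{'+' if v > 0 else ''}{v}" for e, v in b.element_imbalance.items()
            )
            z = b.charge_imbalance
            ztxt = f" charge{'+' if isinstance(z, Fraction) and z > 0 else ''}{z}" if z != 0 else ""
            lines.append(f"{b.reaction_id:<17} {b.status.value:<13}{imb}{ztxt}")
        c = self.counts
        lines.append(
            f"-- {c['reactions']} reactions: {c['balanced']} balanced, "
            f"{c['imbalanced']} imbalanced, {c['undetermined']} undetermined, "
            f"{c['exchange']} exchange"
        )
        if self.missing_structure:
            lines.append(f"-- metabolites lacking structure: {', '.join(self.missing_structure)}")
        if self.missing_xref:
            lines.append(f"-- metabolites lacking any cross reference: {', '.join(self.missing_xref)}")
        for group in self.duplicate_names:
            lines.append(f"-- duplicate name group: {', '.join(group)}")
        return "\n".join(lines)


def model_report(model: Model) -> ModelReport:
    """Aggregate balance reports and missing-annotation lists, ordered by id."""
    balance = [
        check_reaction(model.reactions[rid], model) for rid in sorted(model.reactions)
    ]
    missing_structure = sorted(
        m.id for m in model.metabolites.values() if not m.has_structure()
    )
    missing_xref = sorted(m.id for m in model.metabolites.values() if not m.crossrefs())
    by_name: dict[str, list[str]] = {}
    for mid in sorted(model.metabolites):
        met = model.metabolites[mid]
        if met.name.strip():
            by_name.setdefault(normalize_name(met.name), []).append(mid)
    duplicate_names = [ids for _, ids in sorted(by_name.items()) if len(ids) > 1]
    return ModelReport(balance, missing_structure, missing_xref, duplicate_names)
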
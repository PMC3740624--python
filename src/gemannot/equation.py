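"""Parse and serialize human-readable reaction equations.

Grammar (one arrow per equation):

* arrows: ``->`` / ``=>`` irreversible left-to-right, ``<-`` / ``<=``
  irreversible right-to-left (normalized by swapping sides), ``<->`` /
  ``<=>`` reversible;
* participants separated by `` + `` (plus with surrounding spaces, so names
  like ``NAD+`` survive);
* optional coefficient: a bare positive number (integer, decimal, or
  ``p/q``) or parenthesized ``(2)``, followed by a space;
* optional compartment suffix ``[token]`` after the name;
* a one-sided (exchange) equation needs an explicit empty-side token
  (``∅`` or ``nothing``); a genuinely empty side is a syntax error.

Metabolite names may contain spaces and hyphens ("D-glucose 6-phosphate"),
which is why splitting happens on separator tokens only, never on bare
whitespace.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

from .model import Model, Reaction, Side

__all__ = [
    "EquationSyntaxError",
    "ParsedParticipant",
    "ParsedEquation",
    "parse_equation",
    "format_equation",
    "format_coefficient",
]

EMPTY_SIDE_TOKENS = {"∅", "Ø", "nothing"}

_ARROW_RE = re.compile(r"<=>|<->|<=|<-|=>|->")
_COEFF_PAREN_RE = re.compile(r"^\(\s*([0-9][0-9.,/]*)\s*\)\s*(.+)$", re.DOTALL)
_COEFF_BARE_RE = re.compile(r"^([0-9]+(?:\.[0-9]+)?(?:/[0-9]+)?)\s+(.+)$", re.DOTALL)
_COMPARTMENT_RE = re.compile(r"^(.*?)\s*\[(\w+)\]$")


class EquationSyntaxError(ValueError):
    """Malformed reaction equation text."""


@dataclass(frozen=True)
class ParsedParticipant:
    name: str
    coefficient: Fraction
    side: Side
    compartment: Optional[str] = None


@dataclass
class ParsedEquation:
    participants: list[ParsedParticipant]
    reversible: bool
    warnings: list[str] = field(default_factory=list)

    def side(self, side: Side) -> list[ParsedParticipant]:
        return [p for p in self.participants if p.side == side]


def _parse_coefficient(text: str) -> Fraction:
    if "/" in text:
        num, den = text.split("/", 1)
        value = Fraction(int(num), int(den))
    else:
        value = Fraction(text)
    if value <= 0:
        raise EquationSyntaxError(f"non-positive coefficient {text!r}")
    return value


def _parse_participant(token: str, side: Side) -> ParsedParticipant:
    token = token.strip()
    if not token:
        raise EquationSyntaxError("empty participant between separators")
    coeff = Fraction(1)
    m = _COEFF_PAREN_RE.match(token) or _COEFF_BARE_RE.match(token)
    if m:
        coeff = _parse_coefficient(m.group(1))
        token = m.group(2).strip()
    compartment = None
    m = _COMPARTMENT_RE.match(token)
    if m:
        token, compartment = m.group(1).strip(), m.group(2)
    if not token:
        raise EquationSyntaxError("participant has a coefficient/compartment but no name")
    return ParsedParticipant(token, coeff, side, compartment)


def _parse_side(text: str, side: Side, warnings: list[str]) -> list[ParsedParticipant]:
    text = text.strip()
    if not text:
        raise EquationSyntaxError(
            "empty equation side; use an explicit '∅' or 'nothing' token "
            "for exchange reactions"
        )
    if text in EMPTY_SIDE_TOKENS:
        return []
    merged: dict[tuple[str, Optional[str]], ParsedParticipant] = {}
    for raw in text.split(" + "):
        p = _parse_participant(raw, side)
        key = (p.name, p.compartment)
        if key in merged:
            prev = merged[key]
            merged[key] = ParsedParticipant(
                p.name, prev.coefficient + p.coefficient, side, p.compartment
            )
            warnings.append(
                f"duplicate participant {p.name!r} on {side.value} side; "
                f"coefficients summed"
            )
        else:
            merged[key] = p
    return list(merged.values())


def parse_equation(text: str) -> ParsedEquation:
    """Parse an equation string; direction is normalized to left-to-right.

    Raises :class:`EquationSyntaxError` on zero or multiple arrows, empty
    sides, or malformed participants.
    """
    if not text or not text.strip():
        raise EquationSyntaxError("empty equation")
    arrows = _ARROW_RE.findall(text)
    if len(arrows) != 1:
        raise EquationSyntaxError(
            f"equation must contain exactly one arrow, found {len(arrows)}: {text!r}"
        )
    arrow = arrows[0]
    left_text, right_text = _ARROW_RE.split(text, maxsplit=1)
    reversible = arrow in ("<->", "<=>")
    swap = arrow in ("<-", "<=")

    warnings: list[str] = []
    if swap:
        left_text, right_text = right_text, left_text
    reactants = _parse_side(left_text, Side.REACTANT, warnings)
    products = _parse_side(right_text, Side.PRODUCT, warnings)
    if not reactants and not products:
        raise EquationSyntaxError("equation has no participants on either side")
    return ParsedEquation(reactants + products, reversible, warnings)


def format_coefficient(value: Fraction) -> str:
    """Exact text for a rational coefficient.

    Integers print bare; rationals whose denominator divides a power of ten
    print as exact decimals (1/2 → "0.5"); anything else prints as "p/q".
    """
    value = Fraction(value)
    if value.denominator == 1:
        return str(value.numerator)
    den = value.denominator
    twos = fives = 0
    while den % 2 == 0:
        den //= 2
        twos += 1
    while den % 5 == 0:
        den //= 5
        fives += 1
    if den == 1:
        digits = max(twos, fives)
        scaled = value.numerator * 10**digits // value.denominator
        text = f"{scaled:0{digits + 1}d}"
        return f"{text[:-digits]}.{text[-digits:]}"
    return f"{value.numerator}/{value.denominator}"


def _format_participant(name: str, coeff: Fraction, compartment: Optional[str]) -> str:
    out = name if coeff == 1 else f"{format_coefficient(coeff)} {name}"
    return f"{out}[{compartment}]" if compartment else out


def format_equation(reaction, model: Optional[Model] = None) -> str:
    """Canonical equation text for a Reaction (in a model) or ParsedEquation.

    Coefficients of 1 are omitted, participants keep input order, the
    compartment suffix is printed whenever known, and direction renders as
    ``->`` (irreversible) or ``<=>`` (reversible). An empty side prints the
    explicit ``∅`` token so exchange equations stay parseable.
    """
    if isinstance(reaction, ParsedEquation):
        entries = [
            (p.name, p.coefficient, p.compartment, p.side) for p in reaction.participants
        ]
        reversible = reaction.reversible
    else:
        if model is None:
            raise ValueError("a Model is required to format a Reaction")
        entries = []
        for p in reaction.participants:
            if p.metabolite_id not in model.metabolites:
                raise KeyError(
                    f"reaction {reaction.id!r} references unknown metabolite "
                    f"{p.metabolite_id!r}"
                )
            met = model.metabolites[p.metabolite_id]
            entries.append(
                (met.name or met.id, p.coefficient, met.compartment or None, p.side)
            )
        reversible = reaction.reversible
    left = [
        _format_participant(n, c, cm) for n, c, cm, s in entries if s == Side.REACTANT
    ]
    right = [
        _format_participant(n, c, cm) for n, c, cm, s in entries if s == Side.PRODUCT
    ]
    arrow = "<=>" if reversible else "->"
    return f"{' + '.join(left) or '∅'} {arrow} {' + '.join(right) or '∅'}"
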
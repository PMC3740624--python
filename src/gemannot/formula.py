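"""Element-count algebra for molecular formulas.

Chemical formulas in draft metabolic models are plain strings
("C10H12N5O13P3"); balance checking and peptide assembly need them as exact
integer multisets over element symbols. ``ElementCount`` is an immutable,
hashable mapping from element symbol to positive count, with the integer
arithmetic used by condensation reactions and reaction-balance sums.

Element symbols are validated against the shape ``^[A-Z][a-z]?$`` only, not
against the periodic table: draft models legitimately contain generic
placeholders such as "R" or "X", which downstream consistency checks flag
rather than reject.
"""

from __future__ import annotations

import re
from collections.abc import Iterator, Mapping

__all__ = [
    "ElementCount",
    "FormulaError",
    "GENERIC_ELEMENTS",
    "parse_formula",
    "formula_combine",
]

_SYMBOL_RE = re.compile(r"^[A-Z][a-z]?$")
_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")

#: Placeholder "elements" used in polymeric / generic formulas. Parsed like
#: any element, but reactions containing them cannot be balance-asserted.
GENERIC_ELEMENTS = frozenset({"R", "X"})


class FormulaError(ValueError):
    """Raised for malformed formula strings or negative element arithmetic."""


class ElementCount(Mapping):
    """Immutable multiset of elements, e.g. ``{"C": 4, "H": 8, "N": 2, "O": 3}``.

    Zero-valued entries are never stored; two ElementCounts compare equal
    iff they contain the same elements with the same positive counts.
    """

    __slots__ = ("_counts", "_hash")

    def __init__(self, counts: Mapping[str, int] | None = None):
        clean: dict[str, int] = {}
        for sym, n in (counts or {}).items():
            if not _SYMBOL_RE.match(sym):
                raise FormulaError(f"invalid element symbol {sym!r}")
            n = int(n)
            if n < 0:
                raise FormulaError(f"negative count for element {sym!r}")
            if n:
                clean[sym] = n
        self._counts = dict(sorted(clean.items()))
        self._hash = hash(tuple(self._counts.items()))

    def __getitem__(self, sym: str) -> int:
        return self._counts[sym]

    def get(self, sym: str, default: int = 0) -> int:
        return self._counts.get(sym, default)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __hash__(self) -> int:
        return self._hash

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ElementCount):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == {k: v for k, v in other.items() if v}
        return NotImplemented

    def __repr__(self) -> str:
        return f"ElementCount({self._counts!r})"

    def __add__(self, other: "ElementCount") -> "ElementCount":
        return formula_combine(self, other, 1, +1)

    def __sub__(self, other: "ElementCount") -> "ElementCount":
        return formula_combine(self, other, 1, -1)

    def scaled(self, k: int) -> "ElementCount":
        """Return this multiset with every count multiplied by ``k >= 0``."""
        if k < 0:
            raise FormulaError("scale factor must be non-negative")
        return ElementCount({e: n * k for e, n in self._counts.items()})

    def has_generic(self) -> bool:
        """True if any placeholder symbol (R, X) is present."""
        return any(e in GENERIC_ELEMENTS for e in self._counts)

    def to_hill(self) -> str:
        """Serialize in Hill order: C first, H second, then alphabetical.

        If no carbon is present all elements are alphabetical (standard
        Hill convention).
        """
        items = dict(self._counts)
        parts: list[str] = []
        order: list[str]
        if "C" in items:
            order = ["C"] + (["H"] if "H" in items else [])
            order += sorted(e for e in items if e not in ("C", "H"))
        else:
            order = sorted(items)
        for e in order:
            n = items[e]
            parts.append(e if n == 1 else f"{e}{n}")
        return "".join(parts)


def parse_formula(text: str) -> ElementCount:
    """Parse a molecular formula string into an :class:`ElementCount`.

    Accepts concatenated ``Symbol[count]`` tokens, e.g. ``"C10H12N5O13P3"``,
    ``"FeS"``, ``"H2O"``. Repeated symbols accumulate. Raises
    :class:`FormulaError` naming the offending position on any character
    that cannot start a token.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or not m.group(1):
            raise FormulaError(
                f"malformed formula {text!r}: unexpected character "
                f"{text[pos]!r} at position {pos}"
            )
        sym, digits = m.group(1), m.group(2)
        n = int(digits) if digits else 1
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    return ElementCount(counts)


def formula_combine(
    a: ElementCount, b: ElementCount, b_scale: int = 1, sign: int = +1
) -> ElementCount:
    """Return ``a + sign * b_scale * b`` element-wise.

    ``sign`` must be +1 or -1; ``b_scale`` a non-negative integer.
    Subtraction that would drive any element negative raises
    :class:`FormulaError` naming the element. Zero entries are dropped.
    """
    if sign not in (+1, -1):
        raise FormulaError("sign must be +1 or -1")
    if b_scale < 0:
        raise FormulaError("b_scale must be non-negative")
    out = dict(a)
    for e, n in b.items():
        out[e] = out.get(e, 0) + sign * b_scale * n
        if out[e] < 0:
            raise FormulaError(f"element {e!r} would go negative")
    return ElementCount(out)
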
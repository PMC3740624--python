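"""Semi-automatic di-/polypeptide structure assembly from metabolite names.

Reconstructions that model peptidoglycan synthesis carry dipeptides such as
glycylglycine that chemical databases list only as individual residues. This
module recognizes peptide names in two common spellings —

* hyphenated three-letter codes: ``Gly-Gly``, ``Ala-Gly-Ser`` (stereo
  prefixes ``L-``/``D-`` tolerated and recorded), and
* IUPAC combining form: ``glycylglycine``, ``L-alanyl-L-glutamate`` (every
  non-final residue by its ``-yl`` name, the final one by its full name) —

and assembles the neutral peptide by amide condensation: the element counts
equal the sum of the free amino-acid formulas minus one water per peptide
bond, and a SMILES is produced by chaining residue backbone fragments
N-to-C. The bundled table covers the 20 canonical L-amino acids and is
user-extensible via a TSV file with the same columns.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

from .formula import ElementCount, formula_combine, parse_formula
from .model import ChemicalStructure

__all__ = [
    "Residue",
    "ResidueTable",
    "default_residue_table",
    "parse_peptide_name",
    "assemble_peptide",
    "WATER",
]

WATER = ElementCount({"H": 2, "O": 1})

_STEREO_TOKENS = {"l", "d", "dl"}


@dataclass(frozen=True)
class Residue:
    code: str               # three-letter code, lowercase ("gly")
    name: str               # full amino-acid name ("glycine")
    alt_names: tuple[str, ...]   # e.g. ("aspartate",) for aspartic acid
    combining: tuple[str, ...]   # "-yl" combining names ("glycyl")
    formula: ElementCount   # free (neutral) amino acid
    fragment: str           # backbone SMILES fragment "N...C(=O)"


class ResidueTable:
    def __init__(self, residues: list[Residue]):
        self.residues = list(residues)
        self.by_code = {r.code: r for r in residues}
        self.by_combining: dict[str, Residue] = {}
        self.by_full_name: dict[str, Residue] = {}
        for r in residues:
            for c in r.combining:
                self.by_combining[c] = r
            self.by_full_name[r.name.replace(" ", "")] = r
            for alt in r.alt_names:
                self.by_full_name[alt.replace(" ", "")] = r
        # longest-first order drives greedy segmentation
        self._combining_desc = sorted(self.by_combining, key=len, reverse=True)

    def __len__(self):
        return len(self.residues)

    def codes(self) -> list[str]:
        return [r.code for r in self.residues]

    @staticmethod
    def from_tsv(path) -> "ResidueTable":
        residues = []
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        header = lines[0].split("\t")
        for line in lines[1:]:
            if not line.strip():
                continue
            row = dict(zip(header, line.split("\t")))
            residues.append(
                Residue(
                    code=row["code"].strip().lower(),
                    name=row["name"].strip().lower(),
                    alt_names=tuple(
                        a.strip().lower() for a in row.get("alt_names", "").split("|") if a.strip()
                    ),
                    combining=tuple(
                        c.strip().lower() for c in row["combining"].split("|") if c.strip()
                    ),
                    formula=parse_formula(row["formula"]),
                    fragment=row["fragment"].strip(),
                )
            )
        return ResidueTable(residues)


_DEFAULT_TABLE: Optional[ResidueTable] = None


def default_residue_table() -> ResidueTable:
    """The bundled 20-residue table (cached)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        ref = resources.files("gemannot.data").joinpath("residues.tsv")
        with resources.as_file(ref) as path:
            _DEFAULT_TABLE = ResidueTable.from_tsv(path)
    return _DEFAULT_TABLE


def _strip_stereo(tokens: list[str]) -> list[str]:
    return [t for t in tokens if t not in _STEREO_TOKENS]


def parse_peptide_name(
    name: str, table: ResidueTable | None = None
) -> Optional[list[str]]:
    """Recognize a peptide name; returns residue codes N-to-C, or None.

    Misses (any unrecognized token, a lone residue, a sugar ``-yl`` name
    like glucosylglycine) return None rather than raising — absence is the
    signal that other annotation routes should be tried.
    """
    table = table or default_residue_table()
    if not name or not name.strip():
        return None
    lowered = name.strip().lower()

    # form (a): hyphen-separated three-letter codes, e.g. "Gly-Gly", "L-Ala-Gly"
    tokens = _strip_stereo([t.strip() for t in lowered.split("-") if t.strip()])
    if len(tokens) >= 2 and all(t in table.by_code for t in tokens):
        return tokens

    # form (b): combining form. Drop stereo prefixes, then hyphens/spaces.
    compact = "".join(_strip_stereo(re.split(r"[-\s]+", lowered)))
    codes: list[str] = []
    rest = compact
    while rest:
        if codes and rest in table.by_full_name:
            codes.append(table.by_full_name[rest].code)
            return codes if len(codes) >= 2 else None
        # greedy longest combining-name match at the left edge
        for cand in table._combining_desc:
            if rest.startswith(cand):
                codes.append(table.by_combining[cand].code)
                rest = rest[len(cand):]
                break
        else:
            return None
    return None


def assemble_peptide(
    residues: list[str], table: ResidueTable | None = None
) -> ChemicalStructure:
    """Chain residues through amide bonds into a neutral peptide structure.

    Element counts follow the condensation law: sum of free amino-acid
    formulas minus (n-1) waters. The SMILES is the concatenation of each
    residue's ``N...C(=O)`` backbone fragment, closed with the C-terminal
    hydroxyl.
    """
    table = table or default_residue_table()
    if len(residues) < 2:
        raise ValueError("a peptide needs at least two residues")
    missing = [r for r in residues if r not in table.by_code]
    if missing:
        raise KeyError(f"unknown residue code(s): {missing}")
    res = [table.by_code[r] for r in residues]
    counts = ElementCount()
    for r in res:
        counts = formula_combine(counts, r.formula, 1, +1)
    counts = formula_combine(counts, WATER, len(res) - 1, -1)
    smiles = "".join(r.fragment for r in res) + "O"
    return ChemicalStructure(smiles=smiles, formula=counts, formal_charge=0)
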
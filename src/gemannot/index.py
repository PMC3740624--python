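"""Local, offline searchable index over chemical resource tables.

Chemical databases ship name/synonym/structure tables; annotating a model
against them needs (a) exact lookup by normalized name, (b) ranked fuzzy
lookup for near-miss names, and (c) lookup by cross reference. The index is
built once from delimited tables (or SDF-like records), persists to a
single self-describing JSON file, and rebuilds byte-identically from the
same inputs.

Name similarity is the Jaccard index of character-trigram sets computed on
normalized names — deterministic, symmetric, and requiring no training
data. Names shorter than three characters only ever match exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .formula import ElementCount, parse_formula
from .miriam import CrossReference, Registry, XrefValidationError, default_registry
from .model import ChemicalStructure

__all__ = [
    "normalize_name",
    "trigrams",
    "trigram_jaccard",
    "ResourceRecord",
    "ResourceIndex",
    "TableConfig",
    "IndexConfigError",
    "build_index",
    "search_exact",
    "search_ranked",
    "lookup_xref",
    "read_sdf_records",
]

_GREEK = {
    "α": "alpha", "β": "beta", "γ": "gamma", "δ": "delta", "ε": "epsilon",
    "ζ": "zeta", "η": "eta", "θ": "theta", "ι": "iota", "κ": "kappa",
    "λ": "lambda", "μ": "mu", "ν": "nu", "ξ": "xi", "π": "pi", "ρ": "rho",
    "σ": "sigma", "τ": "tau", "φ": "phi", "χ": "chi", "ψ": "psi", "ω": "omega",
    "Α": "alpha", "Β": "beta", "Γ": "gamma", "Δ": "delta", "Ω": "omega",
}
_COLLAPSE = set("-,()[]{}'\"")


class IndexConfigError(ValueError):
    """Bad table configuration (unknown namespace, missing column)."""


def normalize_name(text: str) -> str:
    """Case-fold, spell out Greek letters, collapse punctuation to spaces.

    Idempotent: ``normalize_name(normalize_name(x)) == normalize_name(x)``.
    """
    if not text:
        raise ValueError("cannot normalize an empty name")
    out = []
    for ch in text:
        if ch in _GREEK:
            out.append(f" {_GREEK[ch]} ")
        elif ch in _COLLAPSE or ch.isspace():
            out.append(" ")
        else:
            out.append(ch.lower())
    return " ".join("".join(out).split())


def trigrams(text: str) -> frozenset[str]:
    """Set of contiguous character trigrams of a (normalized) string."""
    return frozenset(text[i : i + 3] for i in range(len(text) - 2))


def trigram_jaccard(a: str, b: str) -> float:
    """Jaccard similarity of trigram sets; exact equality scores 1.0.

    Strings shorter than three characters match only exactly (score 1.0)
    and score 0.0 against everything else.
    """
    if a == b:
        return 1.0
    ta, tb = trigrams(a), trigrams(b)
    if not ta or not tb:
        return 0.0
    return len(ta & tb) / len(ta | tb)


@dataclass(frozen=True)
class ResourceRecord:
    xref: CrossReference
    primary_name: str
    synonyms: tuple[str, ...] = ()
    formula: Optional[ElementCount] = None
    charge: Optional[int] = None
    structure: Optional[ChemicalStructure] = None

    def all_names(self) -> tuple[str, ...]:
        return (self.primary_name,) + self.synonyms

    def best_score(self, normalized_query: str) -> float:
        return max(
            trigram_jaccard(normalized_query, normalize_name(n)) for n in self.all_names()
        )


@dataclass
class ResourceIndex:
    records: list[ResourceRecord]
    namespace_order: list[str]
    name_map: dict[str, list[int]] = field(default_factory=dict)
    version: str = "gemannot-index-1"

    def __post_init__(self):
        if not self.name_map:
            for i, rec in enumerate(self.records):
                for name in rec.all_names():
                    self.name_map.setdefault(normalize_name(name), []).append(i)
        self._xref_map = {
            (r.xref.namespace, r.xref.identifier): i for i, r in enumerate(self.records)
        }

    def _ns_rank(self, ns: str) -> int:
        try:
            return self.namespace_order.index(ns)
        except ValueError:
            return len(self.namespace_order)

    # persistence -------------------------------------------------------------
    def to_json(self) -> str:
        def rec_doc(r: ResourceRecord) -> dict:
            doc: dict = {
                "namespace": r.xref.namespace,
                "identifier": r.xref.identifier,
                "primary_name": r.primary_name,
            }
            if r.synonyms:
                doc["synonyms"] = list(r.synonyms)
            if r.formula is not None:
                doc["formula"] = r.formula.to_hill()
            if r.charge is not None:
                doc["charge"] = r.charge
            if r.structure is not None:
                s = r.structure
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
            return doc

        payload = {
            "version": self.version,
            "namespace_order": self.namespace_order,
            "records": [rec_doc(r) for r in self.records],
        }
        return json.dumps(payload, sort_keys=True, indent=1, ensure_ascii=False)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n", encoding="utf-8")

    @staticmethod
    def load(path) -> "ResourceIndex":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        records = []
        for r in doc["records"]:
            structure = None
            if "structure" in r:
                s = r["structure"]
                structure = ChemicalStructure(
                    inchi=s.get("inchi"),
                    smiles=s.get("smiles"),
                    formula=parse_formula(s["formula"]) if s.get("formula") else None,
                    formal_charge=s.get("charge"),
                )
            records.append(
                ResourceRecord(
                    xref=CrossReference(r["namespace"], r["identifier"]),
                    primary_name=r["primary_name"],
                    synonyms=tuple(r.get("synonyms", ())),
                    formula=parse_formula(r["formula"]) if r.get("formula") else None,
                    charge=r.get("charge"),
                    structure=structure,
                )
            )
        return ResourceIndex(
            records, doc.get("namespace_order", []), version=doc.get("version", "?")
        )


@dataclass
class TableConfig:
    """Declares how to read one resource table.

    ``columns`` maps semantic fields (identifier, name, synonyms, formula,
    charge, inchi, smiles) to column labels in the file. Synonyms are
    ``|``-separated within their cell.
    """

    namespace: str
    path: str
    columns: dict[str, str]
    sep: Optional[str] = None

    @staticmethod
    def from_json(path) -> "TableConfig":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        base = Path(path).parent
        table_path = doc["path"]
        if not Path(table_path).is_absolute():
            table_path = str(base / table_path)
        return TableConfig(
            namespace=doc["namespace"],
            path=table_path,
            columns=doc["columns"],
            sep=doc.get("sep"),
        )


def _infer_sep(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def _record_from_row(
    cfg: TableConfig, row: dict, registry: Registry, warnings: list[str]
) -> Optional[ResourceRecord]:
    def cell(fieldname: str) -> Optional[str]:
        label = cfg.columns.get(fieldname)
        if label is None or label not in row:
            return None
        v = row[label]
        if v is None or (isinstance(v, float) and pd.isna(v)):
            return None
        v = str(v).strip()
        return v or None

    ident = cell("identifier")
    name = cell("name")
    if not ident or not name:
        warnings.append(f"{cfg.namespace}: row missing identifier or name, skipped")
        return None
    try:
        xref = CrossReference(cfg.namespace, ident).validated(registry)
    except XrefValidationError:
        warnings.append(
            f"{cfg.namespace}: identifier {ident!r} fails the registry pattern, skipped"
        )
        return None
    synonyms = tuple(
        s.strip() for s in (cell("synonyms") or "").split("|") if s.strip()
    )
    formula = None
    if cell("formula"):
        formula = parse_formula(cell("formula"))
    charge = None
    if cell("charge") is not None:
        charge = int(float(cell("charge")))
    inchi, smiles = cell("inchi"), cell("smiles")
    structure = None
    if inchi or smiles:
        structure = ChemicalStructure(
            inchi=inchi, smiles=smiles, formal_charge=charge
        )
    return ResourceRecord(xref, name, synonyms, formula, charge, structure)


def build_index(
    tables: Iterable[TableConfig],
    registry: Registry | None = None,
) -> tuple[ResourceIndex, list[str]]:
    """Build a ResourceIndex from resource tables; returns (index, warnings).

    Rows with identifiers that fail their namespace pattern are skipped with
    a warning. Records are ordered by (table order, row order), so the same
    inputs always produce an identical index.
    """
    registry = registry or default_registry()
    warnings: list[str] = []
    records: list[ResourceRecord] = []
    ns_order: list[str] = []
    for cfg in tables:
        if not registry.knows(cfg.namespace):
            raise IndexConfigError(f"unknown namespace {cfg.namespace!r} in table config")
        if "identifier" not in cfg.columns or "name" not in cfg.columns:
            raise IndexConfigError(
                f"{cfg.namespace}: table config must map 'identifier' and 'name' columns"
            )
        if cfg.namespace not in ns_order:
            ns_order.append(cfg.namespace)
        sep = cfg.sep or _infer_sep(cfg.path)
        frame = pd.read_csv(cfg.path, sep=sep, dtype=str, keep_default_na=False)
        missing = [c for c in cfg.columns.values() if c not in frame.columns]
        if missing:
            raise IndexConfigError(
                f"{cfg.namespace}: mapped column(s) {missing} absent from {cfg.path}"
            )
        for row in frame.to_dict(orient="records"):
            rec = _record_from_row(cfg, row, registry, warnings)
            if rec is not None:
                records.append(rec)
    return ResourceIndex(records, ns_order), warnings


def search_exact(index: ResourceIndex, name: str) -> list[ResourceRecord]:
    """All records whose normalized primary name or synonym equals the query."""
    ids = index.name_map.get(normalize_name(name), [])
    return [index.records[i] for i in ids]


def search_ranked(
    index: ResourceIndex, name: str, k: int = 10
) -> list[tuple[ResourceRecord, float]]:
    """Top-``k`` records by trigram-Jaccard score, descending.

    Exact normalized matches score 1.0 and rank first. Ties break by
    namespace order (table order at build time) then identifier. Zero-score
    records are excluded.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    q = normalize_name(name)
    scored = []
    for i, rec in enumerate(index.records):
        s = rec.best_score(q)
        if s > 0.0:
            scored.append((rec, s, index._ns_rank(rec.xref.namespace), i))
    scored.sort(key=lambda t: (-t[1], t[2], t[0].xref.identifier))
    return [(rec, s) for rec, s, _, _ in scored[:k]]


def lookup_xref(index: ResourceIndex, xref: CrossReference) -> Optional[ResourceRecord]:
    """Exact (namespace, identifier) lookup; no canonicalization is applied.

    Callers holding a bare identifier should canonicalize through the
    registry (:meth:`CrossReference.validated`) first.
    """
    i = index._xref_map.get((xref.namespace, xref.identifier))
    return index.records[i] if i is not None else None


def read_sdf_records(path, tag_map: dict[str, str]) -> list[dict[str, str]]:
    """Thin SDF adapter: map ``> <TAG>`` data fields to table-style rows.

    ``tag_map`` maps semantic fields (identifier, name, synonyms, formula,
    charge, inchi, smiles) to SDF tag names. The MOL block itself is not
    interpreted; structures travel through the inchi/smiles tags.
    """
    rows: list[dict[str, str]] = []
    text = Path(path).read_text(encoding="utf-8")
    for block in text.split("$$$$"):
        if not block.strip():
            continue
        fields: dict[str, str] = {}
        current: Optional[str] = None
        values: list[str] = []
        for line in block.splitlines():
            if line.startswith(">"):
                if current is not None:
                    fields[current] = "\n".join(values).strip()
                current = line.split("<", 1)[1].rsplit(">", 1)[0] if "<" in line else None
                values = []
            elif current is not None:
                values.append(line)
        if current is not None:
            fields[current] = "\n".join(values).strip()
        row = {
            semantic: fields[tag]
            for semantic, tag in tag_map.items()
            if tag in fields and fields[tag]
        }
        if row:
            rows.append(row)
    return rows
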
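"""Deterministic toy-scale input generator for fully offline testing.

Every input the toolkit consumes is emulated at toy scale from a hardcoded
vocabulary of real metabolites with literature-standard formulas, charges
and SMILES (verified against RDKit): an annotated SBML model, matching
metabolite/reaction spreadsheets with a column-mapping config, a minimal
KGML snippet, chemical resource tables with table configs, the registry
snapshot, and the residue table. The same seed always produces a
byte-identical bundle.

Deliberate defects are injected under flags — an imbalanced reaction
(dropped proton), structure-less metabolites (controlled by
``fraction_annotated``), an ambiguous name pair, a structure-less dipeptide
— and every defect is listed in ``manifest.json``, so consistency reports
can be checked against ground truth exactly.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, asdict
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Optional

from .formula import parse_formula
from .model import (
    Annotation,
    AnnotationKind,
    ChemicalStructure,
    Metabolite,
    Model,
    Reaction,
    ReactionParticipant,
    Side,
)
from .miriam import CrossReference, default_registry
from .sbml import write_sbml

__all__ = ["FixtureSpec", "VOCABULARY", "build_model", "generate"]


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 1
    n_metabolites: int = 14
    n_reactions: int = 5
    fraction_annotated: float = 0.75
    include_imbalanced: bool = False
    include_peptides: bool = False
    include_ambiguous: bool = False

    def __post_init__(self):
        if self.n_metabolites <= 0 or self.n_reactions <= 0:
            raise ValueError("counts must be positive")
        if not (0.0 <= self.fraction_annotated <= 1.0):
            raise ValueError("fraction_annotated must be in [0, 1]")


@dataclass(frozen=True)
class _Compound:
    id: str
    name: str
    formula: str
    charge: int
    chebi: str
    kegg: str
    smiles: Optional[str] = None
    synonyms: tuple[str, ...] = ()
    in_resource: bool = True  # peptides deliberately absent from databases


#: Real metabolites with literature-standard anion formulas and charges.
VOCABULARY: tuple[_Compound, ...] = (
    _Compound("h2o", "water", "H2O", 0, "CHEBI:15377", "C00001", "O", ("H2O", "aqua")),
    _Compound("h", "H+", "H", 1, "CHEBI:15378", "C00080", "[H+]", ("proton",)),
    _Compound(
        "atp", "ATP", "C10H12N5O13P3", -4, "CHEBI:30616", "C00002",
        "Nc1ncnc2n(cnc12)[C@@H]1O[C@H](COP([O-])(=O)OP([O-])(=O)OP([O-])([O-])=O)[C@@H](O)[C@H]1O",
        ("adenosine 5'-triphosphate",),
    ),
    _Compound(
        "adp", "ADP", "C10H12N5O10P2", -3, "CHEBI:456216", "C00008",
        "Nc1ncnc2n(cnc12)[C@@H]1O[C@H](COP([O-])(=O)OP([O-])([O-])=O)[C@@H](O)[C@H]1O",
        ("adenosine 5'-diphosphate",),
    ),
    _Compound(
        "pi", "phosphate", "HO4P", -2, "CHEBI:43474", "C00009",
        "OP([O-])([O-])=O", ("hydrogenphosphate", "Pi"),
    ),
    _Compound(
        "glc", "D-glucose", "C6H12O6", 0, "CHEBI:4167", "C00031",
        "OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O", ("glucose", "dextrose"),
    ),
    _Compound(
        "g6p", "D-glucose 6-phosphate", "C6H11O9P", -2, "CHEBI:61548", "C00092",
        "OC1O[C@H](COP([O-])([O-])=O)[C@@H](O)[C@H](O)[C@H]1O",
        ("glucose 6-phosphate",),
    ),
    _Compound(
        "fru", "D-fructose", "C6H12O6", 0, "CHEBI:28757", "C00095",
        "OCC1(O)OC(CO)C(O)C1O", ("fructose",),
    ),
    _Compound("gly", "glycine", "C2H5NO2", 0, "CHEBI:57305", "C00037", "NCC(=O)O"),
    _Compound(
        "ala", "L-alanine", "C3H7NO2", 0, "CHEBI:57972", "C00041",
        "C[C@H](N)C(=O)O", ("alanine",),
    ),
    _Compound(
        "glu", "L-glutamate", "C5H8NO4", -1, "CHEBI:29985", "C00025",
        "N[C@@H](CCC([O-])=O)C(=O)O", ("glutamate",),
    ),
    _Compound("co2", "CO2", "CO2", 0, "CHEBI:16526", "C00011", "O=C=O", ("carbon dioxide",)),
    _Compound("lac", "L-lactate", "C3H5O3", -1, "CHEBI:16651", "C00186", "CC(O)C([O-])=O"),
    _Compound("pyr", "pyruvate", "C3H3O3", -1, "CHEBI:15361", "C00022", "CC(=O)C([O-])=O"),
    _Compound("nad", "NAD+", "C21H26N7O14P2", -1, "CHEBI:57540", "C00003"),
    _Compound("nadh", "NADH", "C21H27N7O14P2", -2, "CHEBI:57945", "C00004"),
    _Compound(
        "glygly", "glycylglycine", "C4H8N2O3", 0, "CHEBI:17201", "C02037",
        in_resource=False,
    ),
)

_BY_ID = {c.id: c for c in VOCABULARY}

# (reaction id, name, [(met, coeff, side)], reversible)
_R = Side.REACTANT
_P = Side.PRODUCT
_REACTION_TEMPLATES = (
    ("ATPASE", "ATP hydrolysis",
     [("atp", 1, _R), ("h2o", 1, _R), ("adp", 1, _P), ("pi", 1, _P), ("h", 1, _P)], False),
    ("HEX1", "hexokinase",
     [("atp", 1, _R), ("glc", 1, _R), ("adp", 1, _P), ("g6p", 1, _P), ("h", 1, _P)], False),
    ("PGI", "glucose isomerase", [("glc", 1, _R), ("fru", 1, _P)], True),
    ("LDH", "lactate dehydrogenase",
     [("lac", 1, _R), ("nad", 1, _R), ("pyr", 1, _P), ("nadh", 1, _P), ("h", 1, _P)], False),
    ("EX_GLC", "glucose exchange", [("glc", 1, _R)], False),
)

_IMBALANCED_TEMPLATE = (
    "ATPASE_NOH", "ATP hydrolysis (proton dropped)",
    [("atp", 1, _R), ("h2o", 1, _R), ("adp", 1, _P), ("pi", 1, _P)], False,
)
_PEPTIDE_TEMPLATE = (
    "GLYGLY_SYNTH", "glycylglycine synthesis",
    [("gly", 2, _R), ("glygly", 1, _P), ("h2o", 1, _P)], False,
)

_PAD_ORDER = ("co2", "ala", "glu", "lac", "pyr", "fru", "nad", "nadh", "gly")


def _metabolite_from(compound: _Compound, with_structure: bool, compartment: str = "c") -> Metabolite:
    met = Metabolite(id=compound.id, name=compound.name, compartment=compartment)
    met.add_annotation(Annotation.formula(parse_formula(compound.formula)))
    met.add_annotation(Annotation.charge(compound.charge))
    met.add_annotation(Annotation.crossref("chebi", compound.chebi))
    met.add_annotation(Annotation.crossref("kegg.compound", compound.kegg))
    for syn in compound.synonyms:
        met.add_annotation(Annotation.synonym(syn))
    if with_structure and compound.smiles:
        met.add_annotation(
            Annotation.structure(
                ChemicalStructure(
                    smiles=compound.smiles,
                    formula=parse_formula(compound.formula),
                    formal_charge=compound.charge,
                )
            )
        )
    return met


def build_model(spec: FixtureSpec) -> tuple[Model, dict]:
    """Construct the fixture model in memory; returns (model, manifest)."""
    rng = random.Random(spec.seed)
    templates = list(_REACTION_TEMPLATES)
    rng.shuffle(templates)
    chosen = templates[: min(spec.n_reactions, len(templates))]
    chosen.sort(key=lambda t: t[0])
    if spec.include_imbalanced:
        chosen.append(_IMBALANCED_TEMPLATE)
    if spec.include_peptides:
        chosen.append(_PEPTIDE_TEMPLATE)

    needed = []
    for _, _, parts, _ in chosen:
        for mid, _, _ in parts:
            if mid not in needed:
                needed.append(mid)
    for mid in _PAD_ORDER:
        if len(needed) >= spec.n_metabolites:
            break
        if mid not in needed:
            needed.append(mid)
    needed.sort()

    # which metabolites carry a structure: seeded draw over those that can
    candidates = [m for m in needed if _BY_ID[m].smiles and m != "glygly"]
    n_struct = round(spec.fraction_annotated * len(candidates))
    structured = set(rng.sample(sorted(candidates), n_struct))

    model = Model(id=f"fixture_seed{spec.seed}")
    model.compartments["c"] = "cytosol"
    for mid in needed:
        model.add_metabolite(_metabolite_from(_BY_ID[mid], mid in structured))

    if spec.include_ambiguous:
        model.compartments["e"] = "extracellular"
        twin = _metabolite_from(_BY_ID["glc"], False, compartment="e")
        twin.id = "glc_e"
        twin.name = "D-Glucose"  # same normalized name as "D-glucose"
        model.add_metabolite(twin)

    exchange_ids, imbalanced_ids, balanced_ids = [], [], []
    for rid, rname, parts, reversible in chosen:
        rxn = Reaction(
            id=rid,
            name=rname,
            participants=[
                ReactionParticipant(mid, Fraction(coeff), side) for mid, coeff, side in parts
            ],
            reversible=reversible,
        )
        if rid.startswith("EX_"):
            exchange_ids.append(rid)
        elif rid == _IMBALANCED_TEMPLATE[0]:
            imbalanced_ids.append(rid)
        else:
            balanced_ids.append(rid)
        model.add_reaction(rxn)

    missing_structure = sorted(m.id for m in model.metabolites.values() if not m.has_structure())
    duplicate_groups = [["glc", "glc_e"]] if spec.include_ambiguous else []
    manifest = {
        "spec": asdict(spec),
        "counts": {
            "metabolites": len(model.metabolites),
            "reactions": len(model.reactions),
        },
        "defects": {
            "imbalanced": sorted(imbalanced_ids),
            "undetermined": [],
            "exchange": sorted(exchange_ids),
            "balanced": sorted(balanced_ids),
            "missing_structure": missing_structure,
            "missing_xref": [],
            "duplicate_name_groups": duplicate_groups,
            "peptide_targets": ["glygly"] if spec.include_peptides else [],
        },
    }
    return model, manifest


_KGML_SNIPPET = """<?xml version="1.0" encoding="UTF-8"?>
<pathway name="path:toy00010" org="toy" number="00010" title="toy glycolysis fragment">
  <entry id="1" name="cpd:C00031" type="compound"/>
  <entry id="2" name="cpd:C00095" type="compound"/>
  <reaction id="10" name="rn:R00771" type="reversible">
    <substrate id="1" name="cpd:C00031"/>
    <product id="2" name="cpd:C00095"/>
  </reaction>
</pathway>
"""


def _write_tables(model: Model, out: Path) -> dict[str, str]:
    met_rows = ["id,name,compartment,formula,charge,chebi,kegg,smiles"]
    for mid in sorted(model.metabolites):
        met = model.metabolites[mid]
        c = _BY_ID.get(mid.removesuffix("_e"), None)
        formula = met.first_formula()
        smiles = ""
        for s in met.structures():
            smiles = s.smiles or ""
        chebi = kegg = ""
        for xref in met.crossrefs():
            if xref.namespace == "chebi":
                chebi = xref.identifier
            elif xref.namespace == "kegg.compound":
                kegg = xref.identifier
        met_rows.append(
            ",".join(
                [
                    mid,
                    f'"{met.name}"',
                    met.compartment,
                    formula.to_hill() if formula else "",
                    str(met.first_charge() if met.first_charge() is not None else ""),
                    chebi,
                    kegg,
                    smiles,
                ]
            )
        )
    (out / "metabolites.csv").write_text("\n".join(met_rows) + "\n", encoding="utf-8")

    from .equation import format_equation

    rxn_rows = ["id,name,equation"]
    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        rxn_rows.append(f'{rid},"{rxn.name}","{format_equation(rxn, model)}"')
    (out / "reactions.csv").write_text("\n".join(rxn_rows) + "\n", encoding="utf-8")

    mapping = {
        "metabolites": {
            "id": "id", "name": "name", "compartment": "compartment",
            "formula": "formula", "charge": "charge", "smiles": "smiles",
            "xref:chebi": "chebi", "xref:kegg.compound": "kegg",
        },
        "reactions": {"id": "id", "name": "name", "equation": "equation"},
        "default_compartment": "c",
    }
    (out / "mapping.json").write_text(
        json.dumps(mapping, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return mapping


def _write_resource_tables(out: Path) -> list[Path]:
    """ChEBI-style and KEGG-style resource tables over the vocabulary.

    Peptides are deliberately absent — chemical databases typically list
    only the individual residues.
    """
    configs = []
    for ns, ident_attr, fname in (
        ("chebi", "chebi", "resource_chebi.tsv"),
        ("kegg.compound", "kegg", "resource_kegg.tsv"),
    ):
        rows = ["identifier\tname\tsynonyms\tformula\tcharge\tsmiles"]
        for c in VOCABULARY:
            if not c.in_resource:
                continue
            rows.append(
                "\t".join(
                    [
                        getattr(c, ident_attr),
                        c.name,
                        "|".join(c.synonyms),
                        c.formula,
                        str(c.charge),
                        c.smiles or "",
                    ]
                )
            )
        (out / fname).write_text("\n".join(rows) + "\n", encoding="utf-8")
        config = {
            "namespace": ns,
            "path": fname,
            "columns": {
                "identifier": "identifier", "name": "name", "synonyms": "synonyms",
                "formula": "formula", "charge": "charge", "smiles": "smiles",
            },
        }
        cfg_path = out / f"{fname.removesuffix('.tsv')}_config.json"
        cfg_path.write_text(json.dumps(config, indent=2, sort_keys=True) + "\n", encoding="utf-8")
        configs.append(cfg_path)
    return configs


def generate(spec: FixtureSpec, out_dir) -> dict:
    """Write the full fixture bundle into ``out_dir``; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model, manifest = build_model(spec)

    write_sbml(model, out / "model.xml")
    _write_tables(model, out)
    (out / "pathway.kgml").write_text(_KGML_SNIPPET, encoding="utf-8")
    _write_resource_tables(out)

    for pkg_file in ("registry.json", "residues.tsv"):
        ref = resources.files("gemannot.data").joinpath(pkg_file)
        (out / pkg_file).write_bytes(ref.read_bytes())

    manifest["files"] = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
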
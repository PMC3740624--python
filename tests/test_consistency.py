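"""Mass/charge balance checks and the model report."""

from fractions import Fraction

import pytest

from gemannot.consistency import (
    UNKNOWN,
    BalanceStatus,
    charge_balance,
    check_reaction,
    element_balance,
    model_report,
)
from gemannot.formula import parse_formula
from gemannot.model import (
    Annotation,
    ChemicalStructure,
    Metabolite,
    Model,
    Reaction,
    ReactionParticipant,
    Side,
)

ATP_CASE = {
    "atp": ("C10H12N5O13P3", -4),
    "h2o": ("H2O", 0),
    "adp": ("C10H12N5O10P2", -3),
    "pi": ("HO4P", -2),
    "h": ("H", 1),
}


def _model(species, reactions):
    """species: {id: (formula|None, charge|None)}; reactions: {id: ([(mid, coeff, side)], reversible)}"""
    model = Model()
    for mid, (formula, charge) in species.items():
        met = Metabolite(mid, name=mid, compartment="c")
        if formula is not None:
            met.add_annotation(Annotation.formula(parse_formula(formula)))
        if charge is not None:
            met.add_annotation(Annotation.charge(charge))
        model.add_metabolite(met)
    for rid, (parts, reversible) in reactions.items():
        model.add_reaction(
            Reaction(
                rid,
                participants=[
                    ReactionParticipant(m, Fraction(c), s) for m, c, s in parts
                ],
                reversible=reversible,
            )
        )
    return model


ATP_PARTS = [
    ("atp", 1, Side.REACTANT),
    ("h2o", 1, Side.REACTANT),
    ("adp", 1, Side.PRODUCT),
    ("pi", 1, Side.PRODUCT),
    ("h", 1, Side.PRODUCT),
]


def _oracle_sums(model, parts):
    """Independent per-element integer-sum oracle (plain dict arithmetic)."""
    elems: dict[str, int] = {}
    charge = 0
    for mid, coeff, side in parts:
        sign = 1 if side == Side.PRODUCT else -1
        formula, z = ATP_CASE[mid]
        for sym, n in parse_formula(formula).items():
            elems[sym] = elems.get(sym, 0) + sign * coeff * n
        charge += sign * coeff * z
    return {e: v for e, v in elems.items() if v}, charge


def test_atp_hydrolysis_balances():
    model = _model(ATP_CASE, {"R": (ATP_PARTS, False)})
    assert element_balance(model.reactions["R"], model) == {}
    assert charge_balance(model.reactions["R"], model) == 0
    oracle_e, oracle_z = _oracle_sums(model, ATP_PARTS)
    assert oracle_e == {} and oracle_z == 0
    assert check_reaction(model.reactions["R"], model).status == BalanceStatus.BALANCED


def test_dropped_proton_reports_minus_one_hydrogen_and_charge():
    parts = [p for p in ATP_PARTS if p[0] != "h"]
    model = _model(ATP_CASE, {"R": (parts, False)})
    assert element_balance(model.reactions["R"], model) == {"H": -1}
    assert charge_balance(model.reactions["R"], model) == -1
    oracle_e, oracle_z = _oracle_sums(model, parts)
    assert oracle_e == {"H": -1} and oracle_z == -1
    assert check_reaction(model.reactions["R"], model).status == BalanceStatus.IMBALANCED


def test_coefficient_arithmetic_two_a_to_a():
    model = _model(
        {"a": ("H2O", 0)},
        {"R": ([("a", 2, Side.REACTANT), ("a", 1, Side.PRODUCT)], False)},
    )
    assert element_balance(model.reactions["R"], model) == {"H": -2, "O": -1}


def test_missing_formula_makes_reaction_undetermined():
    species = dict(ATP_CASE)
    species["adp"] = (None, -3)
    model = _model(species, {"R": (ATP_PARTS, False)})
    assert element_balance(model.reactions["R"], model) is None
    report = check_reaction(model.reactions["R"], model)
    assert report.status == BalanceStatus.UNDETERMINED
    assert report.missing == ["adp"]


def test_missing_charge_gives_unknown():
    species = dict(ATP_CASE)
    species["h"] = ("H", None)
    model = _model(species, {"R": (ATP_PARTS, False)})
    assert charge_balance(model.reactions["R"], model) == UNKNOWN


def test_generic_elements_make_undetermined():
    model = _model(
        {"acp": ("C3H6R", 0), "acp2": ("C3H6R", 0)},
        {"R": ([("acp", 1, Side.REACTANT), ("acp2", 1, Side.PRODUCT)], False)},
    )
    assert check_reaction(model.reactions["R"], model).status == BalanceStatus.UNDETERMINED


def test_exchange_reactions_exempt():
    model = _model(
        {"glc": ("C6H12O6", 0)},
        {"EX": ([("glc", 1, Side.REACTANT)], False)},
    )
    assert check_reaction(model.reactions["EX"], model).status == BalanceStatus.EXCHANGE


def test_reversal_negates_balance():
    parts = [p for p in ATP_PARTS if p[0] != "h"]
    flipped = [
        (m, c, Side.PRODUCT if s == Side.REACTANT else Side.REACTANT)
        for m, c, s in parts
    ]
    m1 = _model(ATP_CASE, {"R": (parts, False)})
    m2 = _model(ATP_CASE, {"R": (flipped, False)})
    e1 = element_balance(m1.reactions["R"], m1)
    e2 = element_balance(m2.reactions["R"], m2)
    assert {k: -v for k, v in e1.items()} == e2
    assert charge_balance(m1.reactions["R"], m1) == -charge_balance(m2.reactions["R"], m2)


def test_scaling_scales_imbalance():
    parts = [p for p in ATP_PARTS if p[0] != "h"]
    scaled = [(m, Fraction(c) * Fraction(3, 2), s) for m, c, s in parts]
    m1 = _model(ATP_CASE, {"R": (parts, False)})
    m2 = _model(ATP_CASE, {"R": (scaled, False)})
    e1 = element_balance(m1.reactions["R"], m1)
    e2 = element_balance(m2.reactions["R"], m2)
    assert {k: v * Fraction(3, 2) for k, v in e1.items()} == e2


def test_peptide_condensation_reaction_balances():
    """Cross-module conservation: res1 + res2 -> dipeptide + H2O is exact."""
    from gemannot.peptides import assemble_peptide, default_residue_table

    table = default_residue_table()
    for pair in (("gly", "gly"), ("ala", "glu"), ("trp", "ser")):
        struct = assemble_peptide(list(pair), table)
        species = {
            "r1": (table.by_code[pair[0]].formula.to_hill(), 0),
            "r2": (table.by_code[pair[1]].formula.to_hill(), 0),
            "pep": (struct.formula.to_hill(), 0),
            "h2o": ("H2O", 0),
        }
        model = _model(
            species,
            {
                "SYNTH": (
                    [
                        ("r1", 1, Side.REACTANT),
                        ("r2", 1, Side.REACTANT),
                        ("pep", 1, Side.PRODUCT),
                        ("h2o", 1, Side.PRODUCT),
                    ],
                    False,
                )
            },
        )
        assert check_reaction(model.reactions["SYNTH"], model).status == BalanceStatus.BALANCED


def test_structure_derived_formula_feeds_balance():
    model = Model()
    w = Metabolite("w", name="water", compartment="c")
    w.add_annotation(Annotation.structure(ChemicalStructure(smiles="O", formal_charge=0)))
    model.add_metabolite(w)
    w2 = Metabolite("w2", name="water prime", compartment="c")
    w2.add_annotation(Annotation.formula(parse_formula("H2O")))
    w2.add_annotation(Annotation.charge(0))
    model.add_metabolite(w2)
    model.add_reaction(
        Reaction(
            "T",
            participants=[
                ReactionParticipant("w", Fraction(1), Side.REACTANT),
                ReactionParticipant("w2", Fraction(1), Side.PRODUCT),
            ],
        )
    )
    assert check_reaction(model.reactions["T"], model).status == BalanceStatus.BALANCED


def test_model_report_aggregates(bundle_dir, bundle_manifest):
    from gemannot.sbml import read_sbml

    model, _ = read_sbml(bundle_dir / "model.xml")
    report = model_report(model)
    defects = bundle_manifest["defects"]
    assert sorted(b.reaction_id for b in report.by_status(BalanceStatus.IMBALANCED)) == defects["imbalanced"]
    assert sorted(b.reaction_id for b in report.by_status(BalanceStatus.EXCHANGE)) == defects["exchange"]
    assert report.missing_structure == defects["missing_structure"]
    assert report.duplicate_names == defects["duplicate_name_groups"]
    assert report.counts["reactions"] == len(model.reactions)


def test_report_renders_text_and_json(bundle_dir):
    from gemannot.sbml import read_sbml

    model, _ = read_sbml(bundle_dir / "model.xml")
    report = model_report(model)
    text = report.to_text()
    assert "imbalanced" in text and "ATPASE_NOH" in text
    doc = report.to_dict()
    assert doc["counts"]["imbalanced"] == 1
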
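"""Reaction-equation grammar: parsing, formatting, fixpoint."""

from fractions import Fraction

import pytest

from gemannot.equation import (
    EquationSyntaxError,
    format_coefficient,
    format_equation,
    parse_equation,
)
from gemannot.model import Side

# Corpus of syntactically valid equations exercising reversed arrows,
# rational coefficients, multi-word names and compartment suffixes.
CORPUS = [
    "atp[c] + h2o[c] -> adp[c] + pi[c] + h[c]",
    "2 A + 3 B <=> C",
    "C <- 2 A",
    "A -> B",
    "A => B",
    "A <= B",
    "A <-> B",
    "A <=> B",
    "0.5 A + 0.5 B -> C",
    "0.25 O2 + X -> XO",
    "1/3 A -> B",
    "(2) A + B -> C",
    "D-glucose 6-phosphate[c] + h2o[c] -> D-glucose[c] + pi[c]",
    "alpha-D-glucose[e] <=> alpha-D-glucose[c]",
    "NAD+ + ethanol -> NADH + acetaldehyde + H+",
    "L-glutamate[c] + ATP[c] + NH3[c] -> L-glutamine[c] + ADP[c] + pi[c]",
    "2 H+[e] -> 2 H+[c]",
    "acetyl-CoA + oxaloacetate + h2o -> citrate + CoA + H+",
    "glycerol 3-phosphate[c] <=> dihydroxyacetone phosphate[c]",
    "7 A -> 7 B",
    "100 X -> 99 X + X",
    "A[mito] -> A[cyto]",
    "3.5 water -> 3.5 steam",
    "D-fructose 1,6-bisphosphate[c] -> glycerone phosphate[c] + D-glyceraldehyde 3-phosphate[c]",
    "UDP-N-acetyl-D-glucosamine[c] -> ∅",
    "∅ -> biomass",
    "nothing -> acetate[e]",
    "2,3-bisphospho-D-glycerate[c] + h2o[c] -> 3-phospho-D-glycerate[c] + pi[c]",
    "(0.5) O2 <- peroxide",
    "5-phospho-alpha-D-ribose 1-diphosphate[c] + L-glutamine[c] -> 5-phosphoribosylamine[c] + L-glutamate[c] + PPi[c]",
]


def _shape(parsed):
    return (
        sorted(
            (p.name, p.compartment, str(p.coefficient), p.side.value)
            for p in parsed.participants
        ),
        parsed.reversible,
    )


@pytest.mark.parametrize("text", CORPUS)
def test_parse_format_parse_is_a_fixpoint(text):
    once = parse_equation(text)
    again = parse_equation(format_equation(once))
    assert _shape(once) == _shape(again)
    # and formatting is stable from then on
    assert format_equation(once) == format_equation(again)


def test_atp_hydrolysis_shape():
    eq = parse_equation("atp[c] + h2o[c] -> adp[c] + pi[c] + h[c]")
    assert len(eq.side(Side.REACTANT)) == 2
    assert len(eq.side(Side.PRODUCT)) == 3
    assert all(p.coefficient == 1 for p in eq.participants)
    assert all(p.compartment == "c" for p in eq.participants)
    assert not eq.reversible


def test_coefficients_and_reversibility():
    eq = parse_equation("2 A + 3 B <=> C")
    coeffs = {p.name: p.coefficient for p in eq.side(Side.REACTANT)}
    assert coeffs == {"A": Fraction(2), "B": Fraction(3)}
    assert [p.name for p in eq.side(Side.PRODUCT)] == ["C"]
    assert eq.reversible


def test_right_to_left_arrow_swaps_sides():
    eq = parse_equation("C <- 2 A")
    assert {p.name: p.coefficient for p in eq.side(Side.REACTANT)} == {"A": Fraction(2)}
    assert [p.name for p in eq.side(Side.PRODUCT)] == ["C"]
    assert not eq.reversible


def test_side_swap_preserves_participant_multiset():
    fwd = parse_equation("2 A + B -> 3 C")
    rev = parse_equation("3 C <- 2 A + B")
    assert _shape(fwd) == _shape(rev)


def test_duplicate_names_merge_with_warning():
    eq = parse_equation("A + A -> B")
    (reactant,) = eq.side(Side.REACTANT)
    assert reactant.coefficient == 2
    assert eq.warnings


@pytest.mark.parametrize(
    "bad",
    [
        "A + B",            # no arrow
        "A -> B -> C",      # two arrows
        "A -> ",            # empty side without explicit token
        " -> B",
        "0 A -> B",         # non-positive coefficient
        "",
    ],
)
def test_syntax_errors(bad):
    with pytest.raises(EquationSyntaxError):
        parse_equation(bad)


def test_format_omits_unit_coefficients_and_prints_decimals():
    eq = parse_equation("1 A + 0.5 B -> C")
    assert format_equation(eq) == "A + 0.5 B -> C"


def test_format_coefficient_rationals():
    assert format_coefficient(Fraction(1, 2)) == "0.5"
    assert format_coefficient(Fraction(3, 4)) == "0.75"
    assert format_coefficient(Fraction(7)) == "7"
    assert format_coefficient(Fraction(1, 3)) == "1/3"  # non-decimal stays exact


def test_format_reaction_in_model(bundle_dir):
    from gemannot.sbml import read_sbml

    model, _ = read_sbml(bundle_dir / "model.xml")
    text = format_equation(model.reactions["PGI"], model)
    assert "<=>" in text
    assert "[c]" in text
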
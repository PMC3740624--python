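"""Mass/charge balance: ATP hydrolysis, with and without its proton.

Builds a five-species model with literature formulas and charges for the
physiological (anionic) protonation states, then checks conservation. The
signed imbalance map is products minus reactants, so a missing proton on
the product side shows up as H: -1 and charge -1.
"""

from fractions import Fraction

from gemannot import Annotation, Metabolite, Model, Reaction, ReactionParticipant, Side
from gemannot.consistency import check_reaction
from gemannot.formula import parse_formula

SPECIES = {
    "atp": ("C10H12N5O13P3", -4),
    "h2o": ("H2O", 0),
    "adp": ("C10H12N5O10P2", -3),
    "pi": ("HO4P", -2),
    "h": ("H", 1),
}

model = Model(id="atp_demo")
for mid, (formula, charge) in SPECIES.items():
    met = Metabolite(mid, name=mid, compartment="c")
    met.add_annotation(Annotation.formula(parse_formula(formula)))
    met.add_annotation(Annotation.charge(charge))
    model.add_metabolite(met)

full = [
    ReactionParticipant("atp", Fraction(1), Side.REACTANT),
    ReactionParticipant("h2o", Fraction(1), Side.REACTANT),
    ReactionParticipant("adp", Fraction(1), Side.PRODUCT),
    ReactionParticipant("pi", Fraction(1), Side.PRODUCT),
    ReactionParticipant("h", Fraction(1), Side.PRODUCT),
]
model.add_reaction(Reaction("ATPASE", participants=full))
model.add_reaction(Reaction("ATPASE_NOH", participants=full[:-1]))

for rid in ("ATPASE", "ATPASE_NOH"):
    report = check_reaction(model.reactions[rid], model)
    print(f"{rid}: status={report.status.value}")
    print(f"  element imbalance (products - reactants): {dict(report.element_imbalance)}")
    print(f"  charge imbalance: {report.charge_imbalance}")

print()
print("ATPASE conserves every element and the net charge; ATPASE_NOH is the")
print("classic curation slip: one hydrogen and one positive charge short.")
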
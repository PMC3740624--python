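"""Peptide assembly: from a metabolite name to a structure.

Dipeptides in peptidoglycan-synthesis reconstructions rarely have database
entries, but their names are systematic. The parser recognizes both the
three-letter-code and IUPAC combining-name spellings; assembly chains the
residues through amide bonds, so the formula is the residue sum minus one
water per peptide bond.
"""

from gemannot import assemble_peptide, parse_peptide_name

for name in ("Gly-Gly", "glycylglycine", "L-alanyl-L-glutamate",
             "Ala-Gly-Ser", "glucosylglycine"):
    residues = parse_peptide_name(name)
    if residues is None:
        print(f"{name!r}: not a recognizable peptide name")
        continue
    struct = assemble_peptide(residues)
    print(f"{name!r}: residues={residues}")
    print(f"   formula {struct.formula.to_hill()}  charge {struct.formal_charge}")
    print(f"   SMILES  {struct.smiles}")

print()
print("Gly-Gly and glycylglycine are the same dipeptide (C4H8N2O3 = 2 x glycine")
print("- H2O); glucosylglycine is refused because 'glucosyl' is a sugar, not a")
print("residue, and a false structure would be worse than none.")
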
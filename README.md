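# gemannot

Offline annotation of genome-scale metabolic models: database cross
references encoded against a MIRIAM registry snapshot, chemical structures
(InChI/SMILES) attached through a local resource index, name matching and
peptide assembly, exact mass/charge balance checking, and annotated SBML
export.

## Why

Genome-scale reconstructions are curated in spreadsheets and published in
SBML, but the annotations that actually identify each metabolite — database
cross references and, better, full chemical structures — are routinely lost
or never added. Without them a model cannot be integrated with other
resources, and without consistent protonation states its reactions cannot
conserve mass and charge, which constraint-based analysis requires. This
package is a headless toolkit for closing that gap: import a model from
SBML, delimited spreadsheets or KGML; attach cross references and
structures through automated and assisted routes; verify every reaction's
element and charge balance; export standards-compliant SBML.

## The core machinery

* **Cross references** are `(namespace, identifier)` pairs validated against
  a bundled registry snapshot of anchored identifier patterns, and encoded
  as `https://identifiers.org/<namespace>/<id>` URIs (CV terms with the
  biological qualifier *is* in SBML). The resource behind a bare identifier
  is *inferred* by pattern matching: `CHEBI:15422` is unambiguous,
  `C00002` matches the KEGG compound pattern `^C\d{5}$`, and a bare `15422`
  returns an ordered candidate list for the caller to resolve.
* **Balance checking** is exact arithmetic: stoichiometric coefficients are
  rationals, element counts integers. For reaction *r* with coefficients
  *s<sub>i</sub>* (negative for reactants) the element imbalance is
  Δ<sub>e</sub> = Σ<sub>i</sub> s<sub>i</sub>·n<sub>i,e</sub> and the charge
  imbalance Δ<sub>z</sub> = Σ<sub>i</sub> s<sub>i</sub>·z<sub>i</sub>;
  *r* is balanced iff every Δ<sub>e</sub> = 0 and Δ<sub>z</sub> = 0.
  Missing formulas or generic placeholders (R, X) make a reaction
  *undetermined*, never silently balanced; one-sided exchange reactions are
  exempt by construction.
* **Name search** runs over a local index built from resource tables:
  exact search on normalized names (case-folded, Greek letters spelled out,
  punctuation collapsed) and ranked fuzzy search scored by the Jaccard
  similarity of character-trigram sets. Exact hits score 1.0; ambiguous
  exact hits are never attached silently.
* **Peptide assembly** recognizes di-/polypeptide names (`Gly-Gly`,
  `glycylglycine`, `L-alanyl-L-glutamate`) and builds the neutral structure
  by amide condensation: elements(peptide) = Σ elements(residues) −
  (n−1)·H₂O, with a SMILES chained N-to-C from residue backbone fragments.

## Worked example

```python
from fractions import Fraction
from gemannot import Annotation, Metabolite, Model, Reaction, ReactionParticipant, Side
from gemannot.consistency import check_reaction
from gemannot.formula import parse_formula

SPECIES = {
    "atp": ("C10H12N5O13P3", -4), "h2o": ("H2O", 0),
    "adp": ("C10H12N5O10P2", -3), "pi": ("HO4P", -2), "h": ("H", 1),
}
model = Model()
for mid, (formula, charge) in SPECIES.items():
    met = Metabolite(mid, name=mid, compartment="c")
    met.add_annotation(Annotation.formula(parse_formula(formula)))
    met.add_annotation(Annotation.charge(charge))
    model.add_metabolite(met)

full = [ReactionParticipant("atp", Fraction(1), Side.REACTANT),
        ReactionParticipant("h2o", Fraction(1), Side.REACTANT),
        ReactionParticipant("adp", Fraction(1), Side.PRODUCT),
        ReactionParticipant("pi", Fraction(1), Side.PRODUCT),
        ReactionParticipant("h", Fraction(1), Side.PRODUCT)]
model.add_reaction(Reaction("ATPASE", participants=full))
model.add_reaction(Reaction("ATPASE_NOH", participants=full[:-1]))

for rid in ("ATPASE", "ATPASE_NOH"):
    r = check_reaction(model.reactions[rid], model)
    print(rid, r.status.value, dict(r.element_imbalance), r.charge_imbalance)
```

prints

```
ATPASE balanced {} 0
ATPASE_NOH imbalanced {'H': Fraction(-1, 1)} -1
```

ATP hydrolysis with the physiological anion formulas conserves every
element and the net charge; dropping the product proton — the classic
protonation-state slip — leaves the reaction one hydrogen (`H: -1`) and one
positive charge (`-1`) short on the product side. The `examples/` directory
has one narrative script per capability (balance checking, cross-reference
inference, name search, peptide assembly, the annotation pipeline, format
conversion); each prints the numbers it computes and says what they mean.

## Command line

```
gemannot fixtures generate --seed 1 --out bundle/         # toy inputs + manifest
gemannot convert bundle/reactions.csv out.xml --from tabular \
    --metabolites bundle/metabolites.csv --mapping bundle/mapping.json
gemannot index --config bundle/resource_chebi_config.json \
    --config bundle/resource_kegg_config.json --out index.json
gemannot annotate out.xml --index index.json --out annotated.xml --log decisions.jsonl
gemannot check annotated.xml                              # exit 1 iff imbalanced
```

Suggest-mode candidates (`--mode suggest`) are written to the decision log
with `accepted: false`; review the log, flip the flags you confirm, and
re-run with `--apply-decisions decisions.jsonl`. Nothing is attached without
confirmation, and an existing structure is never overwritten.

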
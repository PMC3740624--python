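# Methods

## Scope and model of the problem

A metabolic model is represented as metabolites, reactions and compartments
with a *dynamic annotation system*: every entity carries an ordered,
duplicate-free multiset of typed annotations (cross reference, structure,
formula, charge, synonym, note). Multiple annotations of the same type
coexist — a species referenced to both ChEBI and KEGG keeps both — and
identical annotations are stored once, which makes every annotation
operation idempotent by construction. The annotation kinds cover what the
package itself reads and writes; the enum is extensible.

## Cross references and the registry snapshot

A cross reference is `(namespace, identifier)`. Namespaces come from a
bundled, versioned JSON snapshot (`gemannot-registry-1`, 20 namespaces)
giving each an anchored identifier pattern, an identifiers.org URI base, an
optional literal prefix (`CHEBI:`, `GO:`) and aliases for legacy URN forms
(`obo.chebi`). The snapshot is deliberately offline — no live registry
queries — and its version is recorded in the notes of every SBML file the
package writes, so provenance survives export. Users may substitute their
own snapshot (`--registry`).

Two snapshot choices matter. MetaCyc's published pattern is nearly
unanchored and would match almost any string, so the snapshot narrows it to
`^CPD(-[A-Z0-9]+)+$`; BiGG reaction identifiers are constrained to start
with two capitals so that KEGG-style identifiers (`C00002`) do not
double-match. Resource inference tries both the raw identifier and the
prefix-inserted form (`15422` → `CHEBI:15422`), ranks namespaces whose
literal prefix appears in the input first, and otherwise preserves registry
order. Ambiguity is surfaced as a multi-candidate list, never resolved
silently; the CLI only auto-picks under an explicit flag.

## Formats

**SBML.** Reading accepts Level 2 and 3 via libsbml; CV-term resource URIs
decode through the registry (identifiers.org https/http forms and legacy
`urn:miriam:` with percent-encoded colons), and URIs the registry cannot
resolve are preserved verbatim as note annotations rather than dropped.
Writing always emits Level 3 Version 1 core (no FBC package): cross
references become CV terms with biological qualifier *is*; structures,
formulas, charges and synonyms go to structured notes under COBRA-style
keys (`FORMULA:`, `CHARGE:`, `INCHI:`, `SMILES:`, plus `STRUCTURE_FORMULA:`
/ `STRUCTURE_CHARGE:` for the bookkeeping fields of a structure object, so
the annotation multiset survives a write/read cycle). All structure-bearing
keys in one notes block merge into a single structure annotation — they
describe the same molecule; models carrying several alternative structures
per species are out of scope for notes round-tripping.

SBML stores stoichiometry as IEEE doubles while the model keeps exact
rationals. On read, doubles are recovered with
`Fraction(x).limit_denominator(10^6)`, which is exact for every decimal or
small-denominator coefficient a curator would type (0.5, 0.25, 1/3) and is
the reason half-stoichiometry reactions balance exactly after a round trip.

**Spreadsheets.** CSV, TSV and xlsx are read through one pandas-based
abstraction with an explicit user-declared column mapping — semantic fields
(`id`, `name`, `formula`, `charge`, `compartment`, `inchi`, `smiles`,
`xref:<namespace>`, `equation`) mapped to column labels, never positional
guessing. Reaction equations are parsed from text; metabolites appearing
only in equations are auto-created with a warning, matching how such sheets
are written in practice.

**KGML.** Minimal import: compound entries become metabolites (the
`cpd:`-stripped token doubles as a kegg.compound cross reference), reaction
elements become coefficient-1 reactions honoring `type="reversible"`.
Graphics and map elements are ignored.

## Equation grammar

One arrow per equation: `->`/`=>` (left-to-right), `<-`/`<=` (right-to-left,
normalized by swapping sides so storage is always left-to-right), `<->`/`<=>`
(reversible). Participants split on ` + ` — plus with surrounding spaces —
so names like `NAD+` and multi-word names like `D-glucose 6-phosphate`
survive; a leading numeric token followed by a space (or a parenthesized
number) is the coefficient; a trailing `[token]` is the compartment.
Duplicate names on one side merge by summing coefficients, with a warning.
One-sided exchange equations need an explicit `∅`/`nothing` token; a silently
empty side is a syntax error. Serialization is canonical (unit coefficients
omitted, `<=>` for reversible, compartment always printed when known) and
`parse∘format∘parse = parse` holds on the corpus of dialects tested.
Coefficients print as exact decimals when the denominator divides a power of
ten (`1/2` → `0.5`) and as `p/q` otherwise, so formatting never loses
exactness.

## Local index and name matching

The index is built from delimited resource tables (identifier, name,
`|`-separated synonyms, formula, charge, InChI/SMILES) plus a JSON config
naming the namespace; SDF-like records map in through a thin tag adapter.
Rows with pattern-invalid identifiers are skipped with warnings. The index
persists to a single self-describing JSON file with a version header;
rebuilding from the same tables reproduces it byte for byte.

Name normalization case-folds, spells out Greek letters (α → alpha),
collapses whitespace/hyphens/commas/parentheses to single spaces, and is
idempotent. Ranked search scores a query against each record as the maximum
over primary name and synonyms of the Jaccard similarity of character
trigram sets of the normalized names. The metric was chosen for being
deterministic, symmetric, training-free and adequate for synonym drift;
names shorter than three characters fall back to exact matching. Exact
matches score 1.0 and rank first; ties break by namespace order (table
order at build time), then identifier. The suggest-mode threshold defaults
to 0.5 — conservative enough that unrelated metabolite names (typical
trigram overlap well under 0.3) do not surface, while single-edit variants
do; it is configurable.

## Annotation pipeline

Order, from automated to assisted: notes transfer → cross-reference lookup
→ name search → peptide assembly, overridable by configuration. Guarantees
enforced across all routes:

* an existing structure is never overwritten — attachment requires an empty
  structure slot;
* conflicts (two cross references resolving to structures with different
  element counts; a notes formula disagreeing with an attached structure)
  attach nothing and surface as rejected decisions with a rationale;
* ambiguous exact name hits are never attached silently; suggest-mode
  candidates attach only after human confirmation through the decision log;
* every route is idempotent: a second run produces zero new decisions.

Each action and refusal is an `AnnotationDecision` (metabolite, method,
score where ranked, accepted flag, rationale), logged as JSON-lines for
machine-auditable provenance and for the review/apply cycle that replaces
GUI interactivity in this headless setting. In the CLI, notes-encoded
annotations in the input SBML are treated as pre-existing state (extracted
at read time, not logged as new decisions); the notes-transfer step logs
decisions when a model is imported with raw notes retained
(`read_sbml(..., extract_notes=False)`), which is the library path for
auditing a foreign model's notes.

## Peptide assembly

The residue table ships with the 20 canonical L-amino acids: three-letter
code, full name (plus carboxylate alternatives such as *glutamate*),
IUPAC combining name(s) (*glycyl*, *tryptophyl*/*tryptophanyl*), free
amino-acid formula, and a backbone SMILES fragment `N…C(=O)`. It is
user-extensible via a TSV with the same columns.

Name recognition accepts the hyphenated code form (`Gly-Gly`, stereo
prefixes `L-`/`D-` tolerated) and the combining form
(`glycylglycine`), segmented greedily longest-match left-to-right over
combining names with the final token required to be a full amino-acid name;
any unconsumed remainder means *no peptide* — deliberately strict, so sugar
`-yl` names (glucosylglycine) are refused rather than mis-assembled.
Assembly chains fragments N-to-C and closes with the C-terminal hydroxyl;
element counts follow the condensation law Σ residues − (n−1)·H₂O, and the
structure is emitted in the neutral protonation state (formal charge 0) —
models needing zwitterions adjust via charge annotations. RDKit serves as
an independent oracle in the tests: the chained SMILES must reproduce the
combinatorial formula for every dipeptide.

## Consistency checking

Formula precedence per metabolite: explicit formula annotation, then
structure-derived counts — curator-entered values outrank derived ones, and
disagreement between them is itself reported. Element and charge imbalances
are exact (rational coefficients, integer counts), products minus
reactants. Status rules: *balanced* iff the element map is empty and the
charge delta zero; *undetermined* when any participant lacks a usable
formula/charge or a formula contains generic placeholders (R, X) —
conservation cannot be asserted over unknowns; *exchange* for one-sided
reactions, exempt by construction. The model-wide report adds metabolites
lacking structures, metabolites lacking any cross reference, and groups of
metabolites whose names normalize identically, all deterministically
ordered by entity id. The CLI `check` command exits nonzero only on
*imbalanced* reactions (not undetermined), so it can gate CI pipelines
without punishing incomplete annotation. Automatic rebalancing is out of
scope by design: the report suggests, the curator decides.

## The fixture generator

All test inputs are generated, never downloaded. The vocabulary is 17 real
metabolites with literature-standard formulas, charges (physiological
anion forms: ATP⁴⁻, ADP³⁻, HPO₄²⁻, …) and SMILES verified against RDKit,
wired into five reaction templates (ATP hydrolysis, hexokinase,
glucose–fructose isomerase, lactate dehydrogenase, a glucose exchange).
A `FixtureSpec(seed, n_metabolites, n_reactions, fraction_annotated,
include_imbalanced, include_peptides, include_ambiguous)` draws a reaction
subset and a structure-bearing metabolite subset from a seeded RNG and
writes the complete bundle: annotated SBML, metabolite/reaction sheets with
a mapping config, a KGML snippet, ChEBI-style and KEGG-style resource
tables with configs, the registry snapshot and the residue table, plus a
`manifest.json` listing every injected defect (the proton-dropped ATPase,
the structure-less metabolites, the duplicate-name pair, the structure-less
dipeptide). The same seed yields a byte-identical bundle. Resource tables
deliberately omit the dipeptide — databases list residues, not peptides —
so the peptide-assembly route is actually exercised.

What the generator does *not* emulate: genome-scale size, annotation noise
(typos, wrong-compartment references), inconsistent protonation conventions
across resources, and SBML idioms from other toolchains beyond the notes
dialect it writes. Passing tests therefore demonstrate the machinery's
correctness on well-formed inputs and its refusal behaviors on the injected
defects, not robustness to arbitrary field data.

## Problem sizes and numeric conventions

The test suite and the acceptance script run at the scale the guarantees
are stated for: 20 fixture seeds for round-trip and manifest checks, the
full 51-identifier registry sample, all 400 dipeptides and 8 000
tripeptides, a 30-equation corpus, 100 sampled name pairs — a few seconds
in total, by design of the toy vocabulary. Scores are compared exactly
(trigram Jaccard is a ratio of small integers); balance arithmetic is
exact; no floating-point tolerances are needed anywhere except the
`limit_denominator` recovery of SBML doubles described above.

## Known limitations

* One structure per metabolite is the supported regime for notes
  round-tripping and conflict detection.
* InChI/SMILES interpretation relies on RDKit; notations RDKit cannot parse
  are carried as text and flagged, not validated.
* The registry snapshot is a curated subset (20 namespaces); identifiers
  from namespaces outside it survive as preserved notes, not as CV terms.
* Peptide assembly records but does not encode stereochemistry (structures
  are emitted without stereo descriptors beyond those in residue
  fragments); acyl-carrier-protein conjugates and other non-peptide
  assemblies are out of scope.
* KGML import carries no stoichiometry (KGML has none); all coefficients
  are 1.
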
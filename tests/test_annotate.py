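"""Structure-annotation procedures and their guarantees."""

import pytest

from gemannot.annotate import (
    AnnotationDecision,
    Method,
    annotate_by_name,
    annotate_by_xref,
    annotate_model,
    annotate_peptides,
    apply_decisions,
    manual_attach,
    read_decision_log,
    transfer_structures,
    write_decision_log,
)
from gemannot.formula import parse_formula
from gemannot.index import ResourceIndex, ResourceRecord
from gemannot.miriam import CrossReference
from gemannot.model import Annotation, ChemicalStructure, Metabolite, Model
from gemannot.sbml import read_sbml


def _tiny_index(records):
    return ResourceIndex(list(records), ["chebi", "kegg.compound"])


def _met(mid, name, *anns):
    met = Metabolite(mid, name=name, compartment="c")
    for a in anns:
        met.add_annotation(a)
    return met


WATER_REC = ResourceRecord(
    CrossReference("chebi", "CHEBI:15377"), "water",
    structure=ChemicalStructure(smiles="O"),
)


def test_xref_lookup_attaches_structure():
    model = Model()
    model.add_metabolite(_met("w", "agua", Annotation.crossref("chebi", "CHEBI:15377")))
    decisions = annotate_by_xref(model, _tiny_index([WATER_REC]))
    (d,) = decisions
    assert d.accepted and d.method == Method.XREF_LOOKUP
    assert model.metabolites["w"].has_structure()


def test_xref_conflict_rejected_with_rationale():
    recs = [
        WATER_REC,
        ResourceRecord(
            CrossReference("kegg.compound", "C00011"), "not water",
            structure=ChemicalStructure(smiles="O=C=O"),
        ),
    ]
    model = Model()
    model.add_metabolite(
        _met(
            "m", "mystery",
            Annotation.crossref("chebi", "CHEBI:15377"),
            Annotation.crossref("kegg.compound", "C00011"),
        )
    )
    (d,) = annotate_by_xref(model, _tiny_index(recs))
    assert not d.accepted and "conflict" in d.rationale
    assert not model.metabolites["m"].has_structure()


def test_already_structured_metabolite_skipped():
    model = Model()
    model.add_metabolite(
        _met(
            "w", "water",
            Annotation.structure(ChemicalStructure(smiles="O")),
            Annotation.crossref("chebi", "CHEBI:15377"),
        )
    )
    assert annotate_by_xref(model, _tiny_index([WATER_REC])) == []


def test_silent_name_match_attaches_unique_exact_hit():
    model = Model()
    model.add_metabolite(_met("w", "Water"))
    (d,) = annotate_by_name(model, _tiny_index([WATER_REC]), mode="silent")
    assert d.accepted and d.method == Method.NAME_EXACT and d.score == 1.0
    met = model.metabolites["w"]
    assert met.has_structure()
    assert met.crossrefs()  # provenance xref recorded


def test_ambiguous_exact_hits_never_silently_attached():
    recs = [
        ResourceRecord(
            CrossReference("chebi", "CHEBI:1"), "glucose",
            structure=ChemicalStructure(smiles="OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O"),
        ),
        ResourceRecord(
            CrossReference("chebi", "CHEBI:2"), "glucose",
            structure=ChemicalStructure(smiles="OCC1(O)OC(CO)C(O)C1O"),
        ),
    ]
    model = Model()
    model.add_metabolite(_met("g", "glucose"))
    (d,) = annotate_by_name(model, _tiny_index(recs), mode="silent")
    assert not d.accepted
    assert "CHEBI:1" in d.rationale and "CHEBI:2" in d.rationale
    assert not model.metabolites["g"].has_structure()


def test_suggest_mode_proposes_without_attaching():
    model = Model()
    model.add_metabolite(_met("g", "glucos"))  # near miss
    recs = [
        ResourceRecord(
            CrossReference("chebi", "CHEBI:1"), "glucose",
            structure=ChemicalStructure(smiles="O"),
        )
    ]
    decisions = annotate_by_name(model, _tiny_index(recs), mode="suggest", threshold=0.3)
    assert decisions
    assert all(d.method == Method.NAME_RANKED and not d.accepted for d in decisions)
    assert all(d.score is not None for d in decisions)
    assert not model.metabolites["g"].has_structure()


def test_threshold_validation():
    with pytest.raises(ValueError):
        annotate_by_name(Model(), _tiny_index([]), mode="silent", threshold=0.0)
    with pytest.raises(ValueError):
        annotate_by_name(Model(), _tiny_index([]), mode="nope")


def test_transfer_from_retained_notes():
    model = Model()
    met = _met("w", "water")
    met.raw_notes = "INCHI: InChI=1S/H2O/h1H2"
    model.add_metabolite(met)
    (d,) = transfer_structures(model)
    assert d.accepted and d.method == Method.NOTES_TRANSFER
    assert model.metabolites["w"].structures()[0].inchi == "InChI=1S/H2O/h1H2"
    # notes consumed: a second run is silent
    assert transfer_structures(model) == []


def test_transfer_formula_line():
    model = Model()
    met = _met("g", "glycylglycine")
    met.raw_notes = "FORMULA: C4H8N2O3"
    model.add_metabolite(met)
    (d,) = transfer_structures(model)
    assert d.accepted
    assert met.first_formula() == parse_formula("C4H8N2O3")


def test_transfer_conflicting_formula_rejected():
    model = Model()
    met = _met("w", "water", Annotation.structure(ChemicalStructure(smiles="O")))
    met.raw_notes = "FORMULA: C6H12O6"
    model.add_metabolite(met)
    (d,) = transfer_structures(model)
    assert not d.accepted and "conflict" in d.rationale
    assert met.first_formula() is None


def test_transfer_rejects_uninterpretable_notation():
    model = Model()
    met = _met("x", "mystery")
    met.raw_notes = "SMILES: not)a(smiles"
    model.add_metabolite(met)
    (d,) = transfer_structures(model)
    assert not d.accepted


def test_peptide_assembly_step():
    model = Model()
    model.add_metabolite(_met("gg", "glycylglycine"))
    (d,) = annotate_peptides(model)
    assert d.accepted and d.method == Method.PEPTIDE_ASSEMBLY
    struct = model.metabolites["gg"].structures()[0]
    assert struct.formula == parse_formula("C4H8N2O3")


def test_manual_attach_from_inchi_file(tmp_path):
    model = Model()
    model.add_metabolite(_met("w", "water"))
    f = tmp_path / "structure.inchi"
    f.write_text("InChI=1S/H2O/h1H2\n")
    d = manual_attach(model, "w", f)
    assert d.accepted and d.method == Method.MANUAL_FILE
    # second attach refused: structures are never overwritten
    d2 = manual_attach(model, "w", f)
    assert not d2.accepted


def test_pipeline_idempotent_on_fixture(bundle_dir, resource_index):
    model, _ = read_sbml(bundle_dir / "model.xml", extract_notes=False)
    before = {
        mid: list(met.structures()) for mid, met in model.metabolites.items()
    }
    first = annotate_model(model, resource_index)
    assert any(d.accepted for d in first)
    # no structure that existed before was replaced
    for mid, structs in before.items():
        if structs:
            assert model.metabolites[mid].structures()[0] == structs[0]
    second = annotate_model(model, resource_index)
    assert second == []


def test_decision_log_round_trip(tmp_path):
    decisions = [
        AnnotationDecision("m1", Method.NAME_RANKED, accepted=False, score=0.7,
                           rationale="candidate awaiting confirmation"),
        AnnotationDecision("m2", Method.XREF_LOOKUP, accepted=True,
                           structure=ChemicalStructure(smiles="O")),
    ]
    log = tmp_path / "decisions.jsonl"
    write_decision_log(decisions, log)
    docs = read_decision_log(log)
    assert len(docs) == 2
    assert docs[0]["score"] == 0.7 and docs[0]["accepted"] is False
    assert docs[1]["structure"]["smiles"] == "O"


def test_apply_decisions_attaches_confirmed_only(tmp_path):
    model = Model()
    model.add_metabolite(_met("w", "water"))
    model.add_metabolite(_met("g", "glucose"))
    docs = [
        {"metabolite_id": "w", "accepted": True, "method": "name_ranked",
         "structure": {"smiles": "O"}},
        {"metabolite_id": "g", "accepted": False, "method": "name_ranked",
         "structure": {"smiles": "O=C=O"}},
    ]
    applied = apply_decisions(model, _tiny_index([]), docs)
    assert applied == 1
    assert model.metabolites["w"].has_structure()
    assert not model.metabolites["g"].has_structure()


def test_rejected_decision_requires_rationale():
    with pytest.raises(ValueError):
        AnnotationDecision("m", Method.NAME_EXACT, accepted=False)
    with pytest.raises(ValueError):
        AnnotationDecision("m", Method.NAME_RANKED, accepted=True)  # no score
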
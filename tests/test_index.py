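"""Name normalization, index build, exact/ranked search, xref lookup."""

import pytest
from hypothesis import given, settings, strategies as st

from gemannot.index import (
    IndexConfigError,
    ResourceIndex,
    TableConfig,
    build_index,
    lookup_xref,
    normalize_name,
    search_exact,
    search_ranked,
    trigram_jaccard,
    trigrams,
)
from gemannot.miriam import CrossReference


def test_normalize_examples():
    assert normalize_name("D-Glucose 6-phosphate") == "d glucose 6 phosphate"
    assert normalize_name("α-D-glucose") == "alpha d glucose"
    assert normalize_name("N,N-dimethylglycine") == "n n dimethylglycine"


_NAMES = st.text(
    alphabet=st.sampled_from(list("abcXYZ0189 -,()αβ")), min_size=1, max_size=30
).filter(lambda s: s.strip(" -,()"))


@settings(derandomize=True, max_examples=200)
@given(_NAMES)
def test_normalize_is_idempotent(name):
    once = normalize_name(name)
    assert normalize_name(once) == once


def _brute_force_jaccard(a, b):
    """Oracle: enumerate trigram sets explicitly."""
    ta = {a[i : i + 3] for i in range(len(a) - 2)}
    tb = {b[i : i + 3] for i in range(len(b) - 2)}
    if not ta or not tb:
        return 1.0 if a == b else 0.0
    inter = len([t for t in ta if t in tb])
    union = len(ta | tb)
    return 1.0 if a == b else inter / union


def test_glucose_fructose_score_matches_enumeration():
    score = trigram_jaccard("glucose", "fructose")
    assert score == _brute_force_jaccard("glucose", "fructose")
    assert 0 < score < 1


@settings(derandomize=True, max_examples=200)
@given(_NAMES, _NAMES)
def test_trigram_score_is_symmetric_and_matches_oracle(a, b):
    a, b = normalize_name(a), normalize_name(b)
    assert trigram_jaccard(a, b) == trigram_jaccard(b, a)
    assert trigram_jaccard(a, b) == pytest.approx(_brute_force_jaccard(a, b))


def test_short_names_match_exactly_only():
    assert trigram_jaccard("h", "h") == 1.0
    assert trigram_jaccard("h", "hg") == 0.0


def test_build_index_from_bundle(resource_index):
    assert len(resource_index.records) > 0
    namespaces = {r.xref.namespace for r in resource_index.records}
    assert namespaces == {"chebi", "kegg.compound"}


def test_invalid_identifier_rows_skipped_with_warning(tmp_path, registry):
    table = tmp_path / "t.tsv"
    table.write_text(
        "identifier\tname\nCHEBI:1\twater\nXYZ\tbroken\nCHEBI:2\tproton\n"
    )
    cfg = TableConfig("chebi", str(table), {"identifier": "identifier", "name": "name"})
    idx, warnings = build_index([cfg], registry)
    assert len(idx.records) == 2
    assert len(warnings) == 1 and "XYZ" in warnings[0]


def test_unknown_namespace_is_config_error(tmp_path, registry):
    table = tmp_path / "t.tsv"
    table.write_text("identifier\tname\nX\tx\n")
    cfg = TableConfig("nonexistent.db", str(table), {"identifier": "identifier", "name": "name"})
    with pytest.raises(IndexConfigError):
        build_index([cfg], registry)


def test_search_exact_case_fold_and_greek(resource_index):
    assert search_exact(resource_index, "WATER")
    assert search_exact(resource_index, "d-gLuCoSe")
    assert search_exact(resource_index, "no such metabolite") == []


def test_synonym_reachable(resource_index):
    hits = search_exact(resource_index, "dextrose")
    assert hits and all("glucose" in r.primary_name.lower() for r in hits)


def test_ranked_exact_match_scores_one_and_ranks_first(resource_index):
    results = search_ranked(resource_index, "D-glucose", k=5)
    assert results[0][1] == 1.0
    assert normalize_name(results[0][0].primary_name) == normalize_name("D-glucose")


def test_ranked_k_limits_results(resource_index):
    assert len(search_ranked(resource_index, "glucose", k=1)) == 1


def test_exact_subset_of_ranked_with_score_one(resource_index):
    for query in ("water", "ATP", "D-fructose"):
        exact = {id(r) for r in search_exact(resource_index, query)}
        ranked_ones = {
            id(r) for r, s in search_ranked(resource_index, query, k=10**6) if s == 1.0
        }
        assert exact <= ranked_ones


def test_ranked_scores_match_brute_force(resource_index):
    query = normalize_name("glucose")
    for rec, score in search_ranked(resource_index, "glucose", k=10**6):
        oracle = max(
            _brute_force_jaccard(query, normalize_name(n)) for n in rec.all_names()
        )
        assert score == pytest.approx(oracle)


def test_lookup_xref_exact_and_strict(resource_index):
    rec = lookup_xref(resource_index, CrossReference("kegg.compound", "C00002"))
    assert rec is not None and rec.primary_name == "ATP"
    assert lookup_xref(resource_index, CrossReference("kegg.compound", "C99999")) is None
    # stored with prefix, queried without: absent (canonicalization is caller's job)
    stored = next(r for r in resource_index.records if r.xref.namespace == "chebi")
    bare = stored.xref.identifier.removeprefix("CHEBI:")
    assert lookup_xref(resource_index, CrossReference("chebi", bare)) is None


def test_index_build_and_serialization_deterministic(bundle_dir, registry, tmp_path):
    cfgs = [
        TableConfig.from_json(bundle_dir / "resource_chebi_config.json"),
        TableConfig.from_json(bundle_dir / "resource_kegg_config.json"),
    ]
    idx1, _ = build_index(cfgs, registry)
    idx2, _ = build_index(cfgs, registry)
    assert idx1.to_json() == idx2.to_json()
    path = tmp_path / "idx.json"
    idx1.save(path)
    reloaded = ResourceIndex.load(path)
    assert reloaded.to_json() == idx1.to_json()


def test_sdf_adapter(tmp_path):
    from gemannot.index import read_sdf_records

    sdf = tmp_path / "records.sdf"
    sdf.write_text(
        "\n  synthetic toy record\n\n  0  0  0  0  0  0  0  0  0  0999 V2000\nM  END\n"
        "> <ChEBI ID>\nCHEBI:15377\n\n> <Name>\nwater\n\n> <SMILES>\nO\n\n$$$$\n"
    )
    rows = read_sdf_records(
        sdf, {"identifier": "ChEBI ID", "name": "Name", "smiles": "SMILES"}
    )
    assert rows == [{"identifier": "CHEBI:15377", "name": "water", "smiles": "O"}]
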
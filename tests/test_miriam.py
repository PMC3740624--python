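"""Resource inference and identifiers.org URI round-trips."""

import pytest

from gemannot.miriam import (
    CrossReference,
    RegistryError,
    UriParseError,
    XrefValidationError,
    default_registry,
    from_uri,
    infer_resource,
    to_uri,
)

# Valid identifiers spanning every namespace in the bundled snapshot.
SAMPLE_IDENTIFIERS = {
    "chebi": ["CHEBI:15422", "CHEBI:15377", "CHEBI:30616", "CHEBI:16761"],
    "kegg.compound": ["C00001", "C00002", "C00031", "C00008"],
    "kegg.reaction": ["R00086", "R00771", "R01786"],
    "kegg.glycan": ["G00001", "G10610"],
    "kegg.pathway": ["map00010", "map00020"],
    "hmdb": ["HMDB0000122", "HMDB0000538"],
    "pubchem.compound": ["5957", "962", "2244"],
    "metacyc.compound": ["CPD-15056", "CPD-8990"],
    "bigg.metabolite": ["atp_c", "h2o_c"],
    "bigg.reaction": ["PFK", "ATPS4r", "HEX1"],
    "seed.compound": ["cpd00001", "cpd00002"],
    "metanetx.chemical": ["MNXM3", "MNXM41"],
    "lipidmaps": ["LMFA01010001", "LMGL02010001"],
    "cas": ["56-65-5", "50-99-7", "7732-18-5"],
    "inchikey": ["XLYOFNOQVPJJNP-UHFFFAOYSA-N", "ZKHQWZAMYRWXGA-KQYNXXCUSA-J"],
    "rhea": ["13065", "11312"],
    "ec-code": ["2.7.1.1", "3.6.1.3", "1.1.1.27"],
    "uniprot": ["P69905", "Q9H0H5", "O43175", "B2RQC6"],
    "go": ["GO:0008152", "GO:0006096"],
    "reactome": ["R-HSA-70171", "R-HSA-1430728"],
}


def all_sample_xrefs():
    return [
        CrossReference(ns, ident)
        for ns, idents in SAMPLE_IDENTIFIERS.items()
        for ident in idents
    ]


def test_sample_set_spans_registry(registry):
    assert set(SAMPLE_IDENTIFIERS) == {e.namespace for e in registry}
    assert len(all_sample_xrefs()) >= 50


def test_infer_prefixed_identifier_unique():
    assert infer_resource("CHEBI:15422") == ["chebi"]


def test_infer_by_pattern():
    assert infer_resource("C00002")[0] == "kegg.compound"


def test_infer_bare_digits_is_ambiguous():
    candidates = infer_resource("15422")
    assert len(candidates) > 1
    assert "pubchem.compound" in candidates
    assert "chebi" in candidates  # digits-only tail matches via prefix insertion


def test_infer_no_match_returns_empty():
    assert infer_resource("!!nonsense!!") == []


def test_infer_only_returns_matching_namespaces(registry):
    """Re-validate every candidate against its own pattern."""
    for xref in all_sample_xrefs():
        for ns in infer_resource(xref.identifier, registry):
            entry = registry.get(ns)
            assert entry.matches(xref.identifier) or (
                entry.id_prefix and entry.matches(entry.id_prefix + xref.identifier)
            )


def test_infer_prefixed_identifiers_rank_their_namespace_first(registry):
    for ns, idents in SAMPLE_IDENTIFIERS.items():
        entry = registry.get(ns)
        if not entry.id_prefix:
            continue
        for ident in idents:
            candidates = infer_resource(ident, registry)
            assert candidates[0] == ns
            assert candidates.count(ns) == 1


def test_to_uri():
    assert (
        to_uri(CrossReference("chebi", "CHEBI:15422"))
        == "https://identifiers.org/chebi/CHEBI:15422"
    )
    assert (
        to_uri(CrossReference("kegg.compound", "C00002"))
        == "https://identifiers.org/kegg.compound/C00002"
    )


def test_to_uri_canonicalizes_bare_prefix_identifier():
    assert (
        to_uri(CrossReference("chebi", "15422"))
        == "https://identifiers.org/chebi/CHEBI:15422"
    )


def test_to_uri_errors():
    with pytest.raises(XrefValidationError):
        to_uri(CrossReference("chebi", "abc"))
    with pytest.raises(RegistryError):
        to_uri(CrossReference("not-a-namespace", "x"))


def test_uri_round_trip_exhaustive(registry):
    for xref in all_sample_xrefs():
        assert from_uri(to_uri(xref, registry), registry) == xref


def test_from_uri_legacy_urn_with_alias_and_percent_encoding():
    assert from_uri("urn:miriam:obo.chebi:CHEBI%3A15422") == CrossReference(
        "chebi", "CHEBI:15422"
    )


def test_from_uri_rejects_unknown_base():
    with pytest.raises(UriParseError):
        from_uri("https://example.org/x")


def test_validated_canonicalizes_namespace_alias(registry):
    xref = CrossReference("obo.chebi", "15422").validated(registry)
    assert xref == CrossReference("chebi", "CHEBI:15422")
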
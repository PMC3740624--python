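"""Cross references: infer the resource behind a bare identifier, encode
identifiers.org URIs, and decode legacy MIRIAM URNs.

Resource inference matches the identifier against every namespace pattern
in the bundled registry snapshot; a literal prefix (CHEBI:) pins the match,
while a bare number is legitimately ambiguous and the caller must choose.
"""

from gemannot import CrossReference, from_uri, infer_resource, to_uri

for ident in ("CHEBI:15422", "C00002", "15422", "HMDB0000122"):
    print(f"{ident!r:18} -> {infer_resource(ident)}")

print()
xref = CrossReference("chebi", "CHEBI:15422")
uri = to_uri(xref)
print(f"to_uri:   {xref}  ->  {uri}")
print(f"from_uri: {uri}  ->  {from_uri(uri)}")
print(f"legacy:   urn:miriam:obo.chebi:CHEBI%3A15422  ->  "
      f"{from_uri('urn:miriam:obo.chebi:CHEBI%3A15422')}")
print()
print("The prefixed ChEBI identifier resolves uniquely; the bare '15422'")
print("matches several namespaces and is returned as an ordered candidate list.")
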
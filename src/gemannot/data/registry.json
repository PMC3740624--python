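{
  "version": "gemannot-registry-1",
  "namespaces": [
    {
      "namespace": "chebi",
      "display_name": "ChEBI",
      "pattern": "^CHEBI:\\d+$",
      "uri_base": "https://identifiers.org/chebi/",
      "id_prefix": "CHEBI:",
      "aliases": ["obo.chebi"]
    },
    {
      "namespace": "kegg.compound",
      "display_name": "KEGG Compound",
      "pattern": "^C\\d{5}$",
      "uri_base": "https://identifiers.org/kegg.compound/"
    },
    {
      "namespace": "kegg.reaction",
      "display_name": "KEGG Reaction",
      "pattern": "^R\\d{5}$",
      "uri_base": "https://identifiers.org/kegg.reaction/"
    },
    {
      "namespace": "kegg.glycan",
      "display_name": "KEGG Glycan",
      "pattern": "^G\\d{5}$",
      "uri_base": "https://identifiers.org/kegg.glycan/"
    },
    {
      "namespace": "kegg.pathway",
      "display_name": "KEGG Pathway",
      "pattern": "^map\\d{5}$",
      "uri_base": "https://identifiers.org/kegg.pathway/"
    },
    {
      "namespace": "hmdb",
      "display_name": "Human Metabolome Database",
      "pattern": "^HMDB\\d{7,9}$",
      "uri_base": "https://identifiers.org/hmdb/"
    },
    {
      "namespace": "pubchem.compound",
      "display_name": "PubChem Compound (CID)",
      "pattern": "^\\d+$",
      "uri_base": "https://identifiers.org/pubchem.compound/"
    },
    {
      "namespace": "metacyc.compound",
      "display_name": "MetaCyc Compound",
      "pattern": "^CPD(-[A-Z0-9]+)+$",
      "uri_base": "https://identifiers.org/metacyc.compound/"
    },
    {
      "namespace": "bigg.metabolite",
      "display_name": "BiGG Metabolite",
      "pattern": "^[a-z][a-z0-9_]+$",
      "uri_base": "https://identifiers.org/bigg.metabolite/"
    },
    {
      "namespace": "bigg.reaction",
      "display_name": "BiGG Reaction",
      "pattern": "^[A-Z]{2,}[A-Za-z0-9_]*$",
      "uri_base": "https://identifiers.org/bigg.reaction/"
    },
    {
      "namespace": "seed.compound",
      "display_name": "ModelSEED Compound",
      "pattern": "^cpd\\d{5}$",
      "uri_base": "https://identifiers.org/seed.compound/"
    },
    {
      "namespace": "metanetx.chemical",
      "display_name": "MetaNetX Chemical",
      "pattern": "^MNXM\\d+$",
      "uri_base": "https://identifiers.org/metanetx.chemical/"
    },
    {
      "namespace": "lipidmaps",
      "display_name": "LIPID MAPS",
      "pattern": "^LM[A-Z]{2}\\d{8,10}$",
      "uri_base": "https://identifiers.org/lipidmaps/"
    },
    {
      "namespace": "cas",
      "display_name": "CAS Registry Number",
      "pattern": "^\\d{1,7}-\\d{2}-\\d$",
      "uri_base": "https://identifiers.org/cas/"
    },
    {
      "namespace": "inchikey",
      "display_name": "InChIKey",
      "pattern": "^[A-Z]{14}-[A-Z]{10}-[A-Z]$",
      "uri_base": "https://identifiers.org/inchikey/"
    },
    {
      "namespace": "rhea",
      "display_name": "Rhea",
      "pattern": "^\\d{5}$",
      "uri_base": "https://identifiers.org/rhea/"
    },
    {
      "namespace": "ec-code",
      "display_name": "Enzyme Nomenclature",
      "pattern": "^\\d+\\.\\d+\\.\\d+\\.(\\d+|-)$",
      "uri_base": "https://identifiers.org/ec-code/",
      "aliases": ["ec"]
    },
    {
      "namespace": "uniprot",
      "display_name": "UniProt Knowledgebase",
      "pattern": "^([A-NR-Z][0-9][A-Z][A-Z0-9]{2}[0-9]|[OPQ][0-9][A-Z0-9]{3}[0-9])$",
      "uri_base": "https://identifiers.org/uniprot/"
    },
    {
      "namespace": "go",
      "display_name": "Gene Ontology",
      "pattern": "^GO:\\d{7}$",
      "uri_base": "https://identifiers.org/go/",
      "id_prefix": "GO:",
      "aliases": ["obo.go"]
    },
    {
      "namespace": "reactome",
      "display_name": "Reactome",
      "pattern": "^R-[A-Z]{3}-\\d+(-\\d+)?$",
      "uri_base": "https://identifiers.org/reactome/"
    }
  ]
}
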
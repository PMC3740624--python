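import pytest

from gemannot.fixtures import FixtureSpec, generate
from gemannot.index import TableConfig, build_index
from gemannot.miriam import default_registry


FULL_SPEC = FixtureSpec(
    seed=1,
    include_imbalanced=True,
    include_peptides=True,
    include_ambiguous=True,
)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """A full fixture bundle with every defect flag switched on."""
    out = tmp_path_factory.mktemp("bundle")
    generate(FULL_SPEC, out)
    return out


@pytest.fixture(scope="session")
def bundle_manifest(bundle_dir):
    import json

    return json.loads((bundle_dir / "manifest.json").read_text())


@pytest.fixture(scope="session")
def resource_index(bundle_dir, registry):
    idx, warnings = build_index(
        [
            TableConfig.from_json(bundle_dir / "resource_chebi_config.json"),
            TableConfig.from_json(bundle_dir / "resource_kegg_config.json"),
        ],
        registry,
    )
    assert not warnings
    return idx
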
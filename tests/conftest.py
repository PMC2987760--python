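import pytest

from countersig import generate_bundle, published_example_config, write_bundle


@pytest.fixture(scope="session")
def planted_bundle():
    """The bundled published-counts synthetic fixture (generated, not stored)."""
    return generate_bundle(published_example_config(seed=11))


@pytest.fixture(scope="session")
def bundle_dir(planted_bundle, tmp_path_factory):
    """The published-counts fixture written out as pipeline-ready files."""
    out = tmp_path_factory.mktemp("bundle")
    write_bundle(planted_bundle, out)
    return out
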
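import pytest

from synsieve import build_collect_fixture, build_neighbourhood_set, default_family_spec


@pytest.fixture(scope="session")
def family_set(tmp_path_factory):
    """Canonical synthetic set: 3 near-identical neighbourhoods + 1 outsider."""
    root = tmp_path_factory.mktemp("family_set")
    manifest = build_neighbourhood_set(default_family_spec(seed=11), root)
    return root, manifest


@pytest.fixture(scope="session")
def collect_fixture(tmp_path_factory):
    """Toy hit table + synthetic source records covering every collect outcome."""
    root = tmp_path_factory.mktemp("collect_fx")
    return build_collect_fixture(root, seed=11)
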
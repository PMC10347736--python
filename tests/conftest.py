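import pytest

from tebench.fixtures import FixtureSpec, make_fixture


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """A small deterministic input bundle shared across tests."""
    out = tmp_path_factory.mktemp("fixture")
    return make_fixture(FixtureSpec(seed=11), out)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A single-chromosome bundle for fast end-to-end runs."""
    out = tmp_path_factory.mktemp("fixture_small")
    spec = FixtureSpec(n_chroms=1, chrom_length=30_000, n_trna_genes=3, seed=7)
    return make_fixture(spec, out)
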
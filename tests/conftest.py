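import pytest

from circkit.fixtures import (
    FixtureSpec,
    generate_fixture_tree,
    make_reference,
    make_tool_calls,
    make_truth,
)
from circkit.io import GeneModel


@pytest.fixture(scope="session")
def spec():
    return FixtureSpec(seed=11, samples=("sample_01", "sample_02", "sample_03"))


@pytest.fixture(scope="session")
def reference(spec):
    return make_reference(spec)


@pytest.fixture(scope="session")
def truth(spec, reference):
    return make_truth(spec, reference)


@pytest.fixture(scope="session")
def tool_calls(spec, truth):
    return make_tool_calls(spec, truth)


@pytest.fixture(scope="session")
def fixture_tree(spec, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture_tree")
    paths = generate_fixture_tree(spec, str(outdir))
    return paths


@pytest.fixture
def toy_model():
    """One plus-strand gene with transcript T1: exons [100,200) and [300,400)."""
    model = GeneModel()
    for exon in ((100, 200), (300, 400)):
        model.add_exon("chr1", *exon, "+", "G1", "T1", "GENE_ONE")
    model.finalise()
    return model
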
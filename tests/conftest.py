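import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from skelenet.fixtures import FixtureSpec, generate, worked_example_graph
from skelenet.graph import build_graph
from skelenet.identifiers import load_alias_table
from skelenet.model import DirectedInteraction, DriverClass, Evidence, InteractionType, SourceDB


def edge(src, dst, itype=InteractionType.PHYSICAL, source=SourceDB.BIOGRID, detail="assay"):
    return DirectedInteraction(src, dst, itype, [Evidence(source, detail=detail)])


@pytest.fixture
def diamond():
    """A -> B -> D and A -> C -> D: two shortest paths of length two."""
    return build_graph([edge("A", "B"), edge("B", "D"), edge("A", "C"), edge("C", "D")])


@pytest.fixture
def chain():
    """D1 -> D2 <- A <- B <- C with drivers D1, D2."""
    drivers = {"D1": DriverClass.NON_SYNDROMIC, "D2": DriverClass.SYNDROMIC}
    return build_graph(
        [edge("D1", "D2"), edge("A", "D2"), edge("B", "A"), edge("C", "B")], drivers
    )


@pytest.fixture(scope="session")
def worked():
    graph, example = worked_example_graph()
    return graph, example


@pytest.fixture(scope="session")
def fixture_dataset(tmp_path_factory):
    """One generated synthetic dataset plus its manifest and alias table."""
    out = tmp_path_factory.mktemp("dataset")
    spec = FixtureSpec(seed=11, n_genes=30, n_drivers=5)
    manifest = generate(spec, out)
    table = load_alias_table(out / "aliases.tsv")
    return out, manifest, table
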
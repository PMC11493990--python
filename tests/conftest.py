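import pathlib

import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("ci")

from transnetkit import fixtures, kb_readers, omics_io
from transnetkit.graph_core import (
    Compartment,
    Direction,
    EdgeType,
    Layer,
    Molecule,
    RegulationEdge,
    TransOmicsNetwork,
)


@pytest.fixture(scope="session")
def toy_kb_dir(tmp_path_factory) -> pathlib.Path:
    d = tmp_path_factory.mktemp("toy_kb")
    fixtures.generate_toy_kb(fixtures.FixtureSpec(seed=11), d)
    return d


@pytest.fixture(scope="session")
def toy_kb(toy_kb_dir) -> kb_readers.KnowledgeBase:
    return kb_readers.load_knowledge_base(toy_kb_dir)


@pytest.fixture(scope="session")
def planted_dir(tmp_path_factory) -> pathlib.Path:
    d = tmp_path_factory.mktemp("planted")
    spec = fixtures.FixtureSpec(seed=5, planted_tf=fixtures.PlantedEnrichment())
    fixtures.generate_omics_with_planted_enrichment(spec, d)
    return d


def make_net(node_specs, edge_specs) -> TransOmicsNetwork:
    """Helper: build a network from (id, layer[, compartment, direction])
    node tuples and (src_idx, dst_idx, edge_type[, sign]) edge tuples."""
    net = TransOmicsNetwork()
    mols = []
    for spec in node_specs:
        ident, layer = spec[0], spec[1]
        compartment = spec[2] if len(spec) > 2 else Compartment.NONE
        direction = spec[3] if len(spec) > 3 else Direction.UNKNOWN
        mols.append(net.add_molecule(Molecule(ident, layer, compartment, direction)))
    for spec in edge_specs:
        i, j, etype = spec[0], spec[1], spec[2]
        sign = spec[3] if len(spec) > 3 else "unsigned"
        net.add_edge(RegulationEdge(mols[i].key, mols[j].key, etype, sign))
    return net


@pytest.fixture
def two_node_net():
    return make_net(
        [("TF1", Layer.TF), ("GeneA", Layer.MRNA)],
        [(0, 1, EdgeType.TF_TARGET)],
    )
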
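import networkx as nx
import pytest

from pdpmflow.module_detection import Module, ModulePartition
from pdpmflow.synthetic import replica_fixture


@pytest.fixture(scope="session")
def replica():
    """In-text worked-number fixture (synthetic symbols)."""
    return replica_fixture(seed=0)


@pytest.fixture(scope="session")
def replica_dir(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("replica")
    replica_fixture(outdir=outdir, seed=0)
    return outdir


@pytest.fixture
def two_cliques_bridge():
    """Two K4 cliques joined by a single bridge edge."""
    g = nx.Graph()
    for base in ("A", "B"):
        nodes = [f"{base}{i}" for i in range(4)]
        for i, u in enumerate(nodes):
            for v in nodes[i + 1:]:
                g.add_edge(u, v)
    g.add_edge("A0", "B0")
    return g


def make_partition(method, label, *node_groups):
    return ModulePartition(
        method=method,
        modules=tuple(
            Module(module_id=f"{label}{i + 1}", nodes=frozenset(nodes))
            for i, nodes in enumerate(node_groups)
        ),
        network_label=label,
    )
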
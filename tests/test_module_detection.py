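import math

import networkx as nx
import numpy as np
import pytest

from pdpmflow.module_detection import (
    MCODEParams,
    Module,
    ModulePartition,
    _mcl_step,
    community,
    mcl,
    mcode,
    mcode_vertex_weight,
    partition_entropy,
    read_partition,
    select_partition,
    write_partition,
)

# ---------------------------------------------------------------------------
# independent brute-force transcription of the complex-growth procedure,
# kept free of the library's helpers (manual k-core pruning, explicit BFS)
# ---------------------------------------------------------------------------


def _oracle_weight(g, v, degree_cutoff=2):
    if g.degree(v) < degree_cutoff:
        return 0.0
    nodes = set(g[v]) | {v}
    best = 0.0
    # find the highest k-core of the closed neighborhood by manual pruning
    for k in range(1, len(nodes) + 1):
        members = set(nodes)
        changed = True
        while changed:
            changed = False
            for u in list(members):
                if sum(1 for w in g[u] if w in members) < k:
                    members.discard(u)
                    changed = True
        if not members:
            break
        n = len(members)
        e = sum(1 for a in members for b in g[a] if b in members) // 2
        density = 2 * e / (n * (n - 1)) if n > 1 else 0.0
        best = k * density
    return best


def _oracle_mcode(g, cutoff=0.2, degree_cutoff=2, min_nodes=4):
    weights = {v: _oracle_weight(g, v, degree_cutoff) for v in g}
    order = sorted(g, key=lambda v: (-weights[v], v))
    taken = set()
    found = []
    for seed in order:
        if seed in taken or weights[seed] <= 0:
            continue
        thr = weights[seed] * (1 - cutoff)
        members = {seed}
        queue = [seed]
        while queue:
            u = queue.pop(0)
            for w in g[u]:
                if w not in members and w not in taken and weights[w] > 0 and weights[w] >= thr:
                    members.add(w)
                    queue.append(w)
        taken |= members
        if len(members) >= min_nodes:
            found.append(frozenset(members))
    return set(found)


class TestVertexWeight:
    def test_k4_vertex(self):
        g = nx.complete_graph(4)
        assert mcode_vertex_weight(g, 0) == 3.0

    def test_pendant_vertex_below_degree_cutoff(self):
        g = nx.path_graph(2)
        assert mcode_vertex_weight(g, 0) == 0.0

    def test_isolated_vertex(self):
        g = nx.Graph()
        g.add_nodes_from([0, 1, 2])
        g.add_edge(1, 2)
        assert mcode_vertex_weight(g, 0) == 0.0

    def test_matches_oracle_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(3, 9))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.9)),
                                    seed=int(rng.integers(0, 2**31)))
            for v in g:
                assert mcode_vertex_weight(g, v) == pytest.approx(_oracle_weight(g, v))


class TestMCODE:
    def test_bridged_cliques_grow_into_one_complex(self, two_cliques_bridge):
        # all vertices weigh 3.0, so the bridge neighbour passes the
        # seed*(1-0.2) threshold and both cliques join one complex —
        # confirmed by the independent transcription of the growth rule
        part = mcode(two_cliques_bridge, label="T")
        got = {m.nodes for m in part.modules}
        assert got == _oracle_mcode(two_cliques_bridge)
        assert got == {frozenset(two_cliques_bridge.nodes)}

    def test_tree_has_no_complexes(self):
        part = mcode(nx.balanced_tree(2, 3), label="T")
        assert part.modules == ()

    def test_separated_cliques_recovered(self):
        g = nx.Graph()
        for base in ("A", "B", "C"):
            nodes = [f"{base}{i}" for i in range(5)]
            for i, u in enumerate(nodes):
                for v in nodes[i + 1:]:
                    g.add_edge(u, v)
        part = mcode(g, label="T")
        assert {frozenset(m.nodes) for m in part.modules} == _oracle_mcode(g)
        assert len(part.modules) == 3

    def test_matches_oracle_on_random_small_graphs(self):
        """Dual-route check of the seed-and-grow procedure."""
        rng = np.random.default_rng(7)
        for _ in range(150):
            n = int(rng.integers(4, 9))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.95)),
                                    seed=int(rng.integers(0, 2**31)))
            part = mcode(g, label="T")
            assert {m.nodes for m in part.modules} == _oracle_mcode(g)

    def test_modules_disjoint_with_internal_neighbors(self):
        g = nx.gnp_random_graph(25, 0.3, seed=5)
        part = mcode(g, label="T")
        seen = set()
        for m in part.modules:
            assert not (seen & m.nodes)
            seen |= m.nodes
            for v in m.nodes:
                assert any(u in m.nodes for u in g[v])

    def test_labels_ranked_by_score(self):
        g = nx.Graph()
        for base, size in (("A", 6), ("B", 4)):
            nodes = [f"{base}{i}" for i in range(size)]
            for i, u in enumerate(nodes):
                for v in nodes[i + 1:]:
                    g.add_edge(u, v)
        part = mcode(g, label="X")
        assert [m.module_id for m in part.modules] == ["X1", "X2"]
        assert part.modules[0].score >= part.modules[1].score


class TestMCL:
    def test_two_triangles_bridge(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"),
                      ("d", "e"), ("e", "f"), ("d", "f"), ("c", "d")])
        part = mcl(g, min_module_nodes=3, label="T")
        assert {frozenset(m.nodes) for m in part.modules} == {
            frozenset("abc"), frozenset("def")
        }

    def test_complete_graph_single_cluster(self):
        part = mcl(nx.complete_graph(5), min_module_nodes=4, label="T")
        assert len(part.modules) == 1
        assert len(part.modules[0]) == 5

    def test_edgeless_graph_no_clusters(self):
        g = nx.Graph()
        g.add_nodes_from(range(6))
        assert mcl(g, label="T").modules == ()

    def test_step_preserves_column_stochasticity(self):
        rng = np.random.default_rng(0)
        m = rng.random((8, 8)) + 0.01
        m /= m.sum(axis=0, keepdims=True)
        for _ in range(10):
            m = _mcl_step(m, 2.0, 2)
            np.testing.assert_allclose(m.sum(axis=0), 1.0, atol=1e-12)


class TestCommunity:
    def test_bridged_cliques_split(self, two_cliques_bridge):
        part = community(two_cliques_bridge, label="T")
        assert {frozenset(m.nodes) for m in part.modules} == {
            frozenset({"A0", "A1", "A2", "A3"}),
            frozenset({"B0", "B1", "B2", "B3"}),
        }

    def test_complete_graph_one_community(self):
        part = community(nx.complete_graph(5), label="T")
        assert len(part.modules) == 1


class TestPartitionEntropy:
    def _part(self, *sizes):
        offset = 0
        groups = []
        for s in sizes:
            groups.append(frozenset(f"n{offset + i}" for i in range(s)))
            offset += s
        return ModulePartition(
            "x", tuple(Module(f"M{i}", g) for i, g in enumerate(groups))
        )

    def test_single_module_zero(self):
        g = nx.complete_graph(4)
        assert partition_entropy(g, self._part(4)).entropy == 0.0

    def test_two_equal_modules_ln2(self):
        g = nx.empty_graph(8)
        assert partition_entropy(g, self._part(4, 4)).entropy == pytest.approx(math.log(2))

    def test_sizes_4_4_8(self):
        g = nx.empty_graph(16)
        h = partition_entropy(g, self._part(4, 4, 8)).entropy
        assert h == pytest.approx(1.0397, abs=1e-4)

    def test_empty_partition_is_inf(self):
        part = ModulePartition("x", ())
        assert math.isinf(partition_entropy(nx.complete_graph(3), part).entropy)

    def test_maximal_at_equal_sizes(self):
        g = nx.empty_graph(12)
        equal = partition_entropy(g, self._part(4, 4, 4)).entropy
        for sizes in ((2, 4, 6), (1, 4, 7), (3, 4, 5)):
            assert partition_entropy(g, self._part(*sizes)).entropy <= equal

    def test_permutation_invariant(self):
        g = nx.empty_graph(12)
        assert partition_entropy(g, self._part(2, 4, 6)).entropy == pytest.approx(
            partition_entropy(g, self._part(6, 2, 4)).entropy
        )


class TestSelectPartition:
    def test_minimum_entropy_wins(self):
        # three separated K5s: every method finds them; tie broken to mcode
        g = nx.Graph()
        for base in ("A", "B", "C"):
            nodes = [f"{base}{i}" for i in range(5)]
            for i, u in enumerate(nodes):
                for v in nodes[i + 1:]:
                    g.add_edge(u, v)
        method, part, table = select_partition(g, label="T")
        assert method == "mcode"
        assert len(part.modules) == 3
        assert len(table) == 3

    def test_all_methods_empty_is_error(self):
        g = nx.path_graph(6)  # a tree: no dense module anywhere
        g = nx.relabel_nodes(g, str)
        params = MCODEParams(min_module_nodes=7)
        with pytest.raises(ValueError, match="no modules"):
            select_partition(g, params, label="T")


def test_partition_round_trip(tmp_path):
    part = ModulePartition(
        "mcode",
        (Module("T1", frozenset({"A", "B", "C", "D"})),
         Module("T2", frozenset({"E", "F", "G", "H"}))),
        network_label="T",
    )
    path = tmp_path / "p.tsv"
    write_partition(part, path)
    back = read_partition(path)
    assert {m.module_id: m.nodes for m in back.modules} == {
        m.module_id: m.nodes for m in part.modules
    }
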
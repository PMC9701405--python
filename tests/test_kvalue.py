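import math

import networkx as nx
import numpy as np
import pytest

from conftest import make_partition
from pdpmflow.kvalue import (
    INDICATORS,
    NormalizedProfile,
    TopologyProfile,
    entropy_weights,
    k_value,
    module_topology,
    normalize_profiles,
    relative_distance,
    score_mrps,
)
from pdpmflow.module_detection import Module
from pdpmflow.mrp import find_mrps
from pdpmflow.synthetic import replica_fixture

# ---------------------------------------------------------------------------
# straight-line transcription of the scoring equations, used as the
# independent oracle for the pipeline implementation
# ---------------------------------------------------------------------------


def _oracle_k_pipeline(raw_profiles, pair_indices):
    """raw_profiles: list of 4-vectors; returns (weights, {pair: K})."""
    x = [list(map(float, row)) for row in raw_profiles]
    m, n = len(x), 4
    # extreme-value normalisation (benefit form)
    norm = [[0.0] * n for _ in range(m)]
    for j in range(n):
        col = [x[i][j] for i in range(m)]
        fmax, fmin = max(col), min(col)
        for i in range(m):
            norm[i][j] = (x[i][j] - fmin) / (fmax - fmin) if fmax > fmin else 0.0
    # entropy weights
    e = [0.0] * n
    for j in range(n):
        col = [norm[i][j] for i in range(m)]
        s = sum(col)
        if s == 0 or all(abs(v - col[0]) < 1e-15 for v in col):
            e[j] = 1.0
            continue
        acc = 0.0
        for v in col:
            p = v / s
            if p > 0:
                acc += p * math.log(p)
        e[j] = -acc / math.log(m)
    info = [1 - ej for ej in e]
    w = [v / sum(info) for v in info] if sum(info) > 0 else [1 / n] * n
    # per-pair relative distance and K
    ks = {}
    for (ia, ib) in pair_indices:
        diffs = [(norm[ia][j] - norm[ib][j]) ** 2 for j in range(n)]
        tot = sum(diffs)
        d = [v / tot for v in diffs] if tot > 1e-18 else [0.0] * n
        ks[(ia, ib)] = math.sqrt(sum(wj * dj for wj, dj in zip(w, d)))
    return w, ks


def _profile(mid, vec):
    return NormalizedProfile(module_id=mid, D=tuple(vec))


class TestModuleTopology:
    def test_k4(self):
        g = nx.complete_graph(4)
        g = nx.relabel_nodes(g, str)
        p = module_topology(g, Module("M", frozenset(g.nodes)))
        assert (p.n_nodes, p.n_edges, p.avg_neighbors, p.cpl) == (4, 6, 3.0, 1.0)

    def test_path4(self):
        g = nx.path_graph(4)
        g = nx.relabel_nodes(g, str)
        p = module_topology(g, Module("M", frozenset(g.nodes)))
        assert (p.n_nodes, p.n_edges) == (4, 3)
        assert p.avg_neighbors == pytest.approx(1.5)
        assert p.cpl == pytest.approx(10 / 6)

    def test_isolated_nodes(self):
        g = nx.empty_graph(4)
        g = nx.relabel_nodes(g, str)
        p = module_topology(g, Module("M", frozenset(g.nodes)))
        assert (p.n_edges, p.avg_neighbors, p.cpl) == (0, 0.0, 0.0)

    def test_induced_subgraph_only(self):
        g = nx.complete_graph(6)
        g = nx.relabel_nodes(g, str)
        p = module_topology(g, Module("M", frozenset({"0", "1", "2", "3"})))
        assert p.n_edges == 6  # K4 induced, outside edges ignored


class TestNormalizeProfiles:
    def _profiles(self, values):
        return [
            TopologyProfile(f"M{i}", v, v, float(v), float(v))
            for i, v in enumerate(values)
        ]

    def test_benefit_orientation(self):
        out = normalize_profiles(self._profiles([0, 5, 10]))
        assert [p.D[0] for p in out] == [0.0, 0.5, 1.0]

    def test_cost_orientation(self):
        orientation = {name: "cost" for name in INDICATORS}
        out = normalize_profiles(self._profiles([0, 5, 10]), orientation)
        assert [p.D[0] for p in out] == [1.0, 0.5, 0.0]

    def test_cost_plus_benefit_is_one(self):
        values = [1, 3, 7, 9]
        benefit = normalize_profiles(self._profiles(values))
        cost = normalize_profiles(self._profiles(values),
                                  {name: "cost" for name in INDICATORS})
        for b, c in zip(benefit, cost):
            for x, y in zip(b.D, c.D):
                assert x + y == pytest.approx(1.0)

    def test_constant_indicator_zeroed(self):
        out = normalize_profiles(self._profiles([5, 5, 5]))
        assert all(p.D == (0.0, 0.0, 0.0, 0.0) for p in out)

    def test_single_profile_rejected(self):
        with pytest.raises(ValueError):
            normalize_profiles(self._profiles([1]))


class TestRelativeDistance:
    def test_unit_difference(self):
        d = relative_distance(_profile("a", (1, 0, 0, 0)), _profile("b", (0, 0, 0, 0)))
        assert d.d == (1.0, 0.0, 0.0, 0.0)

    def test_two_equal_differences(self):
        d = relative_distance(_profile("a", (1, 1, 0, 0)), _profile("b", (0, 0, 0, 0)))
        assert d.d == (0.5, 0.5, 0.0, 0.0)

    def test_identical_profiles_degenerate(self):
        d = relative_distance(_profile("a", (0.3, 0.7, 0.1, 0.5)),
                              _profile("b", (0.3, 0.7, 0.1, 0.5)))
        assert d.d == (0.0, 0.0, 0.0, 0.0)

    def test_sums_to_one_or_zero(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a, b = rng.random(4), rng.random(4)
            d = relative_distance(_profile("a", a), _profile("b", b))
            assert sum(d.d) == pytest.approx(1.0, abs=1e-12)


class TestEntropyWeights:
    def test_one_informative_column(self):
        mat = np.array([[1.0, 2, 2, 2], [3, 2, 2, 2], [5, 2, 2, 2]])
        w = entropy_weights(mat)
        assert w.w[0] == pytest.approx(1.0)
        assert w.w[1:] == (0.0, 0.0, 0.0)

    def test_all_columns_identical_uniform(self):
        mat = np.tile(np.array([[1.0], [2.0], [4.0]]), (1, 4))
        w = entropy_weights(mat)
        assert all(x == pytest.approx(0.25) for x in w.w)

    def test_two_column_example(self):
        w = entropy_weights(np.array([[1.0, 2], [3, 2], [5, 2]]),
                            indicators=("a", "b"))
        assert w.w == pytest.approx((1.0, 0.0))

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            mat = rng.random((int(rng.integers(2, 10)), 4))
            assert sum(entropy_weights(mat).w) == pytest.approx(1.0, abs=1e-12)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            entropy_weights(np.array([[1.0, -1], [2, 3]]))


class TestKValue:
    def _w(self, *vals):
        from pdpmflow.kvalue import WeightVector
        return WeightVector(w=tuple(vals))

    def _d(self, *vals):
        from pdpmflow.kvalue import DistanceVector
        return DistanceVector(pair=("a", "b"), d=tuple(vals))

    def test_uniform_weights_give_half(self):
        assert k_value(self._d(0.1, 0.2, 0.3, 0.4), self._w(0.25, 0.25, 0.25, 0.25)) == 0.5

    def test_concentrated(self):
        assert k_value(self._d(1, 0, 0, 0), self._w(1, 0, 0, 0)) == 1.0

    def test_mixed(self):
        assert k_value(self._d(0.25, 0.25, 0.25, 0.25),
                       self._w(0.4, 0.3, 0.2, 0.1)) == pytest.approx(0.5)

    def test_zero_distance(self):
        assert k_value(self._d(0, 0, 0, 0), self._w(0.4, 0.3, 0.2, 0.1)) == 0.0


class TestScoreMRPs:
    def test_identical_partitions_all_zero(self):
        g = nx.gnp_random_graph(12, 0.4, seed=4)
        g = nx.relabel_nodes(g, str)
        nodes = sorted(g.nodes)
        a = make_partition("planted", "A", set(nodes[:5]), set(nodes[5:10]))
        b = make_partition("planted", "B", set(nodes[:5]), set(nodes[5:10]))
        mrps = find_mrps(a, b)
        scores, w, _ = score_mrps(g, g, a, b, mrps)
        same = [s for s in scores if s.d == (0, 0, 0, 0)]
        assert len(same) == 2
        assert all(s.K == 0.0 for s in same)

    def test_toy_comparison_matches_equation_transcription(self, replica):
        """Dual-implementation check of the full scoring pipeline."""
        g, part_a, part_b = replica.toy_graph, replica.toy_part_a, replica.toy_part_b
        mrps = find_mrps(part_a, part_b)
        scores, w, normalized = score_mrps(g, g, part_a, part_b, mrps)
        # oracle input: raw profiles in the same module order
        mods = list(part_a.modules) + list(part_b.modules)
        raw = []
        for m in mods:
            p = module_topology(g, m)
            raw.append([p.n_nodes, p.n_edges, p.avg_neighbors, p.cpl])
        idx = {m.module_id: i for i, m in enumerate(mods)}
        pair_idx = [(idx[p.module_a], idx[p.module_b]) for p in mrps]
        ow, oks = _oracle_k_pipeline(raw, pair_idx)
        assert np.allclose(w.w, ow, atol=1e-12)
        for s in scores:
            assert s.K == pytest.approx(oks[(idx[s.module_a], idx[s.module_b])], abs=1e-12)

    def test_symmetry_under_stage_swap(self, replica):
        g, pa, pb = replica.toy_graph, replica.toy_part_a, replica.toy_part_b
        fwd, _, _ = score_mrps(g, g, pa, pb, find_mrps(pa, pb))
        rev, _, _ = score_mrps(g, g, pb, pa, find_mrps(pb, pa))
        fmap = {(s.module_a, s.module_b): s.K for s in fwd}
        rmap = {(s.module_b, s.module_a): s.K for s in rev}
        assert fmap.keys() == rmap.keys()
        for k in fmap:
            assert fmap[k] == pytest.approx(rmap[k], abs=1e-12)

    def test_orientation_leaves_distances_unchanged(self, replica):
        # x -> 1-x preserves every squared difference, so d is identical;
        # the entropy weights (computed from the normalized matrix) may shift
        g, pa, pb = replica.toy_graph, replica.toy_part_a, replica.toy_part_b
        mrps = find_mrps(pa, pb)
        benefit, _, _ = score_mrps(g, g, pa, pb, mrps)
        cost, _, _ = score_mrps(g, g, pa, pb, mrps,
                                orientation={n: "cost" for n in INDICATORS})
        for s1, s2 in zip(benefit, cost):
            assert s1.d == pytest.approx(s2.d, abs=1e-12)

    def test_orientation_insensitive_with_distance_weights(self, replica):
        g, pa, pb = replica.toy_graph, replica.toy_part_a, replica.toy_part_b
        mrps = find_mrps(pa, pb)
        benefit, _, _ = score_mrps(g, g, pa, pb, mrps, weight_source="distances")
        cost, _, _ = score_mrps(g, g, pa, pb, mrps,
                                orientation={n: "cost" for n in INDICATORS},
                                weight_source="distances")
        for s1, s2 in zip(benefit, cost):
            assert s1.K == pytest.approx(s2.K, abs=1e-12)


class TestInvariants:
    def test_uniform_weight_k_is_half_for_any_nonidentical_pair(self):
        """With uniform weights every differing pair scores exactly 0.5."""
        from pdpmflow.kvalue import WeightVector
        rng = np.random.default_rng(9)
        w = WeightVector(w=(0.25, 0.25, 0.25, 0.25))
        for _ in range(50):
            a, b = rng.random(4), rng.random(4)
            d = relative_distance(_profile("a", a), _profile("b", b))
            assert k_value(d, w) == pytest.approx(0.5, abs=1e-12)

    def test_k_monotone_in_highest_weight_indicator(self):
        from pdpmflow.kvalue import WeightVector
        w = WeightVector(w=(0.6, 0.2, 0.1, 0.1))
        prev = -1.0
        for delta in np.linspace(0.05, 1.0, 12):
            a = _profile("a", (delta, 0.1, 0.1, 0.1))
            b = _profile("b", (0.0, 0.0, 0.0, 0.0))
            k = k_value(relative_distance(a, b), w)
            assert k >= prev - 1e-12
            prev = k

    def test_k_bounded_by_sqrt_max_weight(self):
        from pdpmflow.kvalue import WeightVector
        rng = np.random.default_rng(13)
        for _ in range(30):
            raw = rng.random(4)
            w = WeightVector(w=tuple(raw / raw.sum()))
            d = relative_distance(_profile("a", rng.random(4)),
                                  _profile("b", rng.random(4)))
            assert k_value(d, w) <= math.sqrt(max(w.w)) + 1e-12
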
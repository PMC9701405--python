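"""Network module detection and minimum-entropy method selection.

Three clustering routes are available — an MCODE-style seed-and-grow
complex finder, Markov clustering (MCL) and greedy modularity communities
— and the route yielding the lowest Shannon entropy of the module size
distribution is selected, i.e. the most concentrated modularisation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "MCODEParams",
    "Module",
    "ModulePartition",
    "PartitionEntropy",
    "mcode_vertex_weight",
    "mcode",
    "mcl",
    "community",
    "partition_entropy",
    "select_partition",
    "write_partition",
    "read_partition",
]


@dataclass(frozen=True)
class MCODEParams:
    """MCODE knobs in the Cytoscape plugin's vocabulary.

    ``node_score_cutoff`` is the allowed fractional drop of a candidate's
    vertex weight below the seed's; ``connectivity_threshold`` aliases the
    degree cutoff in some parameter listings and is retained for config
    fidelity.  ``min_module_nodes`` applies the "nodes >= 4" module filter
    used downstream of detection.
    """

    node_score_cutoff: float = 0.2
    degree_cutoff: int = 2
    k_core: int = 2
    max_depth: int = 100
    connectivity_threshold: int = 2
    min_module_nodes: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.node_score_cutoff <= 1.0:
            raise ValueError("node_score_cutoff must be in [0,1]")
        if self.degree_cutoff < 1 or self.k_core < 2 or self.max_depth < 1:
            raise ValueError("invalid MCODE parameters")


@dataclass(frozen=True)
class Module:
    module_id: str
    nodes: frozenset[str]
    seed: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.nodes:
            raise ValueError("empty module")

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class ModulePartition:
    method: str
    modules: tuple[Module, ...]
    network_label: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        ids = set()
        for mod in self.modules:
            if mod.module_id in ids:
                raise ValueError(f"duplicate module id {mod.module_id}")
            ids.add(mod.module_id)
            if seen & mod.nodes:
                raise ValueError("modules are not node-disjoint")
            seen |= mod.nodes

    def __len__(self) -> int:
        return len(self.modules)

    def by_id(self, module_id: str) -> Module:
        for mod in self.modules:
            if mod.module_id == module_id:
                return mod
        raise KeyError(module_id)

    def clustered_nodes(self) -> frozenset[str]:
        out: set[str] = set()
        for mod in self.modules:
            out |= mod.nodes
        return frozenset(out)

    def filter_min_size(self, min_nodes: int) -> "ModulePartition":
        kept = tuple(m for m in self.modules if len(m) >= min_nodes)
        return replace(self, modules=kept)


@dataclass(frozen=True)
class PartitionEntropy:
    method: str
    entropy: float


def mcode_vertex_weight(net: nx.Graph, v: str, params: MCODEParams | None = None) -> float:
    """Core-clustering weight of a vertex.

    The closed neighborhood N[v] is reduced to its highest k-core; the
    weight is that core's order k times its edge density.  Vertices with
    degree below ``degree_cutoff`` weigh 0, which keeps sparse periphery
    out of the seed list.
    """
    params = params or MCODEParams()
    if net.degree(v) < params.degree_cutoff:
        return 0.0
    closed = set(net[v]) | {v}
    sub = net.subgraph(closed)
    core_numbers = nx.core_number(sub)
    k = max(core_numbers.values())
    if k == 0:
        return 0.0
    core_nodes = [n for n, c in core_numbers.items() if c >= k]
    core = sub.subgraph(core_nodes)
    n = core.number_of_nodes()
    density = 2.0 * core.number_of_edges() / (n * (n - 1)) if n > 1 else 0.0
    return k * density


def _grow_complex(
    net: nx.Graph,
    seed: str,
    weights: dict[str, float],
    assigned: set[str],
    params: MCODEParams,
) -> set[str]:
    threshold = weights[seed] * (1.0 - params.node_score_cutoff)
    members = {seed}
    frontier = [(seed, 0)]
    while frontier:
        node, depth = frontier.pop(0)
        if depth >= params.max_depth:
            continue
        for nb in net[node]:
            if nb in members or nb in assigned:
                continue
            if weights[nb] >= threshold and weights[nb] > 0.0:
                members.add(nb)
                frontier.append((nb, depth + 1))
    return members


def mcode(
    net: nx.Graph,
    params: MCODEParams | None = None,
    label: str | None = None,
) -> ModulePartition:
    """MCODE-style complex detection.

    Complexes are grown breadth-first from unassigned seeds in descending
    vertex-weight order; a neighbor joins when its weight is at least
    ``seed_weight * (1 - node_score_cutoff)``.  Each vertex belongs to at
    most one complex.  Complexes smaller than ``min_module_nodes`` are
    dropped, and the survivors are labelled ``<LABEL><rank>`` by
    descending module score (mean vertex weight), rank starting at 1.
    """
    params = params or MCODEParams()
    label = label if label is not None else net.graph.get("label", "M")
    weights = {v: mcode_vertex_weight(net, v, params) for v in net.nodes}
    order = sorted(net.nodes, key=lambda v: (-weights[v], v))
    assigned: set[str] = set()
    raw: list[tuple[float, str, set[str]]] = []
    for seed in order:
        if seed in assigned or weights[seed] <= 0.0:
            continue
        members = _grow_complex(net, seed, weights, assigned, params)
        assigned |= members
        if len(members) >= params.min_module_nodes:
            score = sum(weights[v] for v in members) / len(members)
            raw.append((score, seed, members))
    raw.sort(key=lambda t: (-t[0], t[1]))
    modules = tuple(
        Module(module_id=f"{label}{rank}", nodes=frozenset(members), seed=seed, score=score)
        for rank, (score, seed, members) in enumerate(raw, start=1)
    )
    return ModulePartition(
        method="mcode", modules=modules, network_label=label, params=params.__dict__.copy()
    )


def _mcl_step(m: np.ndarray, inflation: float, expansion: int) -> np.ndarray:
    """One expansion+inflation round; preserves column stochasticity."""
    expanded = np.linalg.matrix_power(m, expansion)
    inflated = expanded ** inflation
    return inflated / inflated.sum(axis=0, keepdims=True)


def mcl(
    net: nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    max_iter: int = 200,
    tol: float = 1e-6,
    min_module_nodes: int = 4,
    label: str | None = None,
) -> ModulePartition:
    """Markov clustering on the graph's random-walk matrix.

    Self-loops of weight 1 are added, columns are normalised to
    stochasticity, and expansion (matrix power) alternates with inflation
    (elementwise power + column renormalisation) until the largest column
    change falls below ``tol``.  Clusters are read off the attractors of
    the limit matrix; clusters below ``min_module_nodes`` are dropped.
    """
    label = label if label is not None else net.graph.get("label", "M")
    nodes = sorted(net.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty network")
    index = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for u, v in net.edges:
        m[index[u], index[v]] = 1.0
        m[index[v], index[u]] = 1.0
    np.fill_diagonal(m, 1.0)
    m /= m.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        inflated = _mcl_step(m, inflation, expansion)
        if np.abs(inflated - m).max() < tol:
            m = inflated
            converged = True
            break
        m = inflated
    if not converged:
        logger.warning("MCL did not converge in %d iterations; using last iterate", max_iter)
    # attractors: rows with non-negligible mass; cluster = attractor row support
    eps = 1e-8
    clusters: list[set[int]] = []
    for i in range(n):
        if m[i, i] > eps:
            support = {j for j in range(n) if m[i, j] > eps}
            clusters.append(support)
    # merge overlapping supports (attractor systems share columns)
    merged: list[set[int]] = []
    for cl in clusters:
        hit = [g for g in merged if g & cl]
        for g in hit:
            merged.remove(g)
            cl |= g
        merged.append(cl)
    merged = [cl for cl in merged if len(cl) >= min_module_nodes]
    merged.sort(key=lambda cl: (-len(cl), min(nodes[i] for i in cl)))
    modules = tuple(
        Module(module_id=f"{label}{rank}", nodes=frozenset(nodes[i] for i in cl))
        for rank, cl in enumerate(merged, start=1)
    )
    return ModulePartition(
        method="mcl",
        modules=modules,
        network_label=label,
        params={"inflation": inflation, "expansion": expansion},
    )


def community(
    net: nx.Graph, min_module_nodes: int = 4, label: str | None = None
) -> ModulePartition:
    """Greedy modularity communities (CNM), size-filtered.

    Deterministic for a given graph; stands in for GUI community
    clustering plugins without claiming equivalence.
    """
    label = label if label is not None else net.graph.get("label", "M")
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    if net.number_of_edges() == 0:
        comms: list[set[str]] = []
    else:
        comms = [set(c) for c in nx.community.greedy_modularity_communities(net)]
    comms = [c for c in comms if len(c) >= min_module_nodes]
    comms.sort(key=lambda c: (-len(c), min(c)))
    modules = tuple(
        Module(module_id=f"{label}{rank}", nodes=frozenset(c))
        for rank, c in enumerate(comms, start=1)
    )
    return ModulePartition(method="community", modules=modules, network_label=label)


def partition_entropy(
    net: nx.Graph,
    part: ModulePartition,
    include_unclustered: bool = False,
) -> PartitionEntropy:
    """Shannon entropy (nats) of the module size distribution.

    Only clustered nodes enter the distribution by default; with
    ``include_unclustered`` each unclustered network node counts as a
    singleton module.  An empty partition maps to +inf so it always
    orders last in method selection.
    """
    sizes = [len(m) for m in part.modules]
    if include_unclustered:
        n_out = net.number_of_nodes() - len(part.clustered_nodes())
        sizes.extend([1] * n_out)
    total = sum(sizes)
    if total == 0:
        return PartitionEntropy(method=part.method, entropy=math.inf)
    h = -sum((s / total) * math.log(s / total) for s in sizes if s > 0)
    return PartitionEntropy(method=part.method, entropy=h)


_METHOD_PRIORITY = {"mcode": 0, "community": 1, "mcl": 2}


def select_partition(
    net: nx.Graph,
    params: MCODEParams | None = None,
    label: str | None = None,
    include_unclustered: bool = False,
) -> tuple[str, ModulePartition, list[PartitionEntropy]]:
    """Run all three detection methods and keep the minimum-entropy one.

    Ties break by method order mcode > community > mcl.  Raises if no
    method yields any module of at least ``min_module_nodes`` nodes.
    """
    params = params or MCODEParams()
    candidates = [
        mcode(net, params, label=label),
        community(net, min_module_nodes=params.min_module_nodes, label=label),
        mcl(net, min_module_nodes=params.min_module_nodes, label=label),
    ]
    table = [partition_entropy(net, p, include_unclustered) for p in candidates]
    ranked = sorted(
        zip(candidates, table),
        key=lambda pe: (pe[1].entropy, _METHOD_PRIORITY[pe[0].method]),
    )
    best, best_entropy = ranked[0]
    if math.isinf(best_entropy.entropy):
        raise ValueError("no modules found by any method")
    logger.info("selected %s (entropy %.4f)", best.method, best_entropy.entropy)
    return best.method, best, table


def write_partition(part: ModulePartition, path) -> None:
    """TSV with one (module_id, node) row per membership."""
    with open(path, "w") as fh:
        fh.write("module_id\tnode\n")
        for mod in part.modules:
            for node in sorted(mod.nodes):
                fh.write(f"{mod.module_id}\t{node}\n")


def read_partition(path, method: str = "file", network_label: str = "") -> ModulePartition:
    """Read a (module_id, node) TSV, e.g. a supplementary module table."""
    groups: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno + 1}: expected module_id TAB node")
            mid, node = parts[0].strip(), parts[1].strip().upper()
            if lineno == 0 and mid.lower() == "module_id":
                continue
            groups.setdefault(mid, set()).add(node)
    modules = tuple(
        Module(module_id=mid, nodes=frozenset(nodes))
        for mid, nodes in sorted(groups.items())
    )
    return ModulePartition(method=method, modules=modules, network_label=network_label)
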
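"""Entropy-weighted K-value scoring of module reconstruction pairs.

Each module is profiled by four topology indicators — node count, edge
count, mean within-module degree ("average neighbors") and characteristic
path length of the induced subgraph.  Profiles are min–max normalised
over all modules of the comparison (extreme-value method; cost or benefit
orientation per indicator), each pair is reduced to a relative squared
distance vector d with sum(d) = 1, indicator weights w come from the
entropy weight method (an indicator's weight grows with the information
content, 1 minus the normalised Shannon entropy, of its values across
modules), and

    K = sqrt(w1*d1 + w2*d2 + w3*d3 + w4*d4).

A smaller K means the two modules are more similar in structure; because
d is normalised per pair, discrimination between pairs comes entirely
from how each pair's differences align with the non-uniform weights.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .module_detection import Module, ModulePartition
from .mrp import MRPPair

logger = logging.getLogger(__name__)

__all__ = [
    "INDICATORS",
    "TopologyProfile",
    "NormalizedProfile",
    "DistanceVector",
    "WeightVector",
    "KScore",
    "module_topology",
    "normalize_profiles",
    "relative_distance",
    "entropy_weights",
    "k_value",
    "score_mrps",
]

INDICATORS = ("n_nodes", "n_edges", "avg_neighbors", "cpl")

# profiles closer than this per indicator (after normalisation) are equal
_EQ_TOL = 1e-9


@dataclass(frozen=True)
class TopologyProfile:
    module_id: str
    n_nodes: int
    n_edges: int
    avg_neighbors: float
    cpl: float

    def as_vector(self) -> np.ndarray:
        return np.array([self.n_nodes, self.n_edges, self.avg_neighbors, self.cpl], float)


@dataclass(frozen=True)
class NormalizedProfile:
    module_id: str
    D: tuple[float, float, float, float]


@dataclass(frozen=True)
class DistanceVector:
    pair: tuple[str, str]
    d: tuple[float, float, float, float]


@dataclass(frozen=True)
class WeightVector:
    w: tuple[float, ...]
    indicators: tuple[str, ...] = INDICATORS
    entropies: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if any(x < -1e-12 for x in self.w):
            raise ValueError("weights must be non-negative")
        if abs(sum(self.w) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


@dataclass(frozen=True)
class KScore:
    stage: str
    module_a: str
    module_b: str
    d: tuple[float, float, float, float]
    K: float


def module_topology(net: nx.Graph, module: Module) -> TopologyProfile:
    """Profile a module on the subgraph it induces in its disease network.

    CPL averages shortest-path lengths over connected node pairs and is 0
    when no pair is connected.
    """
    if not module.nodes:
        raise ValueError("empty module")
    missing = module.nodes - set(net.nodes)
    if missing:
        raise ValueError(f"module nodes absent from network: {sorted(missing)[:5]}")
    sub = net.subgraph(module.nodes)
    n, m = sub.number_of_nodes(), sub.number_of_edges()
    total, pairs = 0.0, 0
    for _, dists in nx.all_pairs_shortest_path_length(sub):
        for dist in dists.values():
            if dist > 0:
                total += dist
                pairs += 1
    return TopologyProfile(
        module_id=module.module_id,
        n_nodes=n,
        n_edges=m,
        avg_neighbors=2.0 * m / n,
        cpl=total / pairs if pairs else 0.0,
    )


def normalize_profiles(
    profiles: list[TopologyProfile],
    orientation: dict[str, str] | None = None,
) -> list[NormalizedProfile]:
    """Extreme-value (min–max) normalisation pooled over the profiles.

    ``orientation`` maps indicator name to "benefit" (larger is scored
    higher) or "cost" (smaller is scored higher); default all-benefit.
    The choice flips D to 1-D, which leaves pairwise differences |a-b|
    and hence every downstream K unchanged.  A constant indicator
    normalises to 0 for every module.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to normalise")
    orientation = orientation or {}
    mat = np.array([p.as_vector() for p in profiles])
    lo, hi = mat.min(axis=0), mat.max(axis=0)
    out = np.zeros_like(mat)
    for j, name in enumerate(INDICATORS):
        span = hi[j] - lo[j]
        if span == 0:
            logger.info("indicator %s constant across modules; normalised to 0", name)
            continue
        benefit = (mat[:, j] - lo[j]) / span
        out[:, j] = 1.0 - benefit if orientation.get(name, "benefit") == "cost" else benefit
    return [
        NormalizedProfile(module_id=p.module_id, D=tuple(row))
        for p, row in zip(profiles, out)
    ]


def relative_distance(a: NormalizedProfile, b: NormalizedProfile) -> DistanceVector:
    """Per-indicator share of the squared distance between two profiles.

    d_i = (a_i - b_i)^2 / sum_j (a_j - b_j)^2; identical profiles map to
    the all-zero vector (the 0/0 limit consistent with "smaller K = more
    similar").
    """
    av, bv = np.asarray(a.D, float), np.asarray(b.D, float)
    if av.shape != bv.shape:
        raise ValueError("profiles have different arity")
    sq = (av - bv) ** 2
    total = sq.sum()
    if total <= _EQ_TOL**2:
        d = np.zeros_like(sq)
    else:
        d = sq / total
    return DistanceVector(pair=(a.module_id, b.module_id), d=tuple(d))


def entropy_weights(matrix: np.ndarray, indicators: tuple[str, ...] = INDICATORS) -> WeightVector:
    """Entropy weight method on a (modules x indicators) value matrix.

    p_ij = x_ij / sum_i x_ij per column; e_j = -(1/ln m) * sum_i p_ij ln p_ij
    with 0*ln 0 := 0; w_j = (1 - e_j) / sum_k (1 - e_k).  A constant
    column carries no information (e_j = 1, weight 0); if every column is
    constant the weights fall back to uniform.
    """
    x = np.asarray(matrix, float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if (x < 0).any():
        raise ValueError("entropy weights require non-negative values")
    m, n = x.shape
    e = np.ones(n)
    for j in range(n):
        col = x[:, j]
        s = col.sum()
        if s == 0 or np.allclose(col, col[0]):
            # no dispersion -> maximal entropy
            e[j] = 1.0
            continue
        p = col / s
        nz = p[p > 0]
        e[j] = -(nz * np.log(nz)).sum() / math.log(m)
    info = 1.0 - e
    if info.sum() <= 0:
        logger.info("all indicators constant; uniform weights")
        w = np.full(n, 1.0 / n)
    else:
        w = info / info.sum()
    return WeightVector(w=tuple(w), indicators=indicators, entropies=tuple(e))


def k_value(d: DistanceVector, w: WeightVector) -> float:
    """K = sqrt(sum_i w_i d_i)."""
    dv, wv = np.asarray(d.d, float), np.asarray(w.w, float)
    if dv.shape != wv.shape:
        raise ValueError("distance/weight arity mismatch")
    return math.sqrt(float(wv @ dv))


def score_mrps(
    net_a: nx.Graph,
    net_b: nx.Graph,
    part_a: ModulePartition,
    part_b: ModulePartition,
    mrps: list[MRPPair],
    orientation: dict[str, str] | None = None,
    weight_source: str = "profiles",
    min_module_nodes: int = 4,
) -> tuple[list[KScore], WeightVector, list[NormalizedProfile]]:
    """Full K pipeline for one disease-pair comparison.

    Profiles every module (>= ``min_module_nodes`` nodes) of both stages,
    min–max normalises them pooled over the comparison, derives entropy
    weights from the normalised module x indicator matrix (or, with
    ``weight_source='distances'``, from the stacked per-pair d vectors),
    and scores each MRP.  Module ids must be unique across the two
    partitions (they carry the stage prefix).
    """
    part_a = part_a.filter_min_size(min_module_nodes)
    part_b = part_b.filter_min_size(min_module_nodes)
    profiles = [module_topology(net_a, m) for m in part_a.modules]
    profiles += [module_topology(net_b, m) for m in part_b.modules]
    ids = [p.module_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("module ids must be unique across the two partitions")
    normalized = normalize_profiles(profiles, orientation)
    by_id = {p.module_id: p for p in normalized}
    kept = {p.module_id for p in normalized}
    pairs = [p for p in mrps if p.module_a in kept and p.module_b in kept]
    dvecs = [relative_distance(by_id[p.module_a], by_id[p.module_b]) for p in pairs]
    if weight_source == "profiles":
        w = entropy_weights(np.array([p.D for p in normalized]))
    elif weight_source == "distances":
        w = entropy_weights(np.array([dv.d for dv in dvecs]))
    else:
        raise ValueError(f"unknown weight_source {weight_source!r}")
    scores = [
        KScore(stage=p.stage, module_a=p.module_a, module_b=p.module_b,
               d=dv.d, K=k_value(dv, w))
        for p, dv in zip(pairs, dvecs)
    ]
    return scores, w, normalized


def write_k_table(scores: list[KScore], path) -> None:
    """TSV: stage, module_a, module_b, d1..d4, K."""
    with open(path, "w") as fh:
        fh.write("stage\tmodule_a\tmodule_b\td_nodes\td_edges\td_avg_neighbors\td_cpl\tK\n")
        for s in scores:
            d = "\t".join(f"{x:.10g}" for x in s.d)
            fh.write(f"{s.stage}\t{s.module_a}\t{s.module_b}\t{d}\t{s.K:.10g}\n")


def write_weight_table(w: WeightVector, path) -> None:
    """TSV: indicator, entropy, weight."""
    with open(path, "w") as fh:
        fh.write("indicator\tentropy\tweight\n")
        ents = w.entropies or tuple(float("nan") for _ in w.w)
        for name, e, wt in zip(w.indicators, ents, w.w):
            fh.write(f"{name}\t{e:.10g}\t{wt:.10g}\n")


def write_normalized_table(profiles: list[NormalizedProfile], path) -> None:
    """TSV: module_id, normalised indicator values."""
    with open(path, "w") as fh:
        fh.write("module_id\t" + "\t".join(INDICATORS) + "\n")
        for p in profiles:
            fh.write(p.module_id + "\t" + "\t".join(f"{x:.10g}" for x in p.D) + "\n")
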
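"""Synthetic study inputs with machine-readable ground truth.

Everything the pipeline consumes can be generated here: three gene
universes with exact three-set overlap counts, planted-partition
interaction networks whose modules are conserved, churned, split or
merged between disease stages, GMT collections with a planted common
core, and DGV-dialect structural-variant tables with exact per-gene
gain/loss counts.  All draws are fixed by the scenario seed, so outputs
are byte-identical across reruns.

Gene symbols are synthesized (G0001, ...) — no real identifiers, so no
accidental biological claims.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .enrichment import GeneSetCollection, write_gmt
from .module_detection import Module, ModulePartition, write_partition
from .mrp import MRPPair, find_mrps
from .network_io import GeneList, write_network

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "SimulatedScenario",
    "simulate_scenario",
    "simulate_gene_lists",
    "simulate_gmt",
    "simulate_dgv",
    "power_scenario_config",
    "replica_fixture",
]

_SCORE_LO, _SCORE_HI = 400, 999


@dataclass(frozen=True)
class ScenarioConfig:
    """Planted-rewiring scenario description.

    ``plan`` lists one operation per later-stage module (applied between
    consecutive stages): ``{"op": "conserve"|"split"|"merge"|"novel",
    "sources": [module indices], "ways": k, "churn": fraction,
    "size": n}``.  A nonzero ``churn`` replaces that fraction of the
    source members with fresh nodes before the operation.  Unreferenced
    source modules are dropped (their members join the background).
    """

    n_modules: int = 3
    module_size: int = 8
    p_in: float = 0.9
    p_out: float = 0.02
    plan: tuple[dict, ...] = ()
    n_stages: int = 2
    n_background: int = 10
    n_isolates: int = 0
    stage_labels: tuple[str, ...] = ("A", "B", "C")
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if self.module_size < 4:
            raise ValueError("module sizes must be >= 4")
        if self.n_stages > len(self.stage_labels):
            raise ValueError("not enough stage labels")


@dataclass
class GroundTruth:
    """What was planted: memberships, rewiring map and pair labels."""

    memberships: dict[str, dict[str, list[str]]]  # stage -> module_id -> nodes
    rewiring: list[dict]                          # per-transition op records
    pair_kinds: list[tuple[str, str, str]]        # (module_a, module_b, kind)
    progression_genes: list[str]                  # in a module at every stage
    isolates: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "memberships": self.memberships,
                "rewiring": self.rewiring,
                "pair_kinds": [list(t) for t in self.pair_kinds],
                "progression_genes": self.progression_genes,
                "isolates": self.isolates,
            },
            indent=2,
            sort_keys=True,
        )


@dataclass
class StageData:
    label: str
    graph: nx.Graph
    partition: ModulePartition
    gene_list: GeneList


@dataclass
class SimulatedScenario:
    config: ScenarioConfig
    stages: list[StageData]
    truth: GroundTruth

    def mrps(self, a: int = 0, b: int = 1) -> list[MRPPair]:
        return find_mrps(self.stages[a].partition, self.stages[b].partition)

    def write(self, outdir: str | Path) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest: dict[str, str] = {}
        for stage in self.stages:
            genes_path = outdir / f"stage_{stage.label}.genes.txt"
            genes_path.write_text("\n".join(stage.gene_list.genes) + "\n")
            edges_path = outdir / f"stage_{stage.label}.edges.tsv"
            _write_string_edges(stage.graph, edges_path)
            part_path = outdir / f"stage_{stage.label}.modules.tsv"
            write_partition(stage.partition, part_path)
            manifest[f"genes_{stage.label}"] = str(genes_path)
            manifest[f"edges_{stage.label}"] = str(edges_path)
            manifest[f"modules_{stage.label}"] = str(part_path)
        truth_path = outdir / "ground_truth.json"
        truth_path.write_text(self.truth.to_json() + "\n")
        manifest["ground_truth"] = str(truth_path)
        return manifest


def _write_string_edges(g: nx.Graph, path: Path) -> None:
    rows = []
    for u, v, data in g.edges(data=True):
        a, b = sorted((u, v))
        rows.append((a, b, int(data.get("score", _SCORE_HI))))
    rows.sort()
    with path.open("w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for a, b, s in rows:
            fh.write(f"{a}\t{b}\t{s}\n")


class _NamePool:
    def __init__(self) -> None:
        self.counter = 0

    def take(self, n: int) -> list[str]:
        names = [f"G{self.counter + i + 1:04d}" for i in range(n)]
        self.counter += n
        return names


def _sample_master_graph(
    universe: list[str],
    co_module: set[frozenset[str]],
    p_in: float,
    p_out: float,
    rng: np.random.Generator,
) -> nx.Graph:
    """One planted-partition interactome shared by every stage.

    A node pair that shares a module in at least one stage gets an edge
    with probability p_in, every other pair with p_out.  Stage networks
    are induced subgraphs of this master graph, mirroring how disease
    networks all derive from a single interactome — so a module conserved
    between stages induces an identical subgraph in both.
    """
    g = nx.Graph()
    nodes = sorted(universe)
    g.add_nodes_from(nodes)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            p = p_in if frozenset((u, v)) in co_module else p_out
            if rng.random() < p:
                g.add_edge(u, v, score=int(rng.integers(_SCORE_LO, _SCORE_HI + 1)))
    return g


def _apply_churn(
    members: list[str], fraction: float, pool: _NamePool, rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    """Replace a fraction of members with fresh nodes; returns (new, dropped)."""
    n_out = int(round(fraction * len(members)))
    if n_out == 0:
        return list(members), []
    out_idx = rng.choice(len(members), size=n_out, replace=False)
    dropped = [members[i] for i in sorted(out_idx)]
    kept = [m for i, m in enumerate(members) if i not in set(out_idx)]
    return kept + pool.take(n_out), dropped


def simulate_scenario(config: ScenarioConfig) -> SimulatedScenario:
    """Generate graphs, gene lists and planted partitions for each stage.

    Memberships for every stage are derived first by applying the
    rewiring plan; then a single master interactome is sampled (pairs
    co-moduled in any stage get an edge with probability p_in, all other
    pairs p_out) and each stage network is its induced subgraph on that
    stage's gene universe.  Modules conserved between stages therefore
    induce identical subgraphs, as they would under a shared interactome.
    """
    rng = np.random.default_rng(config.seed)
    pool = _NamePool()
    labels = config.stage_labels[: config.n_stages]

    modules: list[list[str]] = [
        pool.take(config.module_size) for _ in range(config.n_modules)
    ]
    background = pool.take(config.n_background)
    isolates_per_stage: dict[str, list[str]] = {}
    memberships: dict[str, dict[str, list[str]]] = {}
    rewiring: list[dict] = []
    pair_kinds: list[tuple[str, str, str]] = []
    stage_modules: dict[str, list[list[str]]] = {}

    # pass 1: derive memberships stage by stage
    for si, label in enumerate(labels):
        stage_modules[label] = [list(m) for m in modules]
        memberships[label] = {
            f"{label}{i + 1}": sorted(mod) for i, mod in enumerate(modules)
        }
        isolates_per_stage[label] = pool.take(config.n_isolates)

        if si == config.n_stages - 1:
            break
        next_label = labels[si + 1]
        plan = config.plan or tuple({"op": "conserve", "sources": [i]} for i in range(len(modules)))
        next_modules: list[list[str]] = []
        used: set[int] = set()
        op_records: list[dict] = []
        churned_out: list[str] = []
        for op in plan:
            kind = op["op"]
            churn = float(op.get("churn", 0.0))
            sources = list(op.get("sources", []))
            if kind == "novel":
                next_modules.append(pool.take(int(op["size"])))
                op_records.append({"op": "novel", "target": len(next_modules) - 1})
                continue
            if any(s >= len(modules) for s in sources):
                raise ValueError(f"plan references missing module: {op}")
            used.update(sources)
            if kind == "conserve":
                (src,) = sources
                members, dropped = _apply_churn(modules[src], churn, pool, rng)
                churned_out.extend(dropped)
                next_modules.append(members)
                op_records.append({"op": kind, "sources": sources, "churn": churn,
                                   "target": len(next_modules) - 1})
            elif kind == "split":
                (src,) = sources
                ways = int(op.get("ways", 2))
                members, dropped = _apply_churn(modules[src], churn, pool, rng)
                churned_out.extend(dropped)
                order = list(rng.permutation(len(members)))
                parts = [sorted(members[j] for j in order[k::ways]) for k in range(ways)]
                if any(len(p) < 1 for p in parts):
                    raise ValueError(f"split of module {src} into {ways} ways infeasible")
                for p in parts:
                    next_modules.append(p)
                op_records.append({"op": "split", "sources": sources, "ways": ways,
                                   "targets": list(range(len(next_modules) - ways,
                                                         len(next_modules)))})
            elif kind == "merge":
                if len(sources) < 2:
                    raise ValueError("merge needs >= 2 source modules")
                merged: list[str] = []
                for s in sources:
                    members, dropped = _apply_churn(modules[s], churn, pool, rng)
                    churned_out.extend(dropped)
                    merged.extend(members)
                next_modules.append(sorted(set(merged)))
                op_records.append({"op": "merge", "sources": sources, "churn": churn,
                                   "target": len(next_modules) - 1})
            else:
                raise ValueError(f"unknown plan op {kind!r}")
        # pair labels for this transition
        tgt_ids = [f"{next_label}{i + 1}" for i in range(len(next_modules))]
        for rec in op_records:
            if rec["op"] == "novel":
                continue
            if rec["op"] == "split":
                for t in rec["targets"]:
                    pair_kinds.append(
                        (f"{label}{rec['sources'][0] + 1}", tgt_ids[t], "split")
                    )
            elif rec["op"] == "merge":
                for s in rec["sources"]:
                    pair_kinds.append((f"{label}{s + 1}", tgt_ids[rec["target"]], "merged"))
            else:
                kind = "churned" if rec.get("churn", 0.0) > 0 else "conserved"
                pair_kinds.append(
                    (f"{label}{rec['sources'][0] + 1}", tgt_ids[rec["target"]], kind)
                )
        rewiring.append({"from": label, "to": next_label, "ops": op_records})
        modules = next_modules

    # pass 2: one master interactome; stage nets are induced subgraphs
    co_module: set[frozenset[str]] = set()
    for mods in stage_modules.values():
        for mod in mods:
            for i, u in enumerate(mod):
                for v in mod[i + 1:]:
                    co_module.add(frozenset((u, v)))
    universe = [f"G{i + 1:04d}" for i in range(pool.counter)]
    master = _sample_master_graph(universe, co_module, config.p_in, config.p_out, rng)

    stages: list[StageData] = []
    for label in labels:
        mods = stage_modules[label]
        stage_nodes = sorted({n for mod in mods for n in mod} | set(background))
        graph = master.subgraph(stage_nodes).copy()
        graph.graph["label"] = label
        part = ModulePartition(
            method="planted",
            modules=tuple(
                Module(module_id=f"{label}{i + 1}", nodes=frozenset(mod))
                for i, mod in enumerate(mods)
            ),
            network_label=label,
        )
        gene_list = GeneList(
            disease_label=label, genes=tuple(stage_nodes + isolates_per_stage[label])
        )
        stages.append(StageData(label=label, graph=graph, partition=part, gene_list=gene_list))

    in_every_stage = set.intersection(
        *({n for mod in memberships[lab].values() for n in mod} for lab in labels)
    )
    truth = GroundTruth(
        memberships=memberships,
        rewiring=rewiring,
        pair_kinds=pair_kinds,
        progression_genes=sorted(in_every_stage),
        isolates=isolates_per_stage,
    )
    return SimulatedScenario(config=config, stages=stages, truth=truth)


def power_scenario_config(seed: int) -> ScenarioConfig:
    """The standard planted-rewiring power scenario.

    Four modules of 10 nodes, dense within (p_in = 0.85) and sparse
    between (p_out = 0.02); between the two stages one module is
    conserved, one is split two ways, and two merge (the merge absorbing
    a 30% membership churn), so conserve/churn/split/merge are all
    represented.
    """
    return ScenarioConfig(
        n_modules=4,
        module_size=10,
        p_in=0.85,
        p_out=0.02,
        n_background=8,
        plan=(
            {"op": "conserve", "sources": [0]},
            {"op": "split", "sources": [2], "ways": 2},
            {"op": "merge", "sources": [1, 3], "churn": 0.3},
        ),
        seed=seed,
    )


def simulate_gene_lists(
    region_counts: dict[str, int],
    labels: tuple[str, str, str],
    seed: int = 0,
) -> tuple[GeneList, GeneList, GeneList]:
    """Three gene lists with exact Venn region counts.

    ``region_counts`` keys: ``a, b, c`` (exclusive), ``ab, ac, bc``
    (pair-only) and ``abc`` (triple).
    """
    rng = np.random.default_rng(seed)
    pool = _NamePool()
    regions = {k: pool.take(region_counts.get(k, 0)) for k in
               ("a", "b", "c", "ab", "ac", "bc", "abc")}
    def build(label: str, keys: tuple[str, ...]) -> GeneList:
        genes = [g for k in keys for g in regions[k]]
        order = rng.permutation(len(genes))
        return GeneList(disease_label=label, genes=tuple(genes[i] for i in order))
    return (
        build(labels[0], ("a", "ab", "ac", "abc")),
        build(labels[1], ("b", "ab", "bc", "abc")),
        build(labels[2], ("c", "ac", "bc", "abc")),
    )


def simulate_gmt(
    stage_genes: dict[str, set[str]],
    n_common_terms: int = 6,
    n_specific_terms: int = 4,
    term_size: int = 8,
    seed: int = 0,
) -> tuple[GeneSetCollection, dict[str, set[str]]]:
    """GMT collection with a planted common core of terms.

    Common terms draw genes shared by all stages; stage-specific terms
    draw from one stage only.  Returns the collection and the planted
    term membership per stage (which stage's gene sets should enrich
    which terms).
    """
    rng = np.random.default_rng(seed)
    shared = sorted(set.intersection(*stage_genes.values()))
    sets: dict[str, frozenset[str]] = {}
    planted: dict[str, set[str]] = {s: set() for s in stage_genes}
    for t in range(n_common_terms):
        size = min(term_size, len(shared))
        picks = rng.choice(shared, size=size, replace=False) if size else []
        term = f"COMMON_{t + 1:02d}"
        sets[term] = frozenset(picks)
        for s in planted:
            planted[s].add(term)
    for stage, genes in stage_genes.items():
        only = sorted(set(genes) - set(shared))
        for t in range(n_specific_terms):
            if not only:
                break
            size = min(term_size, len(only))
            picks = rng.choice(only, size=size, replace=False)
            term = f"{stage}_ONLY_{t + 1:02d}"
            sets[term] = frozenset(picks)
            planted[stage].add(term)
    return GeneSetCollection(name="synthetic", sets=sets), planted


def simulate_dgv(
    design: dict[str, dict[str, int]],
    seed: int = 0,
    n_decoys: int = 3,
    path: str | Path | None = None,
):
    """DGV-dialect variant records with exact per-gene subtype counts.

    ``design`` maps gene -> {subtype: count}.  Decoy rows carry excluded
    subtypes or missing fields to exercise the reader's filter.  Returns
    the rows as a list of dicts; writes a TSV when ``path`` is given.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    acc = 0
    for gene in sorted(design):
        for subtype in sorted(design[gene]):
            if design[gene][subtype] < 0:
                raise ValueError("counts must be non-negative")
            for _ in range(design[gene][subtype]):
                acc += 1
                start = int(rng.integers(1_000_000, 200_000_000))
                rows.append(
                    {
                        "variantaccession": f"nssv{acc:07d}",
                        "chr": str(int(rng.integers(1, 23))),
                        "start": start,
                        "end": start + int(rng.integers(1_000, 1_000_000)),
                        "variantsubtype": subtype,
                        "genes": gene,
                    }
                )
    for i in range(n_decoys):
        acc += 1
        start = int(rng.integers(1_000_000, 200_000_000))
        rows.append(
            {
                "variantaccession": f"nssv{acc:07d}",
                "chr": str(int(rng.integers(1, 23))),
                "start": start,
                "end": start + 5_000,
                "variantsubtype": "duplication" if i % 2 == 0 else "loss",
                "genes": "" if i % 2 else "DECOY",
            }
        )
    # the i%2==0 decoys carry an excluded subtype; odd ones an empty gene field
    if path is not None:
        import pandas as pd

        pd.DataFrame(
            rows,
            columns=["variantaccession", "chr", "start", "end", "variantsubtype", "genes"],
        ).to_csv(path, sep="\t", index=False)
    return rows


# ---------------------------------------------------------------------------
# replica fixture: the in-text worked numbers, on synthetic symbols
# ---------------------------------------------------------------------------

# three-disease gene-list overlap design: totals 288/417/670 with a 56-gene
# triple overlap and 24/54/103 pair-only overlaps
REPLICA_VENN_REGIONS = {
    "a": 154, "b": 234, "c": 457, "ab": 24, "ac": 54, "bc": 103, "abc": 56,
}

# progression-group SV design: 10 genes, 8 carrying SVs, 17 loss + 10 gain
# overall; the four PROG_ANGIO genes carry 13 loss + 4 gain
REPLICA_SV_PROGRESSION = {
    "PROG01": {"loss": 4, "gain": 1},
    "PROG02": {"loss": 3, "gain": 1},
    "PROG03": {"loss": 3, "gain": 1},
    "PROG04": {"loss": 3, "gain": 1},
    "PROG05": {"loss": 2, "gain": 2},
    "PROG06": {"loss": 1, "gain": 2},
    "PROG07": {"loss": 1, "gain": 1},
    "PROG08": {"gain": 1},
    "PROG09": {},
    "PROG10": {},
}
REPLICA_ANGIO_GENES = ("PROG01", "PROG02", "PROG03", "PROG04")

# earlier-transition group: 11 genes with SVs, 14 gain + 12 loss (53.85% gain)
REPLICA_SV_EARLY = {
    f"EARLY{i:02d}": {"gain": g, "loss": l}
    for i, (g, l) in enumerate(
        [(2, 2), (2, 1), (2, 1), (1, 1), (1, 1), (1, 1), (1, 1), (1, 1), (1, 1), (1, 1), (1, 1)],
        start=1,
    )
}

# later-transition group: 3 genes, loss only
REPLICA_SV_LATE = {"LATE01": {"loss": 2}, "LATE02": {"loss": 2}, "LATE03": {"loss": 1}}


def _toy_k_bundle():
    """A 12-node two-partition comparison for exercising the K pipeline."""
    g = nx.Graph(label="toy")
    k4 = ["T01", "T02", "T03", "T04"]
    for i, u in enumerate(k4):
        for v in k4[i + 1:]:
            g.add_edge(u, v)
    path = ["T05", "T06", "T07", "T08"]
    for u, v in zip(path, path[1:]):
        g.add_edge(u, v)
    square = ["T09", "T10", "T11", "T12"]
    for u, v in zip(square, square[1:] + square[:1]):
        g.add_edge(u, v)
    g.add_edge("T01", "T05")
    g.add_edge("T05", "T09")
    part_a = ModulePartition(
        method="planted",
        modules=(
            Module("X1", frozenset(k4)),
            Module("X2", frozenset(square)),
        ),
        network_label="X",
    )
    part_b = ModulePartition(
        method="planted",
        modules=(
            Module("Y1", frozenset(["T01", "T05", "T06", "T07", "T08"])),
            Module("Y2", frozenset(["T09", "T10", "T11", "T12", "T04"])),
        ),
        network_label="Y",
    )
    return g, part_a, part_b


@dataclass
class ReplicaFixture:
    gene_lists: tuple[GeneList, GeneList, GeneList]
    sv_rows: list[dict]
    sv_groups: dict[str, tuple[str, ...]]
    toy_graph: nx.Graph
    toy_part_a: ModulePartition
    toy_part_b: ModulePartition


def replica_fixture(outdir: str | Path | None = None, seed: int = 0) -> ReplicaFixture:
    """Package the in-text worked numbers as a small synthetic fixture.

    Bundles: three gene lists realising the 288/417/670 totals with the
    56/24/54/103 overlap structure; one structural-variant table whose
    gene groups realise the 17:10, 13:4 and 14:12 loss/gain tallies; and
    the 12-node two-partition comparison used as a K-pipeline oracle
    fixture.  All symbols are synthetic.
    """
    lists = simulate_gene_lists(REPLICA_VENN_REGIONS, ("ICM", "SAP", "CHF"), seed=seed)
    design: dict[str, dict[str, int]] = {}
    for d in (REPLICA_SV_PROGRESSION, REPLICA_SV_EARLY, REPLICA_SV_LATE):
        for gene, counts in d.items():
            design[gene] = dict(counts)
    rows = simulate_dgv(design, seed=seed, n_decoys=4)
    groups = {
        "progression": tuple(sorted(REPLICA_SV_PROGRESSION)),
        "angiogenesis": REPLICA_ANGIO_GENES,
        "early_transition": tuple(sorted(REPLICA_SV_EARLY)),
        "late_transition": tuple(sorted(REPLICA_SV_LATE)),
    }
    toy_graph, part_a, part_b = _toy_k_bundle()
    fixture = ReplicaFixture(
        gene_lists=lists,
        sv_rows=rows,
        sv_groups=groups,
        toy_graph=toy_graph,
        toy_part_a=part_a,
        toy_part_b=part_b,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for gl in lists:
            (outdir / f"{gl.disease_label.lower()}_genes.txt").write_text(
                "\n".join(gl.genes) + "\n"
            )
        import pandas as pd

        pd.DataFrame(
            rows,
            columns=["variantaccession", "chr", "start", "end", "variantsubtype", "genes"],
        ).to_csv(outdir / "variants.dgv.tsv", sep="\t", index=False)
        (outdir / "sv_groups.json").write_text(
            json.dumps({k: list(v) for k, v in groups.items()}, indent=2) + "\n"
        )
        write_network(toy_graph, outdir / "toy_network.tsv")
        write_partition(part_a, outdir / "toy_partition_x.tsv")
        write_partition(part_b, outdir / "toy_partition_y.tsv")
    return fixture
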
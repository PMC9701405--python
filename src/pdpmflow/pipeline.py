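"""End-to-end orchestration: networks -> modules -> MRPs -> K -> PDPMs.

A single run configuration (YAML or an in-memory dict) names the
per-stage gene lists, the interactome edge list(s), the stage order and
the model options; ``run_all`` executes the stages in order and writes a
reproducible report bundle (tables for every intermediate, a JSON stage
report and a run manifest).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import yaml

from . import __version__
from .enrichment import ora, overlap_terms, read_gmt, write_enrichment_table
from .kvalue import (
    KScore,
    score_mrps,
    write_k_table,
    write_normalized_table,
    write_weight_table,
)
from .module_detection import (
    MCODEParams,
    ModulePartition,
    partition_entropy,
    select_partition,
    write_partition,
)
from .mrp import find_mrps, write_mrp_table
from .network_io import (
    build_disease_network,
    network_stats,
    read_edge_list,
    read_gene_list,
    venn_counts,
    write_network,
)
from .selection import (
    GOLDEN_CUTOFF,
    select_pdpms,
    stage_report,
    write_pdpm_table,
    write_stage_report,
)
from .sv_analysis import gain_loss_summary, match_genes, read_dgv, write_sv_summary

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    stages: list[str]                      # ordered disease labels, earliest first
    gene_lists: dict[str, str]             # label -> gene list path
    edge_list: str | dict[str, str] = ""   # one interactome or one per stage
    output_dir: str = "pdpm_run"
    min_score: float | None = None
    gene_column: str | None = None
    clustering: MCODEParams = field(default_factory=MCODEParams)
    orientation: dict[str, str] = field(default_factory=dict)
    weight_source: str = "profiles"
    cutoff_percent: float = GOLDEN_CUTOFF
    pooling: str = "global"
    gmt: str | None = None
    dgv: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        clustering = MCODEParams(**raw.pop("clustering", {}))
        return cls(clustering=clustering, **raw)

    def edge_path(self, stage: str) -> str:
        if isinstance(self.edge_list, dict):
            return self.edge_list[stage]
        return self.edge_list


def run_all(config: RunConfig) -> dict:
    """Execute every stage of the analysis and write the report bundle.

    Returns the run manifest (paths of every artifact plus headline
    numbers).  Determinism: the analysis itself is deterministic; the
    seed is recorded for any stochastic extension.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "artifacts": {}}

    if len(config.stages) < 2:
        raise ValueError("need at least 2 stages")

    # stage networks and partitions
    nets: dict[str, nx.Graph] = {}
    parts: dict[str, ModulePartition] = {}
    stats: dict[str, dict] = {}
    entropy_tables: dict[str, list] = {}
    gene_lists = {}
    for label in config.stages:
        gl = read_gene_list(config.gene_lists[label], label, gene_column=config.gene_column)
        gene_lists[label] = gl
        interactome = read_edge_list(config.edge_path(label), min_score=config.min_score)
        net = build_disease_network(interactome, gl)
        nets[label] = net
        stats[label] = network_stats(net).__dict__
        method, part, etable = select_partition(net, config.clustering, label=label)
        parts[label] = part
        entropy_tables[label] = [
            {"method": e.method, "entropy": e.entropy} for e in etable
        ]
        net_path = outdir / f"network_{label}.tsv"
        write_network(net, net_path)
        part_path = outdir / f"modules_{label}.tsv"
        write_partition(part, part_path)
        manifest["artifacts"][f"network_{label}"] = str(net_path)
        manifest["artifacts"][f"modules_{label}"] = str(part_path)
        manifest.setdefault("methods", {})[label] = method

    if len(config.stages) == 3:
        a, b, c = (gene_lists[s] for s in config.stages)
        vc = venn_counts(a, b, c)
        manifest["venn"] = {
            "triple": vc.abc,
            "pair_only": {k: v - vc.abc for k, v in vc.pair_totals.items()},
            "triple_fraction": vc.triple_fraction(),
        }

    (outdir / "network_stats.json").write_text(json.dumps(stats, indent=2, sort_keys=True))
    (outdir / "entropy.json").write_text(json.dumps(entropy_tables, indent=2, sort_keys=True))
    manifest["artifacts"]["network_stats"] = str(outdir / "network_stats.json")
    manifest["artifacts"]["entropy"] = str(outdir / "entropy.json")

    # pairwise comparisons along (and across) the stage order
    comparisons = [
        (a, b)
        for i, a in enumerate(config.stages)
        for b in config.stages[i + 1:]
    ]
    all_scores: list[KScore] = []
    all_mrps = []
    module_nodes: dict[str, frozenset[str]] = {}
    for a, b in comparisons:
        stage = f"{a}-{b}"
        mrps = find_mrps(parts[a], parts[b], stage=stage)
        all_mrps.extend(mrps)
        scores, weights, normalized = score_mrps(
            nets[a], nets[b], parts[a], parts[b], mrps,
            orientation=config.orientation,
            weight_source=config.weight_source,
            min_module_nodes=config.clustering.min_module_nodes,
        )
        all_scores.extend(scores)
        write_weight_table(weights, outdir / f"weights_{stage}.tsv")
        write_normalized_table(normalized, outdir / f"normalized_{stage}.tsv")
        write_k_table(scores, outdir / f"kvalues_{stage}.tsv")
        manifest["artifacts"][f"weights_{stage}"] = str(outdir / f"weights_{stage}.tsv")
        manifest["artifacts"][f"kvalues_{stage}"] = str(outdir / f"kvalues_{stage}.tsv")
        for part in (parts[a], parts[b]):
            for mod in part.modules:
                module_nodes[mod.module_id] = mod.nodes
    write_mrp_table(all_mrps, outdir / "mrps.tsv")
    manifest["artifacts"]["mrps"] = str(outdir / "mrps.tsv")

    pdpms = select_pdpms(all_scores, cutoff_percent=config.cutoff_percent,
                         pooling=config.pooling)
    write_pdpm_table(pdpms, outdir / "pdpms.tsv")
    report = stage_report(pdpms, module_nodes)
    write_stage_report(report, outdir / "stage_report.json")
    manifest["artifacts"]["pdpms"] = str(outdir / "pdpms.tsv")
    manifest["artifacts"]["stage_report"] = str(outdir / "stage_report.json")
    manifest["n_mrps"] = len(all_mrps)
    manifest["n_pdpms"] = len(pdpms.selected)
    manifest["implied_k_threshold"] = pdpms.implied_k_threshold

    # optional enrichment of PDPM gene sets
    if config.gmt:
        collection = read_gmt(config.gmt)
        per_stage_terms: dict[str, set[str]] = {}
        for stage in pdpms.stages():
            genes: set[str] = set()
            for p in pdpms.selected:
                if p.score.stage == stage:
                    genes |= module_nodes.get(p.score.module_a, frozenset())
                    genes |= module_nodes.get(p.score.module_b, frozenset())
            if not genes:
                continue
            rows = ora(genes, collection)
            write_enrichment_table(rows, outdir / f"enrichment_{stage}.tsv")
            manifest["artifacts"][f"enrichment_{stage}"] = str(
                outdir / f"enrichment_{stage}.tsv"
            )
            per_stage_terms[stage] = {r.term for r in rows if r.passes}
        if len(per_stage_terms) >= 2:
            manifest["enriched_term_overlap"] = overlap_terms(per_stage_terms)

    # optional structural-variant summary on PDPM shared genes
    if config.dgv:
        records = read_dgv(config.dgv)
        shared = set(report.get("shared_genes", []))
        summaries = []
        if shared:
            matched = match_genes(records, shared)
            if any(matched.values()):
                summaries.append(gain_loss_summary(matched, "shared"))
        for stage, genes in report.get("stage_specific_genes", {}).items():
            matched = match_genes(records, set(genes))
            if any(matched.values()):
                summaries.append(gain_loss_summary(matched, stage))
        if summaries:
            write_sv_summary(summaries, outdir / "sv_summary.tsv")
            manifest["artifacts"]["sv_summary"] = str(outdir / "sv_summary.tsv")
            manifest["sv"] = {
                s.group: {k: round(v, 2) for k, v in s.percents.items()} for s in summaries
            }

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
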
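"""Module reconstruction pairs (MRPs) and split/merge rewiring calls.

An MRP is a pair of modules, one from each of two disease-stage
partitions, sharing at least one node.  Rewiring between stages is read
off the bipartite overlap structure: an earlier module overlapping
several later modules has split; a later module fed by several earlier
modules has merged; one-to-one partners are conserved; unmatched modules
are lost (earlier) or novel (later).
"""

from __future__ import annotations

from dataclasses import dataclass

from .module_detection import ModulePartition

__all__ = ["MRPPair", "RewiringAnnotation", "find_mrps", "classify_rewiring", "write_mrp_table"]


@dataclass(frozen=True)
class MRPPair:
    stage: str
    module_a: str
    module_b: str
    nodes_a: frozenset[str]
    nodes_b: frozenset[str]
    overlap: frozenset[str]

    def __post_init__(self) -> None:
        if not self.overlap:
            raise ValueError("MRP requires at least one overlapping node")
        if not self.overlap <= (self.nodes_a & self.nodes_b):
            raise ValueError("overlap must be contained in both modules")

    @property
    def jaccard(self) -> float:
        return len(self.overlap) / len(self.nodes_a | self.nodes_b)


@dataclass(frozen=True)
class RewiringAnnotation:
    module_id: str
    kind: str  # split | merge | conserved | novel | lost
    partners: tuple[str, ...]


def find_mrps(
    part_a: ModulePartition, part_b: ModulePartition, stage: str = ""
) -> list[MRPPair]:
    """All module pairs across two partitions sharing >= 1 node.

    Ordered by (module_a id, module_b id); content is symmetric under
    argument swap up to orientation.
    """
    if not part_a.modules or not part_b.modules:
        raise ValueError("both partitions must be non-empty")
    stage = stage or f"{part_a.network_label}-{part_b.network_label}"
    pairs: list[MRPPair] = []
    for ma in sorted(part_a.modules, key=lambda m: m.module_id):
        for mb in sorted(part_b.modules, key=lambda m: m.module_id):
            shared = ma.nodes & mb.nodes
            if shared:
                pairs.append(
                    MRPPair(
                        stage=stage,
                        module_a=ma.module_id,
                        module_b=mb.module_id,
                        nodes_a=ma.nodes,
                        nodes_b=mb.nodes,
                        overlap=frozenset(shared),
                    )
                )
    return pairs


def classify_rewiring(
    part_a: ModulePartition, part_b: ModulePartition
) -> list[RewiringAnnotation]:
    """Split/merge/conserved/novel/lost calls from pairwise node overlap."""
    partners_a: dict[str, list[str]] = {m.module_id: [] for m in part_a.modules}
    partners_b: dict[str, list[str]] = {m.module_id: [] for m in part_b.modules}
    for ma in part_a.modules:
        for mb in part_b.modules:
            if ma.nodes & mb.nodes:
                partners_a[ma.module_id].append(mb.module_id)
                partners_b[mb.module_id].append(ma.module_id)
    out: list[RewiringAnnotation] = []
    for mid in sorted(partners_a):
        ps = sorted(partners_a[mid])
        if not ps:
            out.append(RewiringAnnotation(mid, "lost", ()))
        elif len(ps) >= 2:
            out.append(RewiringAnnotation(mid, "split", tuple(ps)))
        elif len(partners_b[ps[0]]) == 1:
            # one partner each way: the module persists
            out.append(RewiringAnnotation(mid, "conserved", tuple(ps)))
        # else: sole partner is a merge target; reported on the later-stage
        # module's "merge" annotation, whose partners list includes this one
    for mid in sorted(partners_b):
        ps = sorted(partners_b[mid])
        if not ps:
            out.append(RewiringAnnotation(mid, "novel", ()))
        elif len(ps) >= 2:
            out.append(RewiringAnnotation(mid, "merge", tuple(ps)))
    return out


def write_mrp_table(pairs: list[MRPPair], path) -> None:
    """TSV: stage, module_a, module_b, n_overlap, overlap genes."""
    with open(path, "w") as fh:
        fh.write("stage\tmodule_a\tmodule_b\tn_overlap\toverlap_genes\n")
        for p in pairs:
            genes = ",".join(sorted(p.overlap))
            fh.write(f"{p.stage}\t{p.module_a}\t{p.module_b}\t{len(p.overlap)}\t{genes}\n")
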
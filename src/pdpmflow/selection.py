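"""Golden-section selection of paired disease progression modules (PDPMs).

Raw K scores of all module reconstruction pairs are min–max normalised to
a 0–100% scale (pooled globally across stage comparisons by default, so
one raw-K threshold applies everywhere); pairs strictly above the golden
section of the range (61.8%) are called PDPMs — these are the pairs whose
structure changed most between stages.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from .kvalue import KScore

logger = logging.getLogger(__name__)

__all__ = ["GOLDEN_CUTOFF", "ScoredPair", "PDPMSet", "normalize_k", "select_pdpms", "stage_report"]

GOLDEN_CUTOFF = 61.8


@dataclass(frozen=True)
class ScoredPair:
    score: KScore
    k_percent: float
    is_pdpm: bool


@dataclass(frozen=True)
class PDPMSet:
    pairs: tuple[ScoredPair, ...]
    cutoff_percent: float
    implied_k_threshold: float  # largest raw K among non-selected pairs
    pooling: str = "global"

    @property
    def selected(self) -> tuple[ScoredPair, ...]:
        return tuple(p for p in self.pairs if p.is_pdpm)

    def stages(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pairs:
            seen.setdefault(p.score.stage)
        return list(seen)


def normalize_k(
    scores: list[KScore], pooling: str = "global"
) -> list[tuple[KScore, float]]:
    """Min–max rescale K to [0, 100] (percent of the pooled K range).

    ``pooling='global'`` rescales over all supplied scores at once;
    ``'per-stage'`` rescales within each stage comparison separately.
    A degenerate (all-equal) K distribution has no range to divide.
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 scores")

    def _norm(group: list[KScore]) -> list[tuple[KScore, float]]:
        ks = [s.K for s in group]
        kmin, kmax = min(ks), max(ks)
        if kmax == kmin:
            raise ValueError("degenerate K distribution (all values equal)")
        return [(s, (s.K - kmin) / (kmax - kmin) * 100.0) for s in group]

    if pooling == "global":
        return _norm(scores)
    if pooling == "per-stage":
        out: list[tuple[KScore, float]] = []
        stages: dict[str, list[KScore]] = {}
        for s in scores:
            stages.setdefault(s.stage, []).append(s)
        for group in stages.values():
            out.extend(_norm(group))
        order = {id(s): i for i, s in enumerate(scores)}
        out.sort(key=lambda t: order[id(t[0])])
        return out
    raise ValueError(f"unknown pooling {pooling!r}")


def select_pdpms(
    scores: list[KScore],
    cutoff_percent: float = GOLDEN_CUTOFF,
    pooling: str = "global",
) -> PDPMSet:
    """Call PDPMs: pairs with normalised K strictly above the cutoff.

    The implied raw-K boundary reported is the largest K among
    non-selected pairs (the "K > boundary" form); the smallest selected K
    appears in the stage report.
    """
    normed = normalize_k(scores, pooling=pooling)
    pairs = tuple(
        ScoredPair(score=s, k_percent=kp, is_pdpm=kp > cutoff_percent)
        for s, kp in normed
    )
    non_selected = [p.score.K for p in pairs if not p.is_pdpm]
    boundary = max(non_selected) if non_selected else float("nan")
    n_sel = sum(p.is_pdpm for p in pairs)
    if n_sel == 0:
        logger.warning("no PDPMs selected at cutoff %.1f%%", cutoff_percent)
    return PDPMSet(
        pairs=pairs,
        cutoff_percent=cutoff_percent,
        implied_k_threshold=boundary,
        pooling=pooling,
    )


def stage_report(
    pdpms: PDPMSet,
    module_nodes: dict[str, frozenset[str]] | None = None,
) -> dict:
    """Per-stage summary of a PDPM selection.

    Reports, per stage comparison: MRP and PDPM counts, mean K over PDPMs
    and over all MRPs, and the maximum-K pair.  With ``module_nodes``
    (module id -> node set) it also builds the overlap-gene roster: genes
    appearing in PDPM overlaps of every stage versus stage-specific ones.
    """
    report: dict = {
        "cutoff_percent": pdpms.cutoff_percent,
        "pooling": pdpms.pooling,
        "implied_k_threshold": pdpms.implied_k_threshold,
        "n_pairs": len(pdpms.pairs),
        "n_pdpms": len(pdpms.selected),
        "stages": {},
    }
    stage_genes: dict[str, set[str]] = {}
    for stage in pdpms.stages():
        in_stage = [p for p in pdpms.pairs if p.score.stage == stage]
        sel = [p for p in in_stage if p.is_pdpm]
        entry = {
            "n_mrps": len(in_stage),
            "n_pdpms": len(sel),
            "mean_k_all": sum(p.score.K for p in in_stage) / len(in_stage),
            "mean_k_pdpm": (sum(p.score.K for p in sel) / len(sel)) if sel else None,
            "min_k_pdpm": min((p.score.K for p in sel), default=None),
        }
        if in_stage:
            top = max(in_stage, key=lambda p: p.score.K)
            entry["max_k_pair"] = f"{top.score.module_a}-{top.score.module_b}"
        report["stages"][stage] = entry
        if module_nodes is not None:
            genes: set[str] = set()
            for p in sel:
                na = module_nodes.get(p.score.module_a, frozenset())
                nb = module_nodes.get(p.score.module_b, frozenset())
                genes |= na & nb
            stage_genes[stage] = genes
    if module_nodes is not None and stage_genes:
        shared = set.intersection(*stage_genes.values()) if stage_genes else set()
        report["shared_genes"] = sorted(shared)
        report["stage_specific_genes"] = {
            stage: sorted(g - shared) for stage, g in stage_genes.items()
        }
    # stages ordered by PDPM mean K ascending = closest disease pair first
    ranked = sorted(
        (s for s, e in report["stages"].items() if e["mean_k_pdpm"] is not None),
        key=lambda s: report["stages"][s]["mean_k_pdpm"],
    )
    report["stage_closeness_order"] = ranked
    return report


def write_pdpm_table(pdpms: PDPMSet, path) -> None:
    """TSV: stage, module_a, module_b, K, k_percent, is_pdpm."""
    with open(path, "w") as fh:
        fh.write("stage\tmodule_a\tmodule_b\tK\tk_percent\tis_pdpm\n")
        for p in pdpms.pairs:
            s = p.score
            fh.write(
                f"{s.stage}\t{s.module_a}\t{s.module_b}\t{s.K:.10g}\t"
                f"{p.k_percent:.6f}\t{str(p.is_pdpm).lower()}\n"
            )


def write_stage_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
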
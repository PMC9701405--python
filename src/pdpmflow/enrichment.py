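"""Hypergeometric over-representation analysis against GMT collections.

Mirrors the common web-service defaults for pathway enrichment of module
gene sets: a term passes when it overlaps the query by at least 3 genes,
its upper-tail hypergeometric p-value is below 0.01 and its fold
enrichment is at least 1.5.  No multiple-testing correction is applied by
default (a Benjamini–Hochberg option exists).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

from scipy.stats import false_discovery_control, hypergeom

logger = logging.getLogger(__name__)

__all__ = ["GeneSetCollection", "EnrichmentRow", "read_gmt", "write_gmt", "ora", "overlap_terms"]


@dataclass(frozen=True)
class GeneSetCollection:
    name: str
    sets: dict[str, frozenset[str]]
    source: str = ""

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return frozenset(out)


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    overlap_count: int
    term_size: int
    p_value: float
    fold_enrichment: float
    passes: bool
    q_value: float | None = None
    genes: tuple[str, ...] = ()


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (term TAB description TAB gene...)."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs term, description, >=1 gene")
        term = parts[0].strip()
        if term in sets:
            raise ValueError(f"{path}:{lineno}: duplicate term {term!r}")
        genes = frozenset(g.strip().upper() for g in parts[2:] if g.strip())
        if not genes:
            raise ValueError(f"{path}:{lineno}: term {term!r} has no genes")
        sets[term] = genes
    return GeneSetCollection(name=path.stem, sets=sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for term in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[term]))
            fh.write(f"{term}\tna\t{genes}\n")


def ora(
    query: set[str],
    collection: GeneSetCollection,
    background: set[str] | None = None,
    min_overlap: int = 3,
    p_cutoff: float = 0.01,
    min_enrichment: float = 1.5,
    fdr: bool = False,
) -> list[EnrichmentRow]:
    """Over-representation of a query gene set in each collection term.

    p is the upper-tail hypergeometric probability of drawing at least k
    term genes in |query| draws without replacement from the background;
    fold enrichment is (k/|query|) / (|term ∩ background|/|background|).
    Background defaults to the union of all collection genes; query genes
    outside the background are dropped with a warning.
    """
    if not query:
        raise ValueError("empty query gene set")
    query = {g.upper() for g in query}
    bg = frozenset(g.upper() for g in background) if background else collection.all_genes()
    outside = query - bg
    if outside:
        logger.warning("%d query genes outside background dropped", len(outside))
        query = query & bg
        if not query:
            raise ValueError("no query genes in background")
    n_bg, n_q = len(bg), len(query)
    rows: list[EnrichmentRow] = []
    for term, genes in collection.sets.items():
        term_bg = genes & bg
        hit = query & term_bg
        k, n_term = len(hit), len(term_bg)
        if n_term == 0:
            continue
        p = float(hypergeom.sf(k - 1, n_bg, n_term, n_q))
        fold = (k / n_q) / (n_term / n_bg) if k else 0.0
        rows.append(
            EnrichmentRow(
                term=term,
                overlap_count=k,
                term_size=n_term,
                p_value=p,
                fold_enrichment=fold,
                passes=(k >= min_overlap and p < p_cutoff and fold >= min_enrichment),
                genes=tuple(sorted(hit)),
            )
        )
    rows.sort(key=lambda r: (r.p_value, r.term))
    if fdr and rows:
        qvals = false_discovery_control([r.p_value for r in rows])
        rows = [
            EnrichmentRow(
                term=r.term, overlap_count=r.overlap_count, term_size=r.term_size,
                p_value=r.p_value, fold_enrichment=r.fold_enrichment,
                passes=r.passes, q_value=float(q), genes=r.genes,
            )
            for r, q in zip(rows, qvals)
        ]
    return rows


def overlap_terms(per_stage: dict[str, set[str]]) -> dict[str, int]:
    """Venn-style counts of passing terms across stage comparisons.

    Returns exclusive-region counts keyed by '&'-joined stage combination
    (e.g. 'SAP-ICM&ICM-CHF'), the analogue of the pathway-overlap Venn
    panels for PDPMs.
    """
    if len(per_stage) < 2:
        raise ValueError("need at least 2 stages")
    stages = list(per_stage)
    counts: dict[str, int] = {}
    for r in range(1, len(stages) + 1):
        for combo in combinations(stages, r):
            inside = set.intersection(*(per_stage[s] for s in combo))
            outside: set[str] = set()
            for s in stages:
                if s not in combo:
                    outside |= per_stage[s]
            counts["&".join(combo)] = len(inside - outside)
    return counts


def write_enrichment_table(rows: list[EnrichmentRow], path) -> None:
    """TSV: term, k, term_size, p, fold, passes."""
    with open(path, "w") as fh:
        fh.write("term\toverlap\tterm_size\tp_value\tfold_enrichment\tpasses\n")
        for r in rows:
            fh.write(
                f"{r.term}\t{r.overlap_count}\t{r.term_size}\t{r.p_value:.6g}\t"
                f"{r.fold_enrichment:.4f}\t{str(r.passes).lower()}\n"
            )
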
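"""Structural-variant (DGV-dialect) parsing and gain/loss summaries.

Reads tab-separated structural-variant tables in the Database of Genomic
Variants export dialect (GRCh37 coordinates, one record per accession,
comma-separated gene annotations), keeps the subtypes of interest
(complex, inversion, loss, gain; "gain" = duplication of the encoded
protein, "loss" = deletion), matches records to a query gene set and
summarises gain/loss proportions per gene group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ALLOWED_SUBTYPES",
    "SVRecord",
    "SVSummary",
    "read_dgv",
    "write_dgv",
    "match_genes",
    "gain_loss_summary",
]

ALLOWED_SUBTYPES = frozenset({"complex", "inversion", "loss", "gain"})

_REQUIRED = ("variantaccession", "chr", "start", "end", "variantsubtype", "genes")


@dataclass(frozen=True)
class SVRecord:
    accession: str
    chromosome: str
    start: int
    end: int
    variant_subtype: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.accession}: start > end")


@dataclass(frozen=True)
class SVSummary:
    group: str
    counts: dict[str, int]          # per subtype, accession-deduplicated
    percents: dict[str, float]
    per_gene: dict[str, dict[str, int]]
    n_records: int
    n_genes_hit: int


def read_dgv(path: str | Path) -> list[SVRecord]:
    """Parse a DGV-dialect TSV, keeping only well-formed allowed subtypes.

    Rows with a subtype outside {complex, inversion, loss, gain}, or with
    empty/unknown accession, coordinates or gene annotations, are dropped
    (count logged).  Gene annotations split on commas and upper-case.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    records: list[SVRecord] = []
    n_dropped = 0
    for row in df.itertuples(index=False):
        subtype = getattr(row, "variantsubtype").strip().lower()
        acc = getattr(row, "variantaccession").strip()
        genes_raw = getattr(row, "genes").strip()
        start_raw, end_raw = getattr(row, "start").strip(), getattr(row, "end").strip()
        if (
            subtype not in ALLOWED_SUBTYPES
            or not acc
            or not genes_raw
            or genes_raw.lower() in {"unknown", "na", "nan"}
            or not start_raw.isdigit()
            or not end_raw.isdigit()
        ):
            n_dropped += 1
            continue
        genes = frozenset(g.strip().upper() for g in genes_raw.split(",") if g.strip())
        records.append(
            SVRecord(
                accession=acc,
                chromosome=getattr(row, "chr").strip(),
                start=int(start_raw),
                end=int(end_raw),
                variant_subtype=subtype,
                genes=genes,
            )
        )
    if n_dropped:
        logger.info("%s: dropped %d rows (excluded subtype or missing fields)", path, n_dropped)
    return records


def write_dgv(records: list[SVRecord], path: str | Path) -> None:
    """Write records back in the same dialect (round-trips with read_dgv)."""
    rows = [
        {
            "variantaccession": r.accession,
            "chr": r.chromosome,
            "start": r.start,
            "end": r.end,
            "variantsubtype": r.variant_subtype,
            "genes": ",".join(sorted(r.genes)),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(_REQUIRED)).to_csv(path, sep="\t", index=False)


def match_genes(records: list[SVRecord], genes: set[str]) -> dict[str, list[SVRecord]]:
    """Attach each record to every query gene it annotates.

    Records hitting no query gene are excluded; a record spanning several
    query genes appears under each of them.
    """
    query = {g.upper() for g in genes}
    out: dict[str, list[SVRecord]] = {}
    for rec in records:
        for g in rec.genes & query:
            out.setdefault(g, []).append(rec)
    return out


def gain_loss_summary(matched: dict[str, list[SVRecord]], group: str) -> SVSummary:
    """Subtype counts and percentages for a gene group.

    Counts deduplicate by accession across the whole group, so an SV
    spanning several query genes is counted once (per-gene tallies, which
    do double-count such SVs, are reported alongside).  Percentages are
    over the retained subtypes and sum to 100.
    """
    by_acc: dict[str, SVRecord] = {}
    for recs in matched.values():
        for r in recs:
            by_acc[r.accession] = r
    if not by_acc:
        raise ValueError(f"{group}: no matched structural variants")
    counts: dict[str, int] = {}
    for r in by_acc.values():
        counts[r.variant_subtype] = counts.get(r.variant_subtype, 0) + 1
    total = sum(counts.values())
    percents = {st: 100.0 * n / total for st, n in counts.items()}
    per_gene: dict[str, dict[str, int]] = {}
    for g, recs in sorted(matched.items()):
        uniq = list({r.accession: r for r in recs}.values())
        per_gene[g] = {
            st: sum(1 for r in uniq if r.variant_subtype == st)
            for st in sorted({r.variant_subtype for r in uniq})
        }
    return SVSummary(
        group=group,
        counts=counts,
        percents=percents,
        per_gene=per_gene,
        n_records=total,
        n_genes_hit=sum(1 for recs in matched.values() if recs),
    )


def write_sv_summary(summaries: list[SVSummary], path) -> None:
    """TSV: group, subtype, count, percent."""
    with open(path, "w") as fh:
        fh.write("group\tsubtype\tcount\tpercent\n")
        for s in summaries:
            for st in sorted(s.counts):
                fh.write(f"{s.group}\t{st}\t{s.counts[st]}\t{s.percents[st]:.2f}\n")
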
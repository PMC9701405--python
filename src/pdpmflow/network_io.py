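"""Gene lists, interaction networks and whole-network topology statistics.

Disease gene lists (NCBI/GeneCards-style, one symbol per line or a CSV
column) are intersected with a protein–protein interaction edge list
(STRING export dialect: ``protein1 TAB protein2 TAB combined_score``) to
build per-disease subnetworks, whose global topology is summarised by the
statistics a network viewer would report: density, degree centralization,
mean clustering coefficient, mean degree and characteristic path length.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "GeneList",
    "NetworkStats",
    "OverlapCounts",
    "read_gene_list",
    "read_edge_list",
    "write_network",
    "write_sif",
    "build_disease_network",
    "network_stats",
    "venn_counts",
]


@dataclass(frozen=True)
class GeneList:
    """An ordered, deduplicated list of upper-cased gene symbols."""

    disease_label: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols")
        if any(not g for g in self.genes):
            raise ValueError("empty gene symbol")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def as_set(self) -> set[str]:
        return set(self.genes)


@dataclass(frozen=True)
class NetworkStats:
    """Whole-network topology summary."""

    n_nodes: int
    n_edges: int
    density: float
    degree_centralization: float
    clustering_coefficient: float
    avg_neighbors: float
    characteristic_path_length: float

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


@dataclass(frozen=True)
class OverlapCounts:
    """Region counts of a three-set Venn decomposition of gene lists.

    ``only_*`` are the exclusive regions, ``ab/ac/bc`` the pair-only
    regions (triple excluded) and ``abc`` the triple overlap.  Pairwise
    *totals* (pair-only + triple) are also exposed because both reporting
    conventions occur in the literature.
    """

    labels: tuple[str, str, str]
    only_a: int
    only_b: int
    only_c: int
    ab: int
    ac: int
    bc: int
    abc: int

    @property
    def total_a(self) -> int:
        return self.only_a + self.ab + self.ac + self.abc

    @property
    def total_b(self) -> int:
        return self.only_b + self.ab + self.bc + self.abc

    @property
    def total_c(self) -> int:
        return self.only_c + self.ac + self.bc + self.abc

    @property
    def pair_totals(self) -> dict[str, int]:
        """Pairwise intersections including the triple region."""
        a, b, c = self.labels
        return {
            f"{a}&{b}": self.ab + self.abc,
            f"{a}&{c}": self.ac + self.abc,
            f"{b}&{c}": self.bc + self.abc,
        }

    def triple_fraction(self) -> dict[str, float]:
        """Triple overlap as a fraction of each list (e.g. 56/288)."""
        out = {}
        for label, total in zip(self.labels, (self.total_a, self.total_b, self.total_c)):
            out[label] = self.abc / total if total else 0.0
        return out


def _clean_symbol(raw: str) -> str:
    return raw.strip().strip('"').upper()


def read_gene_list(
    path: str | Path,
    disease_label: str,
    gene_column: str | int | None = None,
) -> GeneList:
    """Read a gene list from plain text (one symbol per line) or CSV.

    Symbols are upper-cased, trimmed and deduplicated preserving first
    occurrence.  ``gene_column`` selects a CSV column by header name or
    0-based index; without it every line is taken as one symbol.
    """
    path = Path(path)
    symbols: list[str] = []
    if gene_column is None:
        for line in path.read_text().splitlines():
            sym = _clean_symbol(line)
            if sym:
                symbols.append(sym)
    else:
        with path.open(newline="") as fh:
            reader = csv.reader(fh)
            rows = list(reader)
        if not rows:
            raise ValueError(f"no genes in {path}")
        if isinstance(gene_column, int):
            idx = gene_column
            body = rows
        else:
            header = [h.strip() for h in rows[0]]
            if gene_column not in header:
                raise ValueError(f"column {gene_column!r} not in header of {path}")
            idx = header.index(gene_column)
            body = rows[1:]
        for row in body:
            if idx < len(row):
                sym = _clean_symbol(row[idx])
                if sym:
                    symbols.append(sym)
    seen: dict[str, None] = {}
    for s in symbols:
        seen.setdefault(s)
    if not seen:
        raise ValueError(f"no genes in {path}")
    logger.info("read %d genes for %s from %s", len(seen), disease_label, path)
    return GeneList(disease_label=disease_label, genes=tuple(seen))


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def read_edge_list(path: str | Path, min_score: float | None = None) -> nx.Graph:
    """Read a STRING-dialect edge list into an undirected simple graph.

    Tab- or whitespace-separated; first two columns are node symbols, an
    optional third column is a confidence score.  A header row is detected
    by a non-numeric score field (or by the canonical ``protein1`` header).
    Duplicate and reversed-duplicate rows collapse keeping the maximum
    score; self-loops are dropped; rows below ``min_score`` are dropped.
    """
    path = Path(path)
    g = nx.Graph(label=path.stem)
    n_dropped = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 columns")
            u, v = _clean_symbol(parts[0]), _clean_symbol(parts[1])
            score: float | None = None
            if len(parts) >= 3:
                tok = parts[2].strip()
                if not _is_number(tok):
                    if lineno == 1 or u == "PROTEIN1":
                        continue  # header row
                    if min_score is not None:
                        raise ValueError(
                            f"{path}:{lineno}: non-numeric score {tok!r}"
                        )
                else:
                    score = float(tok)
            if u == "PROTEIN1" and v == "PROTEIN2":
                continue
            if u == v:
                n_dropped += 1
                continue
            if min_score is not None:
                if score is None:
                    raise ValueError(f"{path}:{lineno}: score column required")
                if score < min_score:
                    n_dropped += 1
                    continue
            if g.has_edge(u, v):
                old = g.edges[u, v].get("score")
                if score is not None and (old is None or score > old):
                    g.edges[u, v]["score"] = score
            else:
                if score is None:
                    g.add_edge(u, v)
                else:
                    g.add_edge(u, v, score=score)
    if n_dropped:
        logger.info("dropped %d rows (self-loops / below threshold)", n_dropped)
    return g


def write_network(net: nx.Graph, path: str | Path) -> None:
    """Write a canonical TSV: sorted endpoints per row, rows sorted."""
    rows = []
    for u, v, data in net.edges(data=True):
        a, b = sorted((u, v))
        score = data.get("score")
        rows.append((a, b, "" if score is None else f"{score:g}"))
    rows.sort()
    with Path(path).open("w") as fh:
        for a, b, s in rows:
            fh.write(f"{a}\t{b}\t{s}\n" if s else f"{a}\t{b}\n")


def write_sif(net: nx.Graph, path: str | Path, relation: str = "pp") -> None:
    with Path(path).open("w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.edges()):
            fh.write(f"{u}\t{relation}\t{v}\n")


def build_disease_network(edges: nx.Graph, genes: GeneList | Iterable[str]) -> nx.Graph:
    """Induced subgraph of the interactome on a disease gene list.

    Genes absent from the interactome and genes left isolated (degree 0
    within the induced subgraph) are excluded from the returned node set,
    matching the convention that a disease network contains interacting
    genes only.
    """
    gene_set = genes.as_set() if isinstance(genes, GeneList) else {g.upper() for g in genes}
    present = gene_set & set(edges.nodes)
    if not present:
        raise ValueError("no disease genes in interactome")
    sub = edges.subgraph(present).copy()
    isolated = [n for n, d in sub.degree() if d == 0]
    sub.remove_nodes_from(isolated)
    label = genes.disease_label if isinstance(genes, GeneList) else "disease"
    sub.graph["label"] = label
    logger.info(
        "%s: %d/%d genes in interactome, %d isolated excluded -> %d nodes",
        label, len(present), len(gene_set), len(isolated), sub.number_of_nodes(),
    )
    if sub.number_of_nodes() == 0:
        raise ValueError("no disease genes in interactome")
    return sub


def network_stats(net: nx.Graph) -> NetworkStats:
    """Topology statistics of a simple undirected graph.

    Density is 2E/(N(N-1)); clustering is the mean local clustering
    coefficient with degree<2 nodes contributing 0; degree centralization
    is Freeman's sum(deg_max - deg_i)/((N-1)(N-2)); the characteristic
    path length averages shortest paths over connected node pairs only, so
    it stays defined on fragmented disease networks.
    """
    n = net.number_of_nodes()
    if n < 2:
        raise ValueError("need at least 2 nodes")
    m = net.number_of_edges()
    density = 2.0 * m / (n * (n - 1))
    clustering = sum(nx.clustering(net).values()) / n
    degrees = [d for _, d in net.degree()]
    dmax = max(degrees)
    centralization = (
        sum(dmax - d for d in degrees) / ((n - 1) * (n - 2)) if n > 2 else 0.0
    )
    total, pairs = 0.0, 0
    for _, dists in nx.all_pairs_shortest_path_length(net):
        for d in dists.values():
            if d > 0:
                total += d
                pairs += 1
    cpl = total / pairs if pairs else 0.0
    return NetworkStats(
        n_nodes=n,
        n_edges=m,
        density=density,
        degree_centralization=centralization,
        clustering_coefficient=clustering,
        avg_neighbors=2.0 * m / n,
        characteristic_path_length=cpl,
    )


def venn_counts(list_a: GeneList, list_b: GeneList, list_c: GeneList) -> OverlapCounts:
    """Exact three-set Venn region counts for three gene lists."""
    a, b, c = list_a.as_set(), list_b.as_set(), list_c.as_set()
    abc = a & b & c
    return OverlapCounts(
        labels=(list_a.disease_label, list_b.disease_label, list_c.disease_label),
        only_a=len(a - b - c),
        only_b=len(b - a - c),
        only_c=len(c - a - b),
        ab=len((a & b) - abc),
        ac=len((a & c) - abc),
        bc=len((b & c) - abc),
        abc=len(abc),
    )
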
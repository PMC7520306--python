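"""Construction of the integrated gene-gene network.

Two component networks are built and merged:

* a **PPI network** integrated from several source databases, keeping an
  interaction only when it is reported by at least ``min_sources`` distinct
  databases (default 2, the robustness filter used for multi-database PPI
  compendia);
* a **co-expression network** from a tumour expression matrix, connecting
  gene pairs whose absolute Spearman rank correlation across samples reaches
  a cutoff (default 0.6).

The merged graph is undirected and unweighted; each edge carries a
``provenance`` attribute (``ppi``, ``coexpression`` or ``both``) retained for
auditability even though propagation treats all edges identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "SourcedEdgeList",
    "read_expression_tsv",
    "read_labels_tsv",
    "collapse_expression",
    "spearman_coexpression",
    "integrate_ppi",
    "merge_networks",
    "read_edge_tsv",
    "write_edge_tsv",
    "write_network_tsv",
    "read_network_tsv",
]


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    if a == b:
        raise ValueError(f"self-loop not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class SourcedEdgeList:
    """Canonical undirected edge list with a per-edge source tag.

    ``edges`` holds ``(gene_a, gene_b, source)`` triples with
    ``gene_a < gene_b`` lexicographically, no self-loops, and each
    (pair, source) combination unique.
    """

    edges: frozenset[tuple[str, str, str]]

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str]]
    ) -> "SourcedEdgeList":
        canon = {(*_canonical_pair(a, b), src) for a, b, src in records}
        return cls(frozenset(canon))

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]], source: str
    ) -> "SourcedEdgeList":
        return cls.from_records((a, b, source) for a, b in pairs)

    def pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset((a, b) for a, b, _ in self.edges)

    def sources(self) -> frozenset[str]:
        return frozenset(src for _, _, src in self.edges)

    def nodes(self) -> frozenset[str]:
        return frozenset(g for a, b, _ in self.edges for g in (a, b))

    def __len__(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# Expression matrix I/O and cleanup
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (first column gene symbols)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def read_labels_tsv(path: str | Path) -> pd.Series:
    """Read a two-column (sample, label) TSV; labels sensitive/resistant."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (sample, label)")
    labels = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].astype(str))
    bad = set(labels.unique()) - {"sensitive", "resistant"}
    if bad:
        raise ValueError(f"{path}: unknown labels {sorted(bad)}")
    return labels


def collapse_expression(raw: pd.DataFrame) -> pd.DataFrame:
    """Clean a raw expression matrix for downstream correlation.

    Rows with an empty or missing gene annotation are removed; duplicate
    gene rows are collapsed to their element-wise mean, as are duplicate
    sample columns.  Gene symbols are uppercased.
    """
    idx = raw.index.astype(str).str.strip()
    keep = np.asarray((idx != "") & (idx.str.lower() != "nan"))
    if not keep.any():
        raise ValueError("no annotated gene rows remain after filtering")
    df = raw.loc[keep].copy()
    df.index = idx[keep].str.upper()
    if df.index.has_duplicates:
        df = df.groupby(level=0, sort=False).mean()
    if df.columns.has_duplicates:
        df = df.T.groupby(level=0, sort=False).mean().T
    return df


# ---------------------------------------------------------------------------
# Co-expression network
# ---------------------------------------------------------------------------

def spearman_coexpression(
    expr: pd.DataFrame,
    cutoff: float = 0.6,
    *,
    genes: Iterable[str] | None = None,
    gene_cap: int | None = 5000,
    block_size: int = 2000,
    source: str = "coexpression",
) -> SourcedEdgeList:
    """All-pairs Spearman co-expression edges at an absolute cutoff.

    For every unordered gene pair the Spearman rank correlation (average
    ranks for ties) is computed across samples; an edge is emitted when
    |rho| >= ``cutoff``.  Genes constant across samples are excluded — their
    correlation is undefined.

    ``genes`` optionally restricts the universe (e.g. to PPI nodes).  The
    pair scan runs blockwise on the rank-standardized matrix; ``gene_cap``
    guards against accidentally launching an all-pairs scan over a very
    large universe and can be raised or set to ``None`` deliberately.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for rank correlation")
    if genes is not None:
        wanted = {str(g).upper() for g in genes}
        expr = expr.loc[expr.index.isin(wanted)]
    values = expr.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")

    # drop zero-variance genes (rho undefined)
    variable = values.std(axis=1) > 0
    values = values[variable]
    names = expr.index.to_numpy()[variable]
    n_genes, n_samples = values.shape
    if n_genes < 2:
        return SourcedEdgeList(frozenset())
    if gene_cap is not None and n_genes > gene_cap:
        raise ValueError(
            f"{n_genes} genes exceeds gene_cap={gene_cap}; raise gene_cap "
            "(or pass gene_cap=None) to run an all-pairs scan at this scale"
        )

    # Spearman = Pearson on average ranks: standardize the rank rows, then
    # rho is a scaled inner product computed blockwise.
    ranks = rankdata(values, axis=1)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1, keepdims=True)
    z = ranks / norms

    records: list[tuple[str, str, str]] = []
    for start in range(0, n_genes, block_size):
        stop = min(start + block_size, n_genes)
        rho = z[start:stop] @ z[start:].T  # block vs. upper remainder
        for bi in range(stop - start):
            i = start + bi
            row = rho[bi]
            hits = np.flatnonzero(np.abs(row) >= cutoff)
            for off in hits:
                j = start + off
                if j > i:
                    records.append((*_canonical_pair(names[i], names[j]), source))
    return SourcedEdgeList.from_records(records)


# ---------------------------------------------------------------------------
# PPI integration and merging
# ---------------------------------------------------------------------------

def integrate_ppi(
    sources: Sequence[SourcedEdgeList], min_sources: int = 2
) -> SourcedEdgeList:
    """Keep interactions reported by at least ``min_sources`` databases.

    Multiplicity counts *distinct* source tags per unordered pair across all
    input lists; with ``min_sources=1`` this is the plain union.
    """
    if not sources:
        raise ValueError("at least one source edge list required")
    if min_sources < 1:
        raise ValueError("min_sources must be >= 1")
    support: dict[tuple[str, str], set[str]] = {}
    for edge_list in sources:
        for a, b, src in edge_list.edges:
            support.setdefault((a, b), set()).add(src)
    kept = [pair for pair, srcs in support.items() if len(srcs) >= min_sources]
    return SourcedEdgeList.from_pairs(kept, source="ppi")


def merge_networks(
    ppi: SourcedEdgeList, coexpr: SourcedEdgeList
) -> tuple[nx.Graph, dict]:
    """Union of the PPI and co-expression networks with edge provenance.

    Returns the undirected simple graph plus a summary record with node and
    edge counts and the size of the pair overlap between the two components.
    """
    ppi_pairs = ppi.pairs()
    co_pairs = coexpr.pairs()
    graph = nx.Graph()
    for a, b in ppi_pairs | co_pairs:
        if (a, b) in ppi_pairs and (a, b) in co_pairs:
            prov = "both"
        elif (a, b) in ppi_pairs:
            prov = "ppi"
        else:
            prov = "coexpression"
        graph.add_edge(a, b, provenance=prov)
    summary = {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "n_ppi_edges": len(ppi_pairs),
        "n_coexpression_edges": len(co_pairs),
        "n_overlap_edges": len(ppi_pairs & co_pairs),
    }
    return graph, summary


# ---------------------------------------------------------------------------
# Edge-list I/O
# ---------------------------------------------------------------------------

def read_edge_tsv(path: str | Path) -> SourcedEdgeList:
    """Read a three-column (geneA, geneB, source) TSV edge list."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] != 3:
        raise ValueError(f"{path}: expected three columns (geneA, geneB, source)")
    return SourcedEdgeList.from_records(
        (str(a).upper(), str(b).upper(), str(s)) for a, b, s in df.itertuples(index=False)
    )


def write_edge_tsv(edges: SourcedEdgeList, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_a\tgene_b\tsource\n")
        for a, b, src in sorted(edges.edges):
            fh.write(f"{a}\t{b}\t{src}\n")


def write_network_tsv(graph: nx.Graph, path: str | Path) -> None:
    """Export the merged network as (geneA, geneB, provenance)."""
    rows = sorted(
        (*_canonical_pair(a, b), data.get("provenance", "ppi"))
        for a, b, data in graph.edges(data=True)
    )
    with Path(path).open("w") as fh:
        fh.write("gene_a\tgene_b\tprovenance\n")
        for a, b, prov in rows:
            fh.write(f"{a}\t{b}\t{prov}\n")


def read_network_tsv(path: str | Path) -> nx.Graph:
    graph = nx.Graph()
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] != 3:
        raise ValueError(f"{path}: expected three columns (geneA, geneB, provenance)")
    for a, b, prov in df.itertuples(index=False):
        graph.add_edge(str(a), str(b), provenance=str(prov))
    return graph
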
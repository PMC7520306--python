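"""Gene-set handling and seed partitioning.

The analysis starts from two curated DNA-repair gene sets — homologous
recombination (HR) and the Fanconi anaemia (FA) FANC-BRCA pathway — read from
GMT files.  Their intersection structure defines the three seed groups used to
initialize the random walks:

* ``HO-G``  — HR-only genes (in HR but not FA),
* ``HFC-G`` — HR/FA common genes (the intersection),
* ``FO-G``  — FA-only genes (in FA but not HR).

Gene identity throughout the package is the uppercased symbol string; no
alias or identifier mapping is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "GeneSetCollection",
    "SeedPartition",
    "read_gmt",
    "write_gmt",
    "partition_seeds",
    "annotate_seeds",
    "write_partition_tsv",
    "read_partition_tsv",
    "GROUP_NAMES",
]

#: Canonical seed-group labels, in the order FA-only, shared, HR-only.
GROUP_NAMES = ("FO-G", "HFC-G", "HO-G")


class GmtParseError(ValueError):
    """Raised when a GMT file violates the three-field-minimum line format."""


def _normalize_symbol(symbol: str) -> str:
    sym = symbol.strip().upper()
    if not sym:
        raise ValueError("empty gene symbol")
    if any(ch.isspace() for ch in sym):
        raise ValueError(f"gene symbol contains whitespace: {symbol!r}")
    return sym


class GeneSetCollection:
    """Named, non-empty sets of uppercase gene symbols.

    A thin mapping from set name to ``frozenset`` of symbols with the GMT
    invariants enforced at construction: unique names, non-empty sets, no
    whitespace inside a symbol.
    """

    def __init__(self, entries: Mapping[str, Iterable[str]]):
        built: dict[str, frozenset[str]] = {}
        for name, genes in entries.items():
            if name in built:
                raise ValueError(f"duplicate gene-set name: {name!r}")
            genes_norm = frozenset(_normalize_symbol(g) for g in genes)
            if not genes_norm:
                raise ValueError(f"gene set {name!r} is empty")
            built[name] = genes_norm
        self._entries = built

    def __getitem__(self, name: str) -> frozenset[str]:
        return self._entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self._entries == other._entries

    def items(self):
        return self._entries.items()

    def names(self) -> list[str]:
        return list(self._entries)

    def __repr__(self) -> str:  # pragma: no cover
        return f"GeneSetCollection({len(self)} sets)"


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (name, description, member genes, tab-separated).

    Duplicate symbols within one line are deduplicated; symbols are
    uppercased.  A line with fewer than three fields or a repeated set name
    raises :class:`GmtParseError` naming the offending line.
    """
    path = Path(path)
    entries: dict[str, list[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields "
                    f"(name, description, genes...), got {len(fields)}"
                )
            name = fields[0]
            if name in entries:
                raise GmtParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = [g for g in fields[2:] if g.strip()]
            if not genes:
                raise GmtParseError(f"{path}:{lineno}: set {name!r} has no genes")
            entries[name] = genes
    return GeneSetCollection(entries)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection back to GMT (description field left as 'na')."""
    with Path(path).open("w") as fh:
        for name, genes in collection.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


@dataclass(frozen=True)
class SeedPartition:
    """The three disjoint seed groups derived from the HR and FA sets.

    Attributes
    ----------
    ho_g : frozenset[str]
        HR-only genes.
    hfc_g : frozenset[str]
        Genes shared by HR and FA.
    fo_g : frozenset[str]
        FA-only genes.
    """

    ho_g: frozenset[str]
    hfc_g: frozenset[str]
    fo_g: frozenset[str]

    def __post_init__(self) -> None:
        if self.ho_g & self.hfc_g or self.ho_g & self.fo_g or self.hfc_g & self.fo_g:
            raise ValueError("seed groups must be pairwise disjoint")

    def groups(self) -> dict[str, frozenset[str]]:
        """Group label -> gene set, in canonical FO-G, HFC-G, HO-G order."""
        return {"FO-G": self.fo_g, "HFC-G": self.hfc_g, "HO-G": self.ho_g}

    def sizes(self) -> dict[str, int]:
        return {name: len(genes) for name, genes in self.groups().items()}


def partition_seeds(fa: Iterable[str], hr: Iterable[str]) -> SeedPartition:
    """Split the FA and HR gene sets into FA-only, shared and HR-only groups.

    The shared genes (``hfc_g``) are the intersection; ``fo_g`` and ``ho_g``
    are the respective set differences, so ``fo_g ∪ hfc_g`` recovers the FA
    input and ``ho_g ∪ hfc_g`` the HR input.
    """
    fa_set = frozenset(_normalize_symbol(g) for g in fa)
    hr_set = frozenset(_normalize_symbol(g) for g in hr)
    if not fa_set or not hr_set:
        raise ValueError("both input gene sets must be non-empty")
    return SeedPartition(
        ho_g=hr_set - fa_set,
        hfc_g=fa_set & hr_set,
        fo_g=fa_set - hr_set,
    )


def annotate_seeds(seeds: Iterable[str], network_nodes: Iterable[str]) -> frozenset[str]:
    """Restrict a seed group to genes present in the network.

    Seeds absent from the network cannot carry restart probability; they are
    dropped with a warning listing them.  An empty intersection is an error —
    the walk would have nowhere to start.
    """
    seeds = frozenset(seeds)
    nodes = frozenset(network_nodes)
    if not nodes:
        raise ValueError("network node set is empty")
    annotated = seeds & nodes
    if not annotated:
        raise ValueError("no seed gene is present in the network")
    dropped = seeds - nodes
    if dropped:
        warnings.warn(
            f"{len(dropped)} seed gene(s) not in network, dropped: "
            + ", ".join(sorted(dropped)),
            stacklevel=2,
        )
    return annotated


def write_partition_tsv(partition: SeedPartition, path: str | Path) -> None:
    """Export as two columns (gene, group), genes sorted within group."""
    with Path(path).open("w") as fh:
        fh.write("gene\tgroup\n")
        for group, genes in partition.groups().items():
            for gene in sorted(genes):
                fh.write(f"{gene}\t{group}\n")


def read_partition_tsv(path: str | Path) -> SeedPartition:
    groups: dict[str, set[str]] = {name: set() for name in GROUP_NAMES}
    with Path(path).open() as fh:
        header = fh.readline()
        if not header.startswith("gene"):
            raise ValueError(f"{path}: expected header starting with 'gene'")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            try:
                gene, group = line.rstrip("\n").split("\t")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: expected two columns") from exc
            if group not in groups:
                raise ValueError(f"{path}:{lineno}: unknown group {group!r}")
            groups[group].add(_normalize_symbol(gene))
    return SeedPartition(
        ho_g=frozenset(groups["HO-G"]),
        hfc_g=frozenset(groups["HFC-G"]),
        fo_g=frozenset(groups["FO-G"]),
    )
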
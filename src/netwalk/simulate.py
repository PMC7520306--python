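"""Synthetic inputs for every pipeline stage.

Real runs of this analysis consume curated pathway gene sets, a
multi-database PPI compendium, a tumour expression matrix and labeled
platinum-response cohorts — none of which can ship with a package.  The
generators here emulate each of those inputs with known ground truth so the
whole pipeline is testable end to end:

* overlapping gene-set pairs with chosen sizes and intersection;
* multi-source edge lists whose per-edge source multiplicity is controlled,
  so the >=2-database integration filter has a known right answer;
* expression matrices where designated gene modules share a latent factor
  (loading rho gives within-module correlation ~ rho^2), so the
  co-expression stage has planted edges to find;
* two-group response datasets with a mean shift planted in designated genes
  (shift applied to the sensitive group, the direction platinum-sensitivity
  markers show);
* a planted-seed benchmark network in which designated "risk" genes are
  preferentially wired to seed genes, giving the propagation stage a
  recoverable ground truth.

Every generator is a pure function of the spec (seed included): the same
spec reproduces bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .genesets import SeedPartition
from .network import SourcedEdgeList
from .propagation import (
    RWRConfig,
    column_normalize,
    make_seed_vector,
    random_walk_restart,
    rank_genes,
)

__all__ = [
    "SyntheticSpec",
    "PlantedBenchmark",
    "gene_universe",
    "simulate_gene_sets",
    "simulate_expression",
    "simulate_ppi_sources",
    "simulate_response_dataset",
    "planted_seed_benchmark",
    "recovery_ranks",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study.

    Defaults mirror the shape of the real inputs at desk scale: a 500-gene
    universe, 50 tumour samples for co-expression, three PPI source
    databases at ~2% edge density with mixed per-edge source multiplicity,
    and response cohorts of 10 sensitive + 10 resistant samples with a
    2-standard-deviation planted shift in candidate genes.

    Attributes
    ----------
    n_genes, n_samples : int
        Universe size and co-expression sample count.
    modules : sequence of (gene list, loading)
        Co-expressed modules; each member gene is loading * latent +
        sqrt(1 - loading^2) * noise, loading in [0, 1].
    n_sources : int
        Number of simulated PPI source databases.
    edge_density : float
        Probability of a ground-truth background edge per gene pair.
    multiplicity_dist : mapping {m: prob}
        Distribution of the number of distinct sources reporting an edge.
    candidate_genes : tuple of str
        Genes carrying the planted response effect.
    effect_size : float
        Mean shift delta, in within-group standard-deviation units.
    n_sensitive, n_resistant : int
        Response-cohort group sizes.
    n_seeds, n_planted : int
        Benchmark: number of seed genes and planted risk genes.
    seed_wiring_factor : float
        Benchmark: risk-to-seed edge probability as a multiple of
        ``edge_density``.
    rng_seed : int
        Mandatory; every generator derives its randomness from it.
    """

    rng_seed: int
    n_genes: int = 500
    n_samples: int = 50
    modules: Sequence[tuple[Sequence[str], float]] = ()
    n_sources: int = 3
    edge_density: float = 0.02
    multiplicity_dist: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.5, 2: 0.3, 3: 0.2}
    )
    candidate_genes: tuple[str, ...] = ()
    effect_size: float = 2.0
    n_sensitive: int = 10
    n_resistant: int = 10
    n_seeds: int = 20
    n_planted: int = 10
    seed_wiring_factor: float = 10.0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_samples <= 0:
            raise ValueError("n_genes and n_samples must be positive")
        for genes, loading in self.modules:
            if not 0 <= loading <= 1:
                raise ValueError(f"module loading {loading} outside [0, 1]")
        if not 0 <= self.edge_density <= 1:
            raise ValueError("edge_density must be in [0, 1]")
        if abs(sum(self.multiplicity_dist.values()) - 1.0) > 1e-9:
            raise ValueError("multiplicity_dist probabilities must sum to 1")
        if self.n_sensitive <= 0 or self.n_resistant <= 0:
            raise ValueError("group sizes must be positive")

    def with_(self, **kwargs) -> "SyntheticSpec":
        return replace(self, **kwargs)


def gene_universe(n_genes: int) -> list[str]:
    """Deterministic synthetic gene symbols G0000, G0001, ..."""
    width = max(4, len(str(n_genes - 1)))
    return [f"G{i:0{width}d}" for i in range(n_genes)]


def simulate_gene_sets(
    spec: SyntheticSpec,
    n_fa: int = 56,
    n_hr: int = 53,
    n_shared: int = 15,
) -> tuple[frozenset[str], frozenset[str]]:
    """An overlapping FA/HR-like gene-set pair with exact sizes and overlap.

    Default sizes reproduce the seed-pathway arithmetic of the real study:
    56 FA genes and 53 HR genes sharing 15, so the partition yields 41
    FA-only and 38 HR-only genes.
    """
    if n_shared > min(n_fa, n_hr):
        raise ValueError("overlap larger than a set")
    total = n_fa + n_hr - n_shared
    if total > spec.n_genes:
        raise ValueError("gene universe too small for the requested sets")
    rng = np.random.default_rng([spec.rng_seed, 101])
    chosen = rng.choice(spec.n_genes, size=total, replace=False)
    universe = gene_universe(spec.n_genes)
    genes = [universe[i] for i in chosen]
    shared = genes[:n_shared]
    fa_only = genes[n_shared : n_shared + (n_fa - n_shared)]
    hr_only = genes[n_shared + (n_fa - n_shared) :]
    return frozenset(shared + fa_only), frozenset(shared + hr_only)


def simulate_expression(spec: SyntheticSpec) -> pd.DataFrame:
    """Genes x samples matrix with planted co-expressed modules.

    Background genes are i.i.d. standard normal per sample.  Each module
    shares a per-sample latent factor: member = loading * factor +
    sqrt(1 - loading^2) * noise, so within-module Spearman correlation is
    controlled by the loading and background pairs stay near zero.
    """
    universe = gene_universe(spec.n_genes)
    index = {g: i for i, g in enumerate(universe)}
    claimed: set[str] = set()
    for genes, _ in spec.modules:
        gset = {str(g) for g in genes}
        unknown = gset - index.keys()
        if unknown:
            raise ValueError(f"module genes not in universe: {sorted(unknown)}")
        if gset & claimed:
            raise ValueError("module gene lists overlap")
        claimed |= gset
    rng = np.random.default_rng([spec.rng_seed, 102])
    values = rng.standard_normal((spec.n_genes, spec.n_samples))
    for genes, loading in spec.modules:
        factor = rng.standard_normal(spec.n_samples)
        rows = [index[str(g)] for g in genes]
        noise = rng.standard_normal((len(rows), spec.n_samples))
        values[rows] = loading * factor + np.sqrt(1 - loading**2) * noise
    samples = [f"S{j:03d}" for j in range(spec.n_samples)]
    return pd.DataFrame(values, index=universe, columns=samples)


def simulate_ppi_sources(
    spec: SyntheticSpec,
) -> tuple[list[SourcedEdgeList], dict[tuple[str, str], int]]:
    """Per-source edge lists from a ground-truth edge set.

    A ground-truth set of undirected edges is sampled at ``edge_density``;
    each edge is then reported by m distinct source databases, m drawn from
    ``multiplicity_dist``.  Returns one edge list per source plus the
    pair -> multiplicity ground truth, so the >=min_sources integration
    filter can be checked exactly.
    """
    if spec.n_sources < 2:
        raise ValueError("need at least 2 sources")
    if max(spec.multiplicity_dist) > spec.n_sources:
        raise ValueError("multiplicity exceeds the number of sources")
    universe = gene_universe(spec.n_genes)
    rng = np.random.default_rng([spec.rng_seed, 103])
    iu, ju = np.triu_indices(spec.n_genes, k=1)
    mask = rng.random(iu.size) < spec.edge_density
    edge_idx = np.flatnonzero(mask)
    if edge_idx.size == 0:
        raise ValueError("edge_density produced zero ground-truth edges")
    mults = list(spec.multiplicity_dist)
    probs = [spec.multiplicity_dist[m] for m in mults]
    drawn = rng.choice(mults, size=edge_idx.size, p=probs)
    source_names = [f"db{s}" for s in range(spec.n_sources)]
    per_source: dict[str, list[tuple[str, str]]] = {s: [] for s in source_names}
    truth: dict[tuple[str, str], int] = {}
    for e, m in zip(edge_idx, drawn):
        a, b = universe[iu[e]], universe[ju[e]]
        truth[(a, b)] = int(m)
        for s in rng.choice(spec.n_sources, size=int(m), replace=False):
            per_source[source_names[s]].append((a, b))
    lists = [
        SourcedEdgeList.from_pairs(pairs, source=name)
        for name, pairs in per_source.items()
    ]
    return lists, truth


def simulate_response_dataset(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, pd.Series]:
    """Two-group expression dataset with a planted shift in candidate genes.

    All genes are i.i.d. standard normal; candidate genes get +delta
    (``effect_size``) added in the sensitive group.  Returns the matrix and
    the sample -> {sensitive, resistant} labels.
    """
    universe = gene_universe(spec.n_genes)
    index = {g: i for i, g in enumerate(universe)}
    unknown = {str(g) for g in spec.candidate_genes} - index.keys()
    if unknown:
        raise ValueError(f"candidate genes not in universe: {sorted(unknown)}")
    if spec.n_sensitive < 2 or spec.n_resistant < 2:
        raise ValueError("each response group needs >= 2 samples")
    rng = np.random.default_rng([spec.rng_seed, 104])
    n_total = spec.n_sensitive + spec.n_resistant
    values = rng.standard_normal((spec.n_genes, n_total))
    cand_rows = [index[str(g)] for g in spec.candidate_genes]
    values[np.ix_(cand_rows, range(spec.n_sensitive))] += spec.effect_size
    samples = [f"S{j:03d}" for j in range(n_total)]
    labels = pd.Series(
        ["sensitive"] * spec.n_sensitive + ["resistant"] * spec.n_resistant,
        index=samples,
    )
    return pd.DataFrame(values, index=universe, columns=samples), labels


@dataclass(frozen=True)
class PlantedBenchmark:
    """Ground truth for an end-to-end rank-recovery experiment."""

    network: nx.Graph
    partition: SeedPartition
    seeds: frozenset[str]
    planted: frozenset[str]


def planted_seed_benchmark(spec: SyntheticSpec) -> PlantedBenchmark:
    """Network where planted "risk" genes are preferentially wired to seeds.

    Background gene pairs connect with probability ``edge_density``;
    (risk, seed) pairs with ``seed_wiring_factor`` times that (capped at 1).
    With factor 1 the planted genes are indistinguishable from background;
    with a large factor propagation from the seeds should rank them near
    the top.  The seed genes are split round-robin into the three seed
    groups so the partition plumbing is exercised.
    """
    if spec.n_seeds + spec.n_planted > spec.n_genes:
        raise ValueError("universe too small for seeds + planted genes")
    universe = gene_universe(spec.n_genes)
    rng = np.random.default_rng([spec.rng_seed, 105])
    chosen = rng.choice(spec.n_genes, size=spec.n_seeds + spec.n_planted, replace=False)
    seeds = [universe[i] for i in chosen[: spec.n_seeds]]
    planted = [universe[i] for i in chosen[spec.n_seeds :]]
    seed_set, planted_set = set(seeds), set(planted)

    p_risk = min(1.0, spec.seed_wiring_factor * spec.edge_density)
    iu, ju = np.triu_indices(spec.n_genes, k=1)
    draws = rng.random(iu.size)
    graph = nx.Graph()
    graph.add_nodes_from(universe)
    for e in range(iu.size):
        a, b = universe[iu[e]], universe[ju[e]]
        cross = (a in planted_set and b in seed_set) or (
            a in seed_set and b in planted_set
        )
        if draws[e] < (p_risk if cross else spec.edge_density):
            graph.add_edge(a, b, provenance="ppi")

    groups: list[set[str]] = [set(), set(), set()]
    for i, g in enumerate(seeds):
        groups[i % 3].add(g)
    partition = SeedPartition(
        fo_g=frozenset(groups[0]),
        hfc_g=frozenset(groups[1]),
        ho_g=frozenset(groups[2]),
    )
    return PlantedBenchmark(
        network=graph,
        partition=partition,
        seeds=frozenset(seed_set),
        planted=frozenset(planted_set),
    )


def recovery_ranks(
    benchmark: PlantedBenchmark, cfg: RWRConfig = RWRConfig()
) -> tuple[list[int], int]:
    """Rank of each planted gene among non-seed genes after propagation.

    Runs the walk restarting on the full seed union, ranks non-seed genes
    by steady-state score (zero-score genes kept at the bottom so every
    planted gene has a rank), and returns the planted genes' 1-based ranks
    plus the number of non-seed genes ranked.
    """
    tm = column_normalize(benchmark.network)
    p0 = make_seed_vector(benchmark.seeds & set(tm.node_order), tm.node_order)
    result = random_walk_restart(tm, p0, cfg, seed_group_name="benchmark")
    ranked = [
        (g, s) for g, s in rank_genes(result, drop_zeros=False)
        if g not in benchmark.seeds
    ]
    position = {g: i + 1 for i, (g, _) in enumerate(ranked)}
    ranks = sorted(position[g] for g in benchmark.planted)
    return ranks, len(ranked)
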
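"""Random walk with restart (RWR) over the integrated network.

The walker starts from a probability vector P0 uniform over the annotated
seed genes and iterates

    P_{t+1} = (1 - r) W P_t + r P0

where W is the column-normalized (degree-normalized) adjacency matrix of the
unweighted network and r is the restart probability (default 0.7).  The
iteration stops when the L1 difference between successive vectors falls
below the tolerance (default 1e-6); the steady state P_inf scores every
gene's proximity to the seed set.

Zero-degree (dangling) nodes would leak probability mass; their mass is
reassigned through the restart distribution P0 at every step, which keeps
the vector summing to 1 and equals replacing their all-zero columns by P0.
For r in (0, 1] the update is a contraction with factor (1 - r), so
convergence is geometric and, at r = 0.7, reached in at most ~13 iterations.

``closed_form_solve`` provides the direct linear-system solution
r (I - (1-r) W')^{-1} P0 on small graphs; it exists purely as an independent
verification path for the iteration.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = [
    "TransitionMatrix",
    "SeedVector",
    "RWRConfig",
    "PropagationResult",
    "column_normalize",
    "make_seed_vector",
    "random_walk_restart",
    "closed_form_solve",
    "rank_genes",
    "write_rnk",
    "read_rnk",
    "write_run_metadata",
]

#: A ranked gene list: (gene, score) pairs, scores non-increasing,
#: lexicographic tie-break.
RankedList = list[tuple[str, float]]


@dataclass(frozen=True)
class TransitionMatrix:
    """Column-stochastic step matrix over a fixed node order.

    ``W[i, j]`` is the probability of stepping to node i from node j; each
    non-dangling column sums to 1.  ``dangling`` records zero-degree nodes,
    whose columns are all-zero here and handled at walk time.
    """

    node_order: tuple[str, ...]
    W: sp.csr_matrix
    dangling: frozenset[str]

    @property
    def n(self) -> int:
        return len(self.node_order)

    def index_of(self, genes: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.node_order)}
        return np.array([lookup[g] for g in genes], dtype=int)


@dataclass(frozen=True)
class SeedVector:
    """Restart distribution: uniform over the annotated seed genes."""

    p0: np.ndarray
    seed_nodes: frozenset[str]


@dataclass(frozen=True)
class RWRConfig:
    """Walk parameters: restart probability, L1 tolerance, iteration cap."""

    restart: float = 0.7
    tol: float = 1e-6
    max_iterations: int = 1000
    norm: str = "L1"

    def __post_init__(self) -> None:
        if not 0 < self.restart <= 1:
            raise ValueError("restart probability must be in (0, 1]")
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")
        if self.norm != "L1":
            raise ValueError("only the L1 convergence norm is implemented")


@dataclass(frozen=True)
class PropagationResult:
    """Steady-state probabilities plus convergence metadata."""

    node_order: tuple[str, ...]
    p_inf: np.ndarray
    iterations: int
    converged: bool
    seed_group_name: str = ""

    def scores(self) -> dict[str, float]:
        return dict(zip(self.node_order, self.p_inf))


def column_normalize(network: nx.Graph) -> TransitionMatrix:
    """Divide each column of the binary adjacency by the node degree.

    Node order is the sorted gene list.  Isolated nodes keep an all-zero
    column and are recorded as dangling.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("network is empty")
    node_order = tuple(sorted(network.nodes))
    adj = nx.to_scipy_sparse_array(network, nodelist=node_order, weight=None, format="csc")
    adj = adj.astype(float)
    degrees = np.asarray(adj.sum(axis=0)).ravel()
    dangling = frozenset(g for g, d in zip(node_order, degrees) if d == 0)
    inv = np.zeros_like(degrees)
    nz = degrees > 0
    inv[nz] = 1.0 / degrees[nz]
    W = (adj @ sp.diags(inv)).tocsr()
    return TransitionMatrix(node_order=node_order, W=W, dangling=dangling)


def make_seed_vector(seeds: Iterable[str], node_order: Sequence[str]) -> SeedVector:
    """Uniform restart vector: each seed gets 1/|seeds|, all others 0."""
    seeds = frozenset(seeds)
    if not seeds:
        raise ValueError("seed set is empty")
    lookup = {g: i for i, g in enumerate(node_order)}
    missing = seeds - lookup.keys()
    if missing:
        raise ValueError(
            "seed gene(s) not in node order (run annotate_seeds first): "
            + ", ".join(sorted(missing))
        )
    p0 = np.zeros(len(node_order))
    p0[[lookup[g] for g in seeds]] = 1.0 / len(seeds)
    return SeedVector(p0=p0, seed_nodes=seeds)


def random_walk_restart(
    W: TransitionMatrix,
    p0: SeedVector,
    cfg: RWRConfig = RWRConfig(),
    seed_group_name: str = "",
) -> PropagationResult:
    """Iterate the restart update from P0 to the steady state.

    At every step, mass on dangling nodes is redistributed through P0 before
    the damped step, preserving sum-to-1.  Non-convergence within
    ``max_iterations`` returns ``converged=False`` with a warning rather
    than raising, so callers can decide.
    """
    if len(p0.p0) != W.n:
        raise ValueError("seed vector and transition matrix node orders differ")
    r = cfg.restart
    restart = p0.p0
    dangling_idx = W.index_of(sorted(W.dangling)) if W.dangling else np.empty(0, int)
    p = restart.copy()
    iterations = 0
    converged = False
    for iterations in range(1, cfg.max_iterations + 1):
        step = W.W @ p
        if dangling_idx.size:
            step = step + p[dangling_idx].sum() * restart
        p_next = (1.0 - r) * step + r * restart
        diff = np.abs(p_next - p).sum()
        p = p_next
        if diff < cfg.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"random walk did not converge in {cfg.max_iterations} iterations "
            f"(restart={r}, tol={cfg.tol})",
            stacklevel=2,
        )
    return PropagationResult(
        node_order=W.node_order,
        p_inf=p,
        iterations=iterations,
        converged=converged,
        seed_group_name=seed_group_name,
    )


_DENSE_SOLVE_LIMIT = 2000


def closed_form_solve(W: TransitionMatrix, p0: SeedVector, r: float) -> np.ndarray:
    """Direct solution r (I - (1-r) W')^{-1} P0 on small graphs.

    W' is W with dangling columns replaced by P0 (the same reassignment the
    iteration applies).  Used only to verify the iterative walker; refuses
    graphs too large for a dense solve.
    """
    if not 0 < r <= 1:
        raise ValueError("restart probability must be in (0, 1]")
    if W.n > _DENSE_SOLVE_LIMIT:
        raise ValueError(f"dense solve limited to {_DENSE_SOLVE_LIMIT} nodes")
    Wd = W.W.toarray()
    if W.dangling:
        Wd[:, W.index_of(sorted(W.dangling))] = p0.p0[:, None]
    A = np.eye(W.n) - (1.0 - r) * Wd
    return np.linalg.solve(A, r * p0.p0)


def rank_genes(result: PropagationResult, drop_zeros: bool = True) -> RankedList:
    """Order genes by descending steady-state score.

    Ties break lexicographically by gene symbol.  With ``drop_zeros``, genes
    whose score is exactly 0 — nodes unreachable from every seed — are
    removed, since a zero score carries no ranking information.
    """
    pairs = sorted(
        zip(result.node_order, result.p_inf), key=lambda gs: (-gs[1], gs[0])
    )
    if drop_zeros:
        pairs = [(g, s) for g, s in pairs if s != 0.0]
    return [(g, float(s)) for g, s in pairs]


def expected_iteration_bound(cfg: RWRConfig) -> int:
    """Contraction-based upper bound on iterations to reach the tolerance."""
    return math.ceil(math.log(cfg.tol) / math.log1p(-cfg.restart)) + 1


def write_rnk(ranked: RankedList, path: str | Path) -> None:
    """Two-column (gene, score) TSV, preranked-GSEA '.rnk' convention."""
    with Path(path).open("w") as fh:
        for gene, score in ranked:
            fh.write(f"{gene}\t{score:.12g}\n")


def read_rnk(path: str | Path) -> RankedList:
    ranked: RankedList = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                gene, score = line.rstrip("\n").split("\t")
                ranked.append((gene, float(score)))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: expected 'gene<TAB>score'") from exc
    return ranked


def write_run_metadata(
    result: PropagationResult, cfg: RWRConfig, path: str | Path
) -> None:
    meta = {
        "seed_group": result.seed_group_name,
        "restart": cfg.restart,
        "tolerance": cfg.tol,
        "iterations": result.iterations,
        "converged": result.converged,
        "n_nodes": len(result.node_order),
        "n_zero_score": int(np.sum(result.p_inf == 0.0)),
    }
    Path(path).write_text(json.dumps(meta, indent=2) + "\n")
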
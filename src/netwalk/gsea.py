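"""Preranked gene-set enrichment on the propagation-ordered gene list.

Implements the running-sum enrichment statistic for a preranked list: walking
down the ranking, the sum increases at each gene-set member ("hit") by its
weighted score share and decreases at each non-member by 1/(N - n_hits); the
enrichment score (ES) is the signed extreme of this profile.  With weight 0
the statistic reduces to the classic Kolmogorov-Smirnov form; with weight 1
(the default) hits are weighted by |score|.

Significance uses a gene-permutation null: random gene sets of matched size
drawn from the ranked universe.  The nominal p-value compares the observed
ES against same-sign null scores with an add-one pseudocount; NES divides ES
by the mean magnitude of same-sign null scores; Benjamini-Hochberg step-up
adjustment is applied across gene sets.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .propagation import RankedList

__all__ = [
    "enrichment_score",
    "running_sum",
    "permutation_pvalues",
    "bh_adjust",
]


def _hit_indicator(genes: Sequence[str], gene_set: Iterable[str]) -> np.ndarray:
    members = {g for g in gene_set}
    return np.fromiter((g in members for g in genes), dtype=bool, count=len(genes))


def _running_sum_from_hits(
    scores: np.ndarray, hits: np.ndarray, weight: float
) -> np.ndarray:
    n = len(scores)
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    if weight == 0:
        hit_w = hits.astype(float)
    else:
        hit_w = np.where(hits, np.abs(scores) ** weight, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        raise ValueError(
            "all hit scores are zero with weight > 0; ES undefined "
            "(use weight=0 or drop zero-score genes)"
        )
    steps = hit_w / denom
    if n > n_hits:
        steps = steps - (~hits) / (n - n_hits)
    return np.cumsum(steps)


def running_sum(
    ranked: RankedList, gene_set: Iterable[str], weight: float = 1.0
) -> np.ndarray:
    """The full running-sum profile down the ranking (for plotting/export)."""
    genes = [g for g, _ in ranked]
    scores = np.array([s for _, s in ranked], dtype=float)
    return _running_sum_from_hits(scores, _hit_indicator(genes, gene_set), weight)


def enrichment_score(
    ranked: RankedList, gene_set: Iterable[str], weight: float = 1.0
) -> float:
    """Signed extreme of the running sum: positive for front-loaded sets."""
    if weight < 0:
        raise ValueError("weight must be >= 0")
    profile = running_sum(ranked, gene_set, weight)
    return float(profile[np.argmax(np.abs(profile))])


def _null_scores(
    scores: np.ndarray,
    set_size: int,
    weight: float,
    n_perm: int,
    rng: np.random.Generator,
    exhaustive: bool,
) -> np.ndarray:
    """Null ES distribution for random same-size sets from the universe."""
    n = len(scores)
    null = []
    if exhaustive:
        draws: Iterable[Sequence[int]] = combinations(range(n), set_size)
    else:
        draws = (
            rng.choice(n, size=set_size, replace=False) for _ in range(n_perm)
        )
    for idx in draws:
        hits = np.zeros(n, dtype=bool)
        hits[list(idx)] = True
        profile = _running_sum_from_hits(scores, hits, weight)
        null.append(profile[np.argmax(np.abs(profile))])
    return np.array(null)


def permutation_pvalues(
    ranked: RankedList,
    sets: Mapping[str, Iterable[str]],
    n_perm: int = 1000,
    rng_seed: int | None = None,
    *,
    weight: float = 1.0,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Gene-permutation significance for a collection of gene sets.

    Per set: nominal p = (1 + #{same-sign null ES at least as extreme}) /
    (1 + #same-sign null); NES = ES / mean(|same-sign null ES|); q from BH
    across sets.  Null distributions are shared across sets of equal overlap
    size, so the same seed gives bit-identical results.

    ``exhaustive=True`` enumerates every size-k subset of the universe as
    the null instead of sampling — exact, feasible only for tiny rankings.

    Returns a DataFrame indexed by set name with columns
    ``size, es, nes, p, q``.
    """
    if n_perm < 1 and not exhaustive:
        raise ValueError("n_perm must be >= 1")
    if rng_seed is None and not exhaustive:
        raise ValueError("rng_seed is required for a sampled permutation null")
    genes = [g for g, _ in ranked]
    scores = np.array([s for _, s in ranked], dtype=float)
    rng = np.random.default_rng(rng_seed)

    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for name, members in sets.items():
        hits = _hit_indicator(genes, members)
        k = int(hits.sum())
        if k == 0:
            raise ValueError(f"gene set {name!r} has no overlap with the ranking")
        profile = _running_sum_from_hits(scores, hits, weight)
        es = float(profile[np.argmax(np.abs(profile))])
        if k not in null_cache:
            null_cache[k] = _null_scores(scores, k, weight, n_perm, rng, exhaustive)
        null = null_cache[k]
        if es >= 0:
            same_sign = null[null >= 0]
            extreme = int((same_sign >= es).sum())
        else:
            same_sign = null[null < 0]
            extreme = int((same_sign <= es).sum())
        if same_sign.size == 0:
            p = 1.0 / (len(null) + 1)
            nes = np.nan
            warnings.warn(
                f"gene set {name!r}: no same-sign null draws; "
                f"p floored at 1/(n_null+1)",
                stacklevel=2,
            )
        else:
            p = (1 + extreme) / (1 + same_sign.size)
            nes = es / np.abs(same_sign).mean()
        rows.append((name, k, es, nes, p))

    df = pd.DataFrame(rows, columns=["set", "size", "es", "nes", "p"]).set_index("set")
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} (p_(j) * n / j) on the ascending order statistics,
    capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
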
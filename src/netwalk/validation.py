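"""Validation of candidate genes in platinum-response expression datasets.

Candidates from each seed-group ranking are tested for differential
expression between platinum-sensitive and platinum-resistant samples in each
labeled dataset (two-sided Welch t-test by default; Wilcoxon rank-sum as an
option), and the evidence is aggregated per gene as the mean of -log10(p)
across the datasets in which the gene is measured.  A gene missing from a
dataset — microarray platforms do not share probe coverage — simply does not
contribute to that gene's mean; the coverage count records how many datasets
did.  Group-level evidence is the mean over the member genes' means.

Also provides the 2^-ddCt relative-expression transform for qPCR-style
cycle-threshold readouts (reference-gene and control-condition normalized).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .propagation import RankedList

__all__ = [
    "differential_test",
    "aggregate_neglogp",
    "select_candidates",
    "CandidateSelection",
    "ddct_relative_expression",
]


def differential_test(
    expr: pd.DataFrame,
    labels: pd.Series,
    genes: Iterable[str],
    method: str = "welch",
) -> pd.DataFrame:
    """Per-gene two-group test between sensitive and resistant samples.

    Parameters
    ----------
    expr : DataFrame
        Genes x samples expression matrix.
    labels : Series
        Sample -> {"sensitive", "resistant"}; both groups need >= 2 samples.
    genes : iterable of str
        Genes to test.  A gene absent from the matrix is recorded with
        ``tested=False`` and NaN p-value, not an error.
    method : {"welch", "wilcoxon"}
        Welch's unequal-variance t-test (default) or Wilcoxon rank-sum.

    Returns
    -------
    DataFrame indexed by gene with columns ``p``, ``direction`` ("+" when
    the sensitive mean exceeds the resistant mean, "-" reversed, "0" tied)
    and ``tested``.
    """
    if method not in {"welch", "wilcoxon"}:
        raise ValueError(f"unknown test method {method!r}")
    labels = labels.loc[labels.index.intersection(expr.columns)]
    sens = labels.index[labels == "sensitive"]
    res = labels.index[labels == "resistant"]
    if len(sens) < 2 or len(res) < 2:
        raise ValueError(
            f"each response group needs >= 2 samples "
            f"(got {len(sens)} sensitive, {len(res)} resistant)"
        )
    rows = []
    for gene in genes:
        gene = str(gene).upper()
        if gene not in expr.index:
            rows.append((gene, np.nan, "", False))
            continue
        a = expr.loc[gene, sens].to_numpy(dtype=float)
        b = expr.loc[gene, res].to_numpy(dtype=float)
        if method == "welch":
            stat, p = stats.ttest_ind(a, b, equal_var=False)
        else:
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        if math.isnan(p):
            # zero variance in both groups: no evidence either way
            p = 1.0
        diff = a.mean() - b.mean()
        direction = "+" if diff > 0 else "-" if diff < 0 else "0"
        rows.append((gene, float(p), direction, True))
    return pd.DataFrame(
        rows, columns=["gene", "p", "direction", "tested"]
    ).set_index("gene")


def aggregate_neglogp(
    reports: Mapping[str, pd.DataFrame],
    genes: Iterable[str],
    groups: Mapping[str, Iterable[str]] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Cross-dataset evidence: per-gene mean of -log10(p).

    ``reports`` maps dataset name to a :func:`differential_test` result.
    For each gene, the mean runs over the datasets where the gene was
    tested; ``coverage`` counts them, and a gene tested nowhere gets NaN
    with coverage 0.  When ``groups`` is given (seed-group -> member genes),
    the second return value is each group's mean over its members' means
    (members with coverage 0 excluded).
    """
    if not reports:
        raise ValueError("at least one dataset report required")
    genes = [str(g).upper() for g in genes]
    per_gene = []
    for gene in genes:
        vals = []
        for report in reports.values():
            if gene in report.index and bool(report.loc[gene, "tested"]):
                p = float(report.loc[gene, "p"])
                vals.append(-math.log10(p))
        per_gene.append(
            (gene, float(np.mean(vals)) if vals else np.nan, len(vals))
        )
    gene_df = pd.DataFrame(
        per_gene, columns=["gene", "mean_neglog10p", "coverage"]
    ).set_index("gene")

    group_means: dict[str, float] = {}
    if groups is not None:
        for name, members in groups.items():
            member_vals = [
                gene_df.loc[str(g).upper(), "mean_neglog10p"]
                for g in members
                if str(g).upper() in gene_df.index
                and gene_df.loc[str(g).upper(), "coverage"] > 0
            ]
            group_means[name] = float(np.mean(member_vals)) if member_vals else np.nan
    return gene_df, pd.Series(group_means, dtype=float)


@dataclass(frozen=True)
class CandidateSelection:
    """Top-k genes per seed-group ranking plus their deduplicated union."""

    per_group: dict[str, list[str]]
    union: list[str]


def select_candidates(
    ranked_lists: Mapping[str, RankedList], k: int
) -> CandidateSelection:
    """Take the top-k genes of each ranking; union preserves first occurrence.

    A ranking shorter than k is used whole, with a warning.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    per_group: dict[str, list[str]] = {}
    union: list[str] = []
    seen: set[str] = set()
    for name, ranked in ranked_lists.items():
        if k > 0 and not ranked:
            raise ValueError(f"ranking {name!r} is empty")
        if k > len(ranked):
            warnings.warn(
                f"ranking {name!r} has only {len(ranked)} genes (< k={k}); "
                "taking the whole list",
                stacklevel=2,
            )
        top = [g for g, _ in ranked[:k]]
        per_group[name] = top
        for g in top:
            if g not in seen:
                seen.add(g)
                union.append(g)
    return CandidateSelection(per_group=per_group, union=union)


def ddct_relative_expression(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target,test - Ct_ref,test) - (Ct_target,ctrl - Ct_ref,ctrl);
    the fold change is 2^-ddCt, so one extra cycle in the test condition
    (ddCt = 1) halves the inferred expression.
    """
    cts = (ct_target_test, ct_ref_test, ct_target_ctrl, ct_ref_ctrl)
    if not all(math.isfinite(c) for c in cts):
        raise ValueError("all Ct values must be finite")
    ddct = (ct_target_test - ct_ref_test) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
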
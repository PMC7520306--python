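"""End-to-end orchestration: partition → network → propagation → enrichment
→ validation → selection.

Stages communicate only through files in the output directory, so every
intermediate (partition TSV, network edge list, per-group .rnk rankings,
enrichment tables, validation report) is inspectable and any stage can be
re-run from the one before it.  The run report JSON collects node/edge
counts, per-group convergence info, the candidate list and the validation
summary; rerunning an identical config reproduces identical outputs, since
the only randomness (the GSEA permutation null) is seeded from the config.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import genesets, gsea, network, propagation, validation

__all__ = ["PipelineConfig", "DatasetInput", "run_pipeline", "load_config"]


@dataclass(frozen=True)
class DatasetInput:
    """One labeled validation dataset: expression TSV + sample-label TSV."""

    name: str
    expression: Path
    labels: Path


@dataclass(frozen=True)
class PipelineConfig:
    """All inputs and tunables of a full run.

    ``gsea_sets_gmt`` and ``expression`` are optional: without an expression
    matrix the network is PPI-only, and without annotation sets the
    enrichment stage is skipped.
    """

    gene_sets_gmt: Path
    fa_set: str
    hr_set: str
    ppi_sources: tuple[Path, ...]
    outdir: Path
    expression: Path | None = None
    datasets: tuple[DatasetInput, ...] = ()
    gsea_sets_gmt: Path | None = None
    restart: float = 0.7
    tol: float = 1e-6
    max_iterations: int = 1000
    coexpression_cutoff: float = 0.6
    min_sources: int = 2
    gene_cap: int | None = 5000
    gsea_weight: float = 1.0
    gsea_n_perm: int = 1000
    gsea_rng_seed: int | None = None
    test_method: str = "welch"
    k: int = 2

    def rwr_config(self) -> propagation.RWRConfig:
        return propagation.RWRConfig(
            restart=self.restart, tol=self.tol, max_iterations=self.max_iterations
        )

    def validate_paths(self) -> None:
        paths: list[Path] = [self.gene_sets_gmt, *self.ppi_sources]
        if self.expression is not None:
            paths.append(self.expression)
        if self.gsea_sets_gmt is not None:
            paths.append(self.gsea_sets_gmt)
        for ds in self.datasets:
            paths.extend([ds.expression, ds.labels])
        missing = [str(p) for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError("missing input file(s): " + ", ".join(missing))
        if self.gsea_sets_gmt is not None and self.gsea_rng_seed is None:
            raise ValueError("gsea_rng_seed is required when enrichment is requested")


def load_config(path: str | Path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file.

    Relative paths in the file are resolved against the file's directory.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    base = path.parent

    def _p(value: str) -> Path:
        p = Path(value)
        return p if p.is_absolute() else base / p

    inputs = raw.get("inputs", {})
    params = raw.get("params", {})
    datasets = tuple(
        DatasetInput(name=d["name"], expression=_p(d["expression"]), labels=_p(d["labels"]))
        for d in inputs.get("datasets", [])
    )
    return PipelineConfig(
        gene_sets_gmt=_p(inputs["gene_sets_gmt"]),
        fa_set=inputs["fa_set"],
        hr_set=inputs["hr_set"],
        ppi_sources=tuple(_p(p) for p in inputs.get("ppi_sources", [])),
        expression=_p(inputs["expression"]) if inputs.get("expression") else None,
        datasets=datasets,
        gsea_sets_gmt=_p(inputs["gsea_sets_gmt"]) if inputs.get("gsea_sets_gmt") else None,
        outdir=_p(raw["outdir"]),
        **{k: v for k, v in params.items()},
    )


def _config_hash(config: PipelineConfig) -> str:
    blob = repr(config).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages in order; returns (and writes) the run report."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "config_hash": _config_hash(config),
        "stages": {},
    }
    failure_marker = outdir / "FAILED"
    if failure_marker.exists():
        failure_marker.unlink()

    def _stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                elapsed = time.perf_counter() - self_inner.t0
                report["stages"][name] = {"seconds": round(elapsed, 3)}
                if exc is not None:
                    failure_marker.write_text(f"{name}: {exc}\n")
                    (outdir / "report.json").write_text(
                        json.dumps(report, indent=2) + "\n"
                    )
                    raise StageError(name, exc) from exc
                return False

        return _Timer()

    # -- partition ---------------------------------------------------------
    with _stage("partition"):
        sets = genesets.read_gmt(config.gene_sets_gmt)
        partition = genesets.partition_seeds(sets[config.fa_set], sets[config.hr_set])
        genesets.write_partition_tsv(partition, outdir / "seed_partition.tsv")
        report["seed_groups"] = partition.sizes()

    # -- network -----------------------------------------------------------
    with _stage("network"):
        sources = [network.read_edge_tsv(p) for p in config.ppi_sources]
        ppi = network.integrate_ppi(sources, min_sources=config.min_sources)
        if config.expression is not None:
            expr = network.collapse_expression(
                network.read_expression_tsv(config.expression)
            )
            coexpr = network.spearman_coexpression(
                expr, cutoff=config.coexpression_cutoff, gene_cap=config.gene_cap
            )
        else:
            coexpr = network.SourcedEdgeList(frozenset())
        graph, summary = network.merge_networks(ppi, coexpr)
        network.write_network_tsv(graph, outdir / "network_edges.tsv")
        (outdir / "network_summary.json").write_text(
            json.dumps(summary, indent=2) + "\n"
        )
        report["network"] = summary

    # -- propagation -------------------------------------------------------
    rankings: dict[str, propagation.RankedList] = {}
    with _stage("propagation"):
        tm = propagation.column_normalize(graph)
        cfg = config.rwr_config()
        report["propagation"] = {}
        for group, seeds in partition.groups().items():
            if not seeds:
                continue
            annotated = genesets.annotate_seeds(seeds, tm.node_order)
            p0 = propagation.make_seed_vector(annotated, tm.node_order)
            result = propagation.random_walk_restart(tm, p0, cfg, seed_group_name=group)
            ranked = propagation.rank_genes(result, drop_zeros=True)
            rankings[group] = ranked
            slug = group.lower().replace("-", "_")
            propagation.write_rnk(ranked, outdir / f"{slug}.rnk")
            propagation.write_run_metadata(result, cfg, outdir / f"{slug}_run.json")
            report["propagation"][group] = {
                "iterations": result.iterations,
                "converged": result.converged,
                "n_seeds_annotated": len(annotated),
                "n_ranked_nonzero": len(ranked),
            }

    # -- enrichment (optional) --------------------------------------------
    with _stage("enrichment"):
        if config.gsea_sets_gmt is not None:
            annot = genesets.read_gmt(config.gsea_sets_gmt)
            report["enrichment"] = {}
            for group, ranked in rankings.items():
                table = gsea.permutation_pvalues(
                    ranked,
                    dict(annot.items()),
                    n_perm=config.gsea_n_perm,
                    rng_seed=config.gsea_rng_seed,
                    weight=config.gsea_weight,
                )
                slug = group.lower().replace("-", "_")
                table.to_csv(outdir / f"gsea_{slug}.tsv", sep="\t")
                report["enrichment"][group] = {
                    "n_sets": int(len(table)),
                    "n_significant_q05": int((table["q"] < 0.05).sum()),
                }

    # -- selection ---------------------------------------------------------
    with _stage("selection"):
        selection = validation.select_candidates(rankings, k=config.k)
        (outdir / "candidates.txt").write_text(
            "".join(g + "\n" for g in selection.union)
        )
        report["candidates"] = {
            "per_group": selection.per_group,
            "union": selection.union,
            "n_unique": len(selection.union),
        }

    # -- validation (optional) --------------------------------------------
    with _stage("validation"):
        if config.datasets:
            reports: dict[str, pd.DataFrame] = {}
            long_rows = []
            for ds in config.datasets:
                expr = network.collapse_expression(
                    network.read_expression_tsv(ds.expression)
                )
                labels = network.read_labels_tsv(ds.labels)
                res = validation.differential_test(
                    expr, labels, selection.union, method=config.test_method
                )
                reports[ds.name] = res
                for gene, row in res.iterrows():
                    long_rows.append(
                        (gene, ds.name, row["p"], row["direction"], row["tested"])
                    )
            pd.DataFrame(
                long_rows, columns=["gene", "dataset", "p", "direction", "tested"]
            ).to_csv(outdir / "validation_report.tsv", sep="\t", index=False)
            gene_df, group_means = validation.aggregate_neglogp(
                reports,
                selection.union,
                groups={g: genes for g, genes in selection.per_group.items()},
            )
            gene_df.to_csv(outdir / "validation_summary.tsv", sep="\t")
            report["validation"] = {
                "datasets": [ds.name for ds in config.datasets],
                "per_gene_mean_neglog10p": {
                    g: (None if pd.isna(v) else round(float(v), 6))
                    for g, v in gene_df["mean_neglog10p"].items()
                },
                "per_group_mean_neglog10p": {
                    g: (None if pd.isna(v) else round(float(v), 6))
                    for g, v in group_means.items()
                },
            }

    (outdir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
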
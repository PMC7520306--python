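# netwalk

Network-propagation prioritization of platinum-response genes in ovarian
cancer, starting from the two DNA-repair pathways most strongly tied to
platinum sensitivity: homologous recombination (HR) and the Fanconi anaemia
(FA) FANC–BRCA pathway.

Resistance to platinum-based chemotherapy is the main cause of treatment
failure in ovarian cancer, and both HR and FA status modulate how tumours
respond to DNA cross-linking agents. `netwalk` is for computational
biologists who want to rank every gene in a gene–gene network by its
proximity to these pathway genes and then test the top-ranked candidates in
platinum-resistant vs. platinum-sensitive expression cohorts.

## The method

1. **Seed partition.** The HR and FA gene sets (GMT format) are split into
   three disjoint seed groups: HR-only (HO-G), HR∩FA common (HFC-G) and
   FA-only (FO-G).
2. **Integrated network.** A PPI network keeps interactions reported by at
   least 2 source databases; a disease-specific co-expression network
   connects gene pairs with absolute Spearman correlation ≥ 0.6 across
   tumour samples; the two are merged into one undirected graph with
   per-edge provenance.
3. **Random walk with restart.** For each seed group, with `W` the
   column-normalized adjacency matrix and `P0` uniform over the annotated
   seeds, iterate

       P(t+1) = (1 − r) W P(t) + r P0,      r = 0.7

   until the L1 change falls below 1e−6. The steady state `P∞` scores every
   gene; genes are ranked in descending order and zero-score genes dropped.
4. **Enrichment.** The ranked list is characterized by a preranked GSEA:
   running-sum enrichment score, gene-permutation null, Benjamini–Hochberg
   adjusted q-values (all reimplemented here, seedable and exhaustive-null
   capable for exact small cases).
5. **Validation and selection.** The top-k (default 2) genes per seed group
   are tested per cohort with a two-sided Welch t-test between
   platinum-sensitive and platinum-resistant samples; evidence is
   aggregated as the mean of −log10(p) across cohorts.

A synthetic-data module generates every input with planted ground truth
(overlapping gene sets, multi-source edge lists, co-expressed modules,
response cohorts with mean shifts, and a planted-risk-gene benchmark), so
the full pipeline runs and is tested without any external download.

## Worked example

```python
from pathlib import Path
from netwalk.cli import simulate_study
from netwalk.pipeline import PipelineConfig, DatasetInput, run_pipeline

indir = Path("demo/inputs"); indir.mkdir(parents=True, exist_ok=True)
simulate_study(seed=1, n_genes=500, n_samples=50, outdir=indir)

config = PipelineConfig(
    gene_sets_gmt=indir / "gene_sets.gmt",
    fa_set="FA_PATHWAY", hr_set="HR_PATHWAY",
    ppi_sources=tuple(sorted(indir.glob("ppi_db*.tsv"))),
    expression=indir / "expression.tsv",
    datasets=tuple(
        DatasetInput(f"cohort{i}", indir / f"cohort{i}_expression.tsv",
                     indir / f"cohort{i}_labels.tsv")
        for i in range(3)),
    outdir=Path("demo/run"), k=2,
)
report = run_pipeline(config)
print("seed groups:  ", report["seed_groups"])
print("network:      ", report["network"]["n_nodes"], "nodes,",
      report["network"]["n_edges"], "edges")
print("candidates:   ", report["candidates"]["union"])
print("evidence:     ", report["validation"]["per_gene_mean_neglog10p"])
```

prints

```
seed groups:   {'FO-G': 41, 'HFC-G': 15, 'HO-G': 38}
network:       495 nodes, 1209 edges
candidates:    ['G0071', 'G0450', 'G0327', 'G0408', 'G0161', 'G0486']
evidence:      {'G0071': 3.771265, 'G0450': 4.403717, 'G0327': 3.997366, 'G0408': 2.75918, 'G0161': 4.723508, 'G0486': 3.033923}
```

The synthetic FA/HR sets (56 and 53 genes sharing 15) partition into 41
FA-only, 15 shared and 38 HR-only seeds. Six unique candidate genes come
out of the top-2-per-group selection, and each shows strong cross-cohort
differential evidence (mean −log10 p between 2.8 and 4.7) because the
generator plants a sensitive-group expression shift in the pathway genes.
Every intermediate lands in `demo/run/` (`seed_partition.tsv`,
`network_edges.tsv`, one `.rnk` ranking per group, `validation_summary.tsv`,
`report.json`).

The same pipeline is exposed on the command line:

```sh
netwalk simulate --seed 1 --outdir demo/inputs
netwalk partition --gmt demo/inputs/gene_sets.gmt \
    --fa-set FA_PATHWAY --hr-set HR_PATHWAY --out partition.tsv
netwalk run-all --config config.yaml
```

(`build-net`, `propagate`, `gsea`, `validate` and `select` run the
individual stages; see `netwalk --help`.)

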
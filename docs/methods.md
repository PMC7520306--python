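# Methods

## Model and procedure

The pipeline ranks genes by their network proximity to seed genes from the
homologous-recombination (HR) and Fanconi-anaemia (FA) DNA-repair pathways
and validates the top-ranked genes against platinum-response expression
cohorts. Its stages:

**Seed partition.** Given the FA and HR gene sets, the three seed groups are
pure set algebra: HFC-G = FA ∩ HR, FO-G = FA \ HR, HO-G = HR \ FA. Gene
identity is the uppercased symbol string throughout; no alias or identifier
mapping is attempted, which keeps the pipeline deterministic and
download-free but means inputs must already use one symbol namespace.
Seeds absent from the network are dropped with an explicit warning (never
silently), and an empty annotated seed set is an error.

**Integrated network.** The PPI component keeps an interaction when it is
reported by at least `min_sources` (default 2) distinct source databases —
the usual robustness filter for multi-database compendia. The co-expression
component connects gene pairs whose absolute Spearman correlation (average
ranks on ties) across tumour samples reaches `cutoff` (default 0.6); genes
with zero variance are excluded because their rank correlation is
undefined. The merged graph is undirected, simple and unweighted; each edge
keeps a `provenance` tag (`ppi` / `coexpression` / `both`) for audit even
though propagation ignores it. Merged counts report the pair union and the
pair overlap separately rather than assuming the two components are
disjoint. The co-expression universe is configurable (all expressed genes
by default, or restricted to a gene list such as the PPI nodes via the
`genes` argument); the all-pairs scan runs blockwise on the
rank-standardized matrix, with a `gene_cap` guard (default 5,000 genes)
that must be raised deliberately for larger universes — an all-pairs scan
over tens of thousands of genes is a conscious resource decision, not a
default.

**Random walk with restart.** With `W` the column-normalized (degree-
normalized) binary adjacency and `P0` uniform over the annotated seeds,

    P(t+1) = (1 − r) W P(t) + r P0.

Parameters: restart probability `r = 0.7`, convergence when the L1 norm of
`P(t+1) − P(t)` drops below `1e−6`, iteration cap 1000. The map is a
contraction with factor `(1 − r)`, so at the defaults convergence needs at
most ⌈log(tol)/log(1 − r)⌉ + 1 ≈ 13 iterations; the cap only protects
degenerate configurations (e.g. r near 0) and non-convergence is flagged,
not raised. The L1 norm is the natural choice for probability vectors and
is recorded in `RWRConfig` so it is visibly a choice.

*Dangling nodes.* Zero-degree nodes have all-zero columns in `W` and would
leak probability mass. At every step the mass sitting on them is
redistributed through `P0` — algebraically identical to replacing their
columns by `P0` — which preserves sum-to-one exactly (checked to 1e−10 per
iteration in the tests). `closed_form_solve` computes
`r (I − (1 − r) W′)⁻¹ P0` (with `W′` carrying that same column
replacement) as an independent dense-solve oracle; it is restricted to
≤ 2000 nodes and used only for verification, never in the pipeline path.

*Ranking.* Genes are sorted by descending steady-state score with
lexicographic tie-break (so equal-score orderings are reproducible). Genes
with score exactly 0 — nodes unreachable from every seed, e.g. other
connected components — are dropped; no epsilon threshold is applied,
because any positive score, however small, is ranking information.
Propagation runs on the full graph rather than the largest connected
component, and the count of zero-score genes is reported in the run
metadata.

**Enrichment.** The preranked GSEA statistic: walking down the ranking, the
running sum gains `|score|^weight / Σ_hits |score|^weight` at gene-set
members and loses `1/(N − n_hits)` at non-members; the enrichment score is
the signed extreme of the profile. `weight = 1` is the default;
`weight = 0` gives the classic Kolmogorov–Smirnov form, which is invariant
under monotone score transforms. The null permutes gene labels (random
same-size sets from the ranked universe) — the appropriate null for a
preranked list with no sample-level labels. Nominal
`p = (1 + #extreme same-sign null) / (1 + #same-sign null)` with an add-one
pseudocount so p is never 0; `NES = ES / mean(|same-sign null ES|)`;
Benjamini–Hochberg step-up across sets. Null distributions are cached per
overlap size, and the generator seed is mandatory, so results are
bit-reproducible. An `exhaustive` mode enumerates every size-k subset for
exact p on tiny rankings; it doubles as the test oracle.

**Validation.** Per cohort, a two-sided Welch t-test per gene between
sensitive and resistant groups (Wilcoxon rank-sum available via
`method="wilcoxon"`); Welch is the default because cohort group variances
are not assumed equal. The direction is the sign of
mean(sensitive) − mean(resistant). A gene with zero variance in both
groups and equal means gets p = 1 rather than NaN. Evidence aggregates as
the per-gene mean of −log10(p) (base 10, the convention for evidence
plots) over the cohorts where the gene is measured; missing genes reduce
the coverage count instead of erroring, mirroring how probe coverage
differs across microarray platforms. Candidate selection takes the top-k
(default 2) of each seed-group ranking and deduplicates the union
preserving first occurrence. The qPCR helper implements
`2^−ΔΔCt` with ΔΔCt = (Ct_target,test − Ct_ref,test) −
(Ct_target,ctrl − Ct_ref,ctrl).

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of a `SyntheticSpec` (seed included) and
always emit ground truth alongside the data, so downstream tests are
self-grading.

* **Gene sets**: exact sizes and overlap (defaults 56 FA / 53 HR sharing
  15, the seed-pathway arithmetic of the motivating analysis, giving the
  41 / 15 / 38 partition).
* **Expression**: background genes i.i.d. standard normal per sample;
  module genes share a per-sample latent factor with loading ρ, so
  within-module correlation is ~ρ² and controllable. Default 500 genes ×
  50 samples.
* **PPI sources**: a ground-truth edge set at density 0.02 whose edges are
  reported by m distinct databases, m drawn from {1: 0.5, 2: 0.3, 3: 0.2}
  across 3 sources — so the ≥2-source filter has an exactly known right
  answer.
* **Response cohorts**: all genes i.i.d. normal, with effect δ (in
  within-group SD units, default 2; sensitivity analyses use 0 and 3)
  added to designated genes in the sensitive group — the direction
  platinum-sensitivity markers show. Cohort sizes mirror small clinical
  series (the bundled study generator uses 4+4, 16+12 and 18+15).
* **Planted-seed benchmark**: 500 nodes, 20 seeds, 10 planted risk genes;
  risk-to-seed pairs connect at 10× the 0.02 background density. Recovery
  is scored as the planted genes' median rank among non-seed genes.

These are deliberately idealized: normal margins, a single-factor module
model, independent edges, no batch effects, dropout, platform noise or
correlated backgrounds. Passing tests therefore demonstrate that the
*algorithms* are correct and that the pipeline recovers planted structure
under clean conditions — not that the statistical power or the candidate
lists transfer to real microarray/RNA-seq cohorts, where normalization and
confounding dominate.

## Numerical choices and degenerate inputs

* Spearman is computed as Pearson on average ranks, blockwise; the edge
  rule is `|ρ| ≥ cutoff` (ties at the cutoff included).
* Transition columns sum to 1 within 1e−12; seed vectors within 1e−12;
  steady states within 1e−10 (dangling mass reassignment makes this exact
  up to float round-off).
* Walk-vs-solve agreement is verified at tolerance 1e−12, which puts the
  iterate within 1e−8 (L∞) of the fixed point; at the default 1e−6 the
  iterate is within ~4e−7 in L1 of the fixed point — ample for a ranking,
  since swaps would need near-exact score ties.
* BH validates p ∈ (0, 1] and returns q in input order, capped at 1.
* Empty gene sets, empty seed intersections, sub-minimum group sizes,
  non-finite expression values and malformed input lines raise informative
  errors; a gene absent from a validation cohort is data, not an error.

## Problem sizes

Tests and the acceptance script run the whole stack at a 500-gene universe
(≈125k candidate co-expression pairs, ≈1.2k integrated edges), 50
co-expression samples, 200-permutation enrichment nulls over 500 random
sets, and 50 random 30-node graphs for the solver cross-check. These sizes
were chosen so the complete suite executes in well under a minute while
every statistic retains enough resolution for its check (e.g. KS < 0.1 on
500 null p-values); the implementation itself is sparse and handles
substantially larger graphs, with the co-expression `gene_cap` as the only
deliberate speed bump.

## Known limitations

* One symbol namespace is assumed; no HGNC/alias reconciliation.
* Edges are unweighted and undirected; no evidence-weighted walks.
* The enrichment stage offers gene-permutation nulls only (no phenotype
  permutation — there are no sample labels in a preranked list).
* Survival analysis, tumour-vs-normal comparisons and mutation-neighbour
  analyses are out of scope; the validation stage covers two-group
  response cohorts only.
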
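# Methods

## The annotation framework

`atlasmap` transfers cell-type labels from a labelled reference atlas (in
practice an in vivo single-cell dataset) onto a query dataset (an in vitro
differentiation time course) with one-vs-rest logistic regression per
reference cell type:

1. **Stratified split.** Reference cells are partitioned into 70% training /
   30% test, with the proportion enforced within every cell type. The
   per-type training share is `round(0.7 · n)` (half-up), clamped so both
   partitions keep at least one cell of every type.
2. **Per-gene AUC ranking.** For each cell type and each gene, a
   single-covariate logistic regression (type vs rest) is fitted on the
   training partition and scored by the area under the ROC curve of its
   predictions. By default the AUC is computed on pooled out-of-fold
   predictions from a stratified tenfold cross-validation of the training
   cells, which is less optimistic than resubstitution; a resubstitution
   mode is available (`gene_auc_mode="resubstitution"`). Genes are ranked by
   AUC, ties broken by gene id; a constant gene has slope 0 and AUC 0.5.
3. **Gene-count optimization.** For each k in a grid (default 5, 10, 20, 50,
   100, 200, 500; entries above the gene universe are truncated and
   deduplicated) a multivariate model on the top-k ranked genes is fitted on
   the training partition and scored by AUC on the held-out test partition.
   The smallest k attaining the maximum wins.
4. **Final fit.** The classifier with the selected gene count is refitted on
   the full reference (train + test) and stored as genes + coefficients +
   intercept in a versioned JSON bundle.
5. **Projection.** Query cells are scored with
   `logistic(intercept + Σ coefᵍ · expressionᵍ)` on the query's normalized
   values. A model gene missing from the query contributes 0 (absence of
   evidence); a model with under 80% gene coverage triggers a warning, with
   zero coverage an error. Probabilities of the independent per-type models
   are deliberately not renormalized across types.
6. **Cluster labelling.** For any input partition of query cells (e.g. a
   Louvain clustering — the package does not mandate one), each cluster is
   labelled by the model with the highest mean per-cell probability; ties
   break by type-id order and a top-two margin below 0.01 flags the cluster
   as ambiguous. A per-label AUC (that type's probabilities, its cluster(s)
   as positives vs all other query cells) quantifies annotation strength.

The procedure is symmetric: swapping reference and query runs unchanged, so
models trained on the in vitro types can be projected back onto in vivo data.

### Numerical choices

- **Ridge penalty.** An unpenalized fit diverges whenever a good marker
  separates the classes perfectly, which is the expected situation. All
  fits therefore carry a small L2 penalty on the slopes (default `1e-4`,
  intercepts unpenalized), applied directly to the log-normalized inputs —
  no standardization layer, which would have to be stored in the bundle and
  would break the simple projection formula above. At this magnitude the
  bias is negligible (final coefficients agree with an unregularized-style
  IRLS solver to well below 1e-6 on non-separable fixtures).
- **Single-gene fits** are a vectorized damped-Newton solver (one
  2-parameter problem per gene, all genes in parallel); multivariate fits
  use scikit-learn's lbfgs LogisticRegression with `C = 1/ridge_penalty`.
- **AUC** is computed by midranks (the Mann–Whitney normalization; tied
  scores count 1/2) on the *linear predictor*. The sigmoid is a global
  monotone map, so this equals the AUC of the probabilities exactly, while
  avoiding spurious float ties where the sigmoid saturates.
- **Determinism.** One root seed drives the split and all CV fold
  assignments (per-type child seeds via a CRC of the type id), so a fixed
  seed reproduces the serialized bundle bit for bit.

## QC and normalization

Cells are removed when they have fewer than 200 detected genes or when
mitochondrial genes exceed 8.5% of their raw counts; both comparisons are
strict, so a cell at exactly 8.5% (or exactly 200 genes) is retained, and
the mito fraction is computed on raw counts as a share of total counts.
Surviving cells are normalized as `ln(1 + count · 10⁴ / cell_total)`. This
depth-scaled log transform replaces heavier variance-stabilizing
regression: the classifier framework only needs a per-gene signal that is
monotone within each cell, which this supplies with no fitted covariates.
Doublet removal is treated as an upstream concern (the CLI accepts an
exclusion barcode list).

## Lineage-graph consensus

Velocity-style analyses export one directed cell-type graph per sample.
`first_appearance` gives each type the earliest timepoint with at least
`min_cells` (default 10) labelled cells; types never reaching the threshold
have no appearance time. `build_consensus` then:

1. drops edges naming a type without an appearance time (logged);
2. counts each directed edge's prevalence across samples;
3. vetoes any direction whose source first appears *after* its target — a
   progenitor must be observed earlier than or simultaneously with its
   derivative, so contradicted directions are not considered;
4. drops edges below a prevalence floor (default 2 samples);
5. if both directions of a pair survive (only possible between
   simultaneously appearing types), keeps the more prevalent; an exact tie
   drops both, with a logged reason;
6. classes surviving edges **strong** when supported by at least half the
   samples (`strong_fraction = 0.5`, rendered solid in DOT output) and
   **weak** otherwise (dashed).

The temporal veto runs before the prevalence floor and the direction
competition: a contradicted direction is excluded from consideration
altogether rather than being allowed to outvote the temporally sound one.
The prevalence floor and the strong/weak threshold are interpretations of
"most prevalent" and of weak links; both are configurable.

Noise this procedure cannot absorb: with only 5 samples and a 20% chance
each of edge dropout and direction flip, a true edge is correctly oriented
in a given sample with probability 0.8·0.8 = 0.64, so the chance of
reaching the default prevalence floor of 2 is ≈ 0.94 per edge and ≈ 0.65
for a 7-edge tree — exact graph recovery under that much noise needs more
samples (the test suite demonstrates reliable recovery at 10% noise with 8
samples). The temporal-soundness guarantee, by contrast, is structural and
holds at any noise level.

## Composition statistics

`proportions` gives exact per-group counts and percentages (long format,
ready for stacked-area plots). `fold_change` reports larger/smaller with a
direction and rounds to the nearest integer for the conventional "12-fold
decrease" phrasing. `count_difference_test` is a two-sided Welch t-test
(unequal variances not assumed — the robust default when only "t test" is
specified) with Welch–Satterthwaite degrees of freedom; two constant groups
with equal means return t = 0, p = 1 by convention.

## The synthetic-data generator

`generate_atlas_pair` emulates the data regime the framework assumes:

- **Counts**: negative binomial (gamma-Poisson) — the standard model for
  UMI counts — with inverse-dispersion `dispersion` (default 2, a typical
  droplet-data value) and a mean-one lognormal per-cell library-size factor
  (σ = 0.25) around `library_size_mean` (default 5,000).
- **Types and markers**: 10 types × 200 cells × 500 genes by default; each
  type owns 10 disjoint marker genes whose mean is inflated by
  `exp(marker_log_fc)` (default e¹ ≈ 2.7, a clear but realistic marker
  contrast) in its own type. Baseline gene weights are lognormal.
- **Mitochondrial block**: the last 10 genes are flagged `MT-` and their
  weights scaled so the expected per-cell mito fraction equals
  `mito_fraction_mean` (default 5%); sampling noise then produces a tail of
  cells above the 8.5% filter.
- **Query batch effect**: every query gene mean carries an independent
  factor `exp(N(0, batch_log_fc_sd))` (default 0.3, a moderate cross-study
  shift). Query clusters equal the true types; `split_type` optionally
  splits one type's cells into two clusters to stress cluster labelling.
- **Time structure**: types sit on a random lineage tree (each type's
  progenitor is an earlier type); a type first appears at day 3 + 2·depth
  and its cells are sampled uniformly over later timepoints.
  `generate_lineage_series` derives noisy per-sample graphs by dropping
  each true edge with `drop_prob` and flipping retained edges with
  `flip_prob`.

The generator deliberately omits ambient RNA, doublets and cell-cycle
structure (those pipeline stages are out of scope) and gives every type the
same abundance and marker count. Passing tests therefore show that the
framework recovers labels when its own assumptions hold — clean
type-specific markers, shared cell types, moderate multiplicative batch
shift — not that it is robust to contamination, nested subtypes, or types
present in only one dataset.

## Problem sizes used in the checks

End-to-end label-recovery runs use the generator defaults (2,000 cells, 500
genes, 10 clusters) across batch shifts {0, 0.3, 1.0, 3.0}; bidirectional
projection uses a noiseless 6-type × 150-cell pair; oracle-equivalence
checks use 100 random 50-cell fixtures; consensus replication uses 100
seeded series. `scripts/acceptance.py --seed N --out results/acceptance.json`
recomputes all of them from scratch.

## Known limitations

- Per-gene CV AUCs refit every gene in every fold; the vectorized solver
  makes this tractable to a few seconds per type at atlas-subsample scale,
  but the design assumes matrices that fit densely in memory.
- Cluster labelling assigns exactly one type per cluster; mixed clusters
  are only surfaced through the ambiguity flag and a low per-label AUC.
- The consensus module consumes exported edge lists; it does not compute
  RNA velocity or graph abstraction.
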
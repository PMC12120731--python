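# Methods

`betacohort` implements a cross-cohort analysis of pancreatic β-cell
single-cell RNA-seq data: machine-learning donor quality control, robust
differential expression between nondiabetic (ND) and type 2 diabetic (T2D)
β cells, donor-level pseudobulk gene–gene correlation against an anchor gene
(ZNT8, the β-cell zinc transporter, in the motivating analysis), and
anchor-high/low subpopulation composition. Every stage is exercised end to
end on synthetic multi-cohort data with known ground truth, so each method
is validated as a parameter-recovery problem.

## Synthetic multi-cohort generator

`simulate.generate_cohorts` draws negative-binomial counts for several
cohorts of two technologies. Gene-level expected counts factorize as

```
mu[cell, g] = depth[cell] * p[g | donor, cohort, cell type, disease]
counts ~ NB(mu, theta)        (Gamma–Poisson, shared dispersion theta)
```

with relative rates built multiplicatively on the log scale from:

* a gene baseline, log-rate ~ N(0, 1);
* a per-cohort gene bias vector (log-sd 0.3) — a batch effect that makes
  per-cohort (never pooled) DE testing necessary;
* technology: smartseq2 cohorts have 10× the droplet depth (base 3,000 vs
  30,000 expected counts/cell) — plate libraries are much deeper;
* cell type: five islet types (α, β, δ, γ, other) in configurable
  proportions (default 30/45/10/10/5%), each with disjoint marker genes
  (GCG, INS, SST, PPY, REG1A, …) uplifted 20× in their own type;
* disease effects: `n_robust_de_genes` shifted by ±`robust_log2fc` in T2D
  donors of *every* cohort with a consistent sign, plus
  `n_private_de_genes_per_cohort` shifted in exactly one cohort (PreT2D
  donors, when present, receive half the log effect);
* a donor-level hub module: the anchor gene plus
  `n_hub_correlated_genes` partners share a per-donor Gaussian latent
  factor z ~ N(0, `hub_latent_sd`). The loading w is solved from the
  requested pairwise correlation ρ via ρ = w²σ_z² / (w²σ_z² + s²), where
  s = `hub_donor_sd` is the module's independent per-donor log-noise, so
  the donor-level log-expression correlation of any two module genes equals
  ρ by construction (default 0.9);
* a small genome-wide per-donor log-noise (`background_donor_sd`,
  default 0.02). Donor biological variance is deliberately concentrated in
  the hub module: a large genome-wide donor effect makes cell-level DE
  tests respond to donor draws rather than to disease (see *Limitations*);
* donor HbA1c built as 0.8 × (standardized hub donor deviation) + noise,
  i.e. a construction correlation of 0.8 with anchor expression, centred at
  5.4% with 1.3% spread;
* mitochondrial genes (`MT-` prefix, ~2% of the panel, elevated baseline),
  a small fraction of cells with 8× boosted mitochondrial rates, and rare
  "jackpot" cells at 20× depth.

Label-swapped outlier donors are created *after* expression is drawn by
swapping the annotated ND/T2D label, so expression contradicts annotation —
the failure mode donor cross-validation is designed to catch. Ground truth
(gene classes with signs, hub membership and ρ, outlier donors with true
labels, per-cell types, donor covariates) is returned alongside the counts.
Identical configs give byte-identical output (one `numpy` PCG64 stream).

Defaults describe the study conditions: 6 cohorts (every third smartseq2),
10 donors per disease group per cohort, 150–250 cells per donor (droplet
donors must comfortably exceed the 50-β-cell pseudobulk filter), 2,000
genes, 20 robust DE genes at |log2FC| = 1, 30 cohort-private genes per
cohort, 10 hub partners at ρ = 0.9, NB dispersion 2. Donor-to-donor
variance magnitudes are not published quantities; the defaults above are
the package's own choice and are exposed in `SimulationConfig`.

## Cell QC, normalization, annotation

`qc.filter_cells` keeps cells that (i) express **more than** 500 genes,
(ii) have a mitochondrial count fraction **below** 10% (droplet) or 20%
(plate), and (iii) are not in the top 1% of total counts. All three
follow strict inequalities; a cell at exactly 500 genes or exactly the
mitochondrial cutoff is removed. The depth quantile (numpy linear
interpolation) is computed per cohort — cohorts differ in depth by an order
of magnitude — and among cells that already passed the first two filters;
re-filtering with `apply_top_quantile=False` is the idempotent form. Every
input cell's metrics and per-filter verdicts are returned.

`qc.ln_tpm1` computes ln(TPM+1) per cell. Without gene lengths TPM equals
CPM (appropriate for UMI data); per-gene kilobase lengths are accepted for
full-length protocols. Zero-total cells normalize to all-zero rows with a
logged warning.

`qc.assign_cell_types` labels each cell by the arg-max of mean normalized
marker expression per type, with `"unassigned"` on ties or an all-zero best
score. This per-cell rule stands in for cluster-then-annotate; against
generator truth it agrees on ≥ 99% of cells at the default 20× marker
uplift.

## Leave-one-donor-out donor QC

Within each cohort with at least two ND and two T2D donors, each donor's β
cells are held out in turn; a classifier trained on the remaining donors'
cells predicts ND vs T2D, and the donor's score is the fraction of its
cells predicted as its annotated label. Donors scoring **below 0.15** are
flagged as outliers (a donor at exactly 0.15 is retained). PreT2D donors
never enter training and are scored descriptively (fraction predicted
T2D), never flagged.

Design choices:

* **Classifier** — gradient-boosted trees (XGBoost) with fixed, recorded
  hyperparameters (40 trees, depth 3, η = 0.3, hist, single thread);
  `logistic` and `nearest_centroid` are available for fast tests.
* **Features** — the top 200 genes by absolute two-sample t statistic,
  computed on each training fold only (leak-free). Unsupervised dispersion
  ranking on ln(TPM+1) droplet data is dominated by detection noise and
  reliably misses disease-informative genes; it remains available via
  `feature_space="dispersion"`.
* **Class balancing** — training cells are weighted so both classes
  contribute equally: holding out a donor skews the ND/T2D cell ratio,
  which otherwise biases every prediction toward the majority class.
* **Iteration** — flagged donors are removed from all later training pools
  and the affected cohorts re-scored until no new donor is flagged
  (`max_rounds`, default 5; `max_rounds=1` is the plain single pass).
  Two mislabeled donors of the same swap direction in one cohort poison
  each other's training folds; removing the cleanly-flagged one and
  re-scoring catches the masked one. Flags are never revoked; a flagged
  donor's reported accuracy is from the round that flagged it.

**Known limitation.** When mislabeled donors of the same direction make up
a large minority of one class in a cohort (roughly ≥ 40%, e.g. four
same-direction swaps among ten donors), the classifier legitimately
accommodates them and even iterative removal can stall with the remaining
outliers scoring just above the cutoff. Donor QC is a screen, not a proof
of label correctness.

## Hurdle differential expression

Per cohort, each gene's normalized expression is modelled in two parts:
a Bernoulli component for detection (expression > 0) and a Gaussian
component for the positive values. Both are compared to intercept-only
fits by likelihood ratio and the statistics summed, LRT ~ χ² with
df = df_detection + df_magnitude. With a single binary group both LRTs are
closed-form (binomial deviance; m·ln(RSS₀/RSS₁) over the m detected
cells), so the whole cohort is a few vectorized reductions. A degenerate
part — no detection variation pooled, or all detected cells in one group —
contributes 0 with a df reduction; df = 0 reports p = 1. Genes detected in
fewer than 3 cells are dropped before testing and never enter the
multiple-testing correction. Empirical type-I error on null NB data
(2,000 genes, 100 cells/group) sits within [0.035, 0.065] at α = 0.05.

Log2 fold change comes from the magnitude component (difference of group
means over detected cells, ÷ ln 2); when one group has no detected cells it
falls back to all-cell group means with a 0.01 pseudocount and is flagged
(`fc_pseudocount`). Direction is the fold-change sign, ties broken by the
detection-rate difference. The cellular-detection-rate nuisance covariate
is not fitted; testing is always within one cohort, never pooled.

Benjamini–Hochberg (`bh_adjust`) is the textbook step-up with NaN
propagation (NaNs excluded from ranking), applied within cohort. A gene is
**robust** when BH-adjusted p < 0.05 in at least `min_cohorts` (default 4)
cohorts with — by default — the same direction in every cohort where it is
significant; without direction consistency a tied direction vote still
excludes the gene. Genes absent from some cohorts are counted only where
tested.

## Donor pseudobulk and shuffled correlation

β-cell counts are summed per donor and TPM-normalized (rows sum to 10⁶).
Donors enter only with **more than** 50 cells (droplet) or 10 cells
(plate); genes are kept with mean TPM **strictly above** 1 across retained
donors. Correlation is computed on ln(TPM+1) of the pseudobulk.

For each of 10 shuffles, ⌈0.4·N⌉ donors are sampled without replacement;
donors with zero anchor TPM are dropped within the shuffle ("very low
expression" is read minimally as zero anchor expression — the rule is
configurable); a shuffle with fewer than 3 usable donors is skipped. The
reported statistic per gene is the mean Pearson r (and Spearman ρ) over
shuffles — an average over subsamples that tamps down single influential
donors. With `donor_fraction=1, n_shuffles=1` it reduces exactly to the
plain coefficients.

P-values use the t transform of the averaged r with an effective n equal
to the median per-shuffle usable donor count, followed by BH. This is a
pragmatic approximation (the averaged statistic has no simple null); a
donor-label permutation null with fixed subsample index sets
(`permutation_null_pvalues`, 1,000 reps) is provided and used in tests as
the independent check — the two agree at the decision level on donor-level
data. **Caveat:** both assume donors are exchangeable. Pooling donors
across cohorts with batch effects induces real between-cohort correlation
(with 6 cohorts the between-cohort component has ~6 effective
observations); measured on null data, ~21% of genes reach FDR < 0.05 when
6 cohorts are pooled versus 0% within one cohort. Correlation analyses are
therefore best run within cohort or on batch-homogeneous donor pools; the
calibration experiments use a single-cohort pool.

`correlate_covariate` gives the Pearson r of ln(TPM+1) against a donor
covariate (e.g. HbA1c) over pairwise-complete donors with a two-sided
t-distribution p (n ≥ 3 required). `group_cv` reports the coefficient of
variation (sample SD / mean, ddof = 1) of ln(TPM+1) anchor expression
across donors per disease group; a zero-mean group yields NaN with a
warning.

## Median-split subpopulations

Per cohort, β cells are split at the cohort-wide median ln(TPM+1) of the
anchor gene (all disease groups pooled, including PreT2D when present —
a per-group median would force 50/50 by construction). A cell is "high"
strictly above the median; ties fall to "low", so for zero-inflated genes
the high class is strictly expressing. The composition shift is
Δ = P(high | T2D) − P(high | ND) per cohort; cohorts missing either group
are skipped. The split is rank-based, hence invariant to monotone
transforms of expression.

## Pipeline

`run_pipeline` chains simulate (or read) → QC + annotation → donor CV →
per-cohort DE + robust intersection → pseudobulk correlation → median
split, writing TSVs per stage and a manifest with every threshold, seed and
surviving cell/donor/gene count (the filter funnel is asserted monotone).
Identical config + seed reproduces every output byte-for-byte (single
`numpy` generator per stage seed, single-threaded XGBoost). Stage failure
writes a `status.json` naming the stage and preserves earlier outputs. The
CLI (`betacohort simulate|qc|donor-cv|de|correlate|subpop|run-all`) is a
thin wrapper; exit codes are 0/1/2 for ok/validation/runtime.

## Problem sizes in tests

The suite favours the smallest configurations that still exercise each
property: 1–2 cohorts with a few hundred genes for unit tests; the default
6-cohort design (hub module off, so only DE signal is planted) over 10
seeds for DE recovery; 2-cohort runs over 10 seeds for donor-CV recovery;
single-cohort 100-donor pools for correlation fidelity, FDR calibration
and HbA1c recovery; 500 donors with deep per-donor sampling (400–500
cells) for the hub-correlation convergence check, since pseudobulk
counting noise (NB dispersion 2) otherwise attenuates donor-level
correlations by ~0.02–0.03. Each calibration experiment plants only the
signal class it measures.

## Limitations

* Cell-level hurdle DE treats cells as replicates. Strong donor-level
  biology shared across cohorts — exactly what the hub module simulates —
  produces chance group imbalances that replicate across genes of the
  module and can enter the robust set as a block. The cross-cohort
  intersection guards against cohort-private artifacts, not against
  disease-independent donor factors; pseudobulk or mixed-model DE would be
  the remedy and is out of scope here.
* Correlation p-values assume batch-homogeneous donor pools (above).
* The generator does not simulate doublets, ambient RNA, spliced/unspliced
  counts, or realistic batch-integration difficulty; passing tests show
  parameter recovery under the stated generative model, not performance on
  real atlases.
* TPM with equal gene lengths is CPM; full-length plate data should supply
  gene lengths.
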
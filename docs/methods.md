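# Methods

## The scoring model

For a samples × genes matrix with class labels, each gene *i* is scored by
a regularized variance ratio

DCFE_i = Σ_c w_c (μ_ic − μ_i)² / (Σ_c w_c σ_c²(i) + λ·MAD_i + ε),

with class weights w_c = n_c/N, per-class **population** variances σ_c²(i)
(ddof = 0), the grand mean μ_i = Σ_c w_c μ_ic, and MAD_i the median absolute
deviation of the gene over all samples. The numerator is the between-class
variance of the class means under the empirical class mixture; the
denominator is the mixture within-class variance plus a robust-dispersion
penalty. λ (default 0.1) controls how strongly high-dispersion genes are
damped; λ = 0 recovers a weighted Fisher ratio exactly, which is the oracle
the test suite compares against. ε = 1e-12 guards the division when a gene
is constant within every class and has zero MAD; a gene with zero
between-class variance is assigned exactly 0 rather than ε-noise.

The population-variance convention in the denominator follows the mixture
reading of the weighted sum: Σ_c w_c σ_c²(i) is then the expected
within-class variance under the class prior, and the λ = 0 score is
invariant to rescaling a gene (numerator and denominator both scale as s²).
With λ > 0 the score is deliberately *not* scale-invariant — the MAD term
scales as s, so inflating a gene's scale inflates its penalty relative to
its variance ratio, which is the intended robustness behaviour.

The unsupervised component CS_i is the one-way ANOVA F-statistic of gene
*i* across a K-means partition of the samples:

CS_i = [Σ_k n_k (m_k − m)² / (K′−1)] / [Σ_k Σ_j (x_j − m_k)² / (N − K′) + ε],

over the K′ non-empty clusters. Constant genes score 0; perfectly
separated genes with zero within-cluster variance are capped at 1e12 so the
downstream min–max normalization stays finite.

The blended score is sDCFE_i = α·DCFE_i + (1−α)·CS_i with α = 0.7 by
default. The two components live on incommensurate scales (a variance
ratio typically O(1) versus an F-statistic that can reach the hundreds), so
by default each component is min–max normalized across genes before
blending; a constant component maps to all zeros. `component_norm="raw"`
applies the literal weighted sum for users who want the unnormalized
combination. Rankings sort by descending sDCFE with ties broken by
ascending feature id, making the ranking a deterministic function of the
input.

## Clustering choices

`clustering_mode="global"` (default) runs one K-means over samples on the
per-feature z-scored matrix, reading "hidden subtypes" as *sample*
subtypes; all genes are then scored against this single partition.
`per_gene` instead clusters each gene's values in one dimension,
scoring each gene against its own partition — a different, also defensible
reading; both are exposed because the choice genuinely changes what CS
measures. K defaults to the number of classes (e.g. 10 for a ten-type
pancancer task, 2 for binary staging). K-means uses k-means++
initialization, 10 restarts, tolerance 1e-6 and a fixed seed (default 42);
none of these choices are scientific claims, they only pin determinism.

## Cutoff selection

`stability_cutoff` picks a top-k cutoff where both of two curves plateau:
stability(k), the mean pairwise Jaccard similarity of top-k sets across B
stratified 50% subsample rescorings, and cv_accuracy(k), the stratified
k-fold cross-validated accuracy of the nearest-centroid classifier on the
top-k features. The chosen k is the smallest grid point whose next-step
relative gain is below 1% on both curves, falling back to the largest grid
point. Fraction-based cutoffs use ceiling rounding (so 50% of 921 features
keeps 461).

## Preprocessing

Features missing in more than `max_feature_missing_rate` (default 0.5) of
samples are dropped before imputation. KNN imputation (default k = 5) uses
Euclidean distance over mutually observed features, rescaled by the number
of usable coordinates (scikit-learn's `nan_euclidean` convention), and
fills a hole with the mean of the feature over the k nearest samples;
observed cells are returned bit-exact. The variance filter removes
features whose population variance over observed values is exactly zero —
an exact test, since the rule is "zero variance", not "small variance".
The log transform is log2(x + 1); scaling is per-feature z-scoring with
population sd, with sd = 0 features mapped to 0. Scaling statistics learned
on training data can be serialized and re-applied to held-out cohorts.
Aligning a validation cohort to a trained feature list fills absent
features with zeros (count reported) and drops extras, preserving the
trained column order exactly.

## Selection algebra and fusion

Importance ranking wraps an external gradient-boosted-tree fit
(xgboost, optional dependency) and keeps features with total-gain
importance strictly greater than zero, ordered by descending importance;
re-implementing gradient boosting would be out of proportion, so the
module's own logic is the retention rule, the ordering, and the set
algebra. Intersection preserves the first set's order and reports Venn
counts satisfying union = only_A + only_B + shared; the non-redundant union
is first-set order followed by the second set's novel ids. Late fusion
concatenates the selected columns of two omics matrices over the samples
present in both (first matrix's row order), prefixing each column with its
omics tag (`rna:`, `meth:`) so identical ids across omics cannot collide.

## Novelty tiering

The evidence table is a user-supplied binary gene × 6-resource matrix
(four curated driver databases, two association resources); no database is
queried at run time, keeping the module deterministic and offline. The
categorical rule is primary: any curated presence → established, else any
presence → emerging, else novel. Mean presence (the row mean of the six
indicators) is reported alongside; published per-gene means are rounded to
one decimal, half up, which is how a 5-of-6 gene can print as 0.8. The
score bands sometimes quoted for the tiers are ambiguous exactly at 0.5,
which the categorical rule sidesteps.

## Evaluation

The nearest-centroid baseline standardizes features with training-set
statistics, uses per-class mean profiles as centroids, and classifies by
minimal Euclidean distance with ties going to the first class in sorted
order. Confusion matrices are reported raw and row-normalized (zero rows
kept at zero with a warning). Binary precision/recall/F1/accuracy follow
the usual definitions with zero-denominator cases reported as 0 with a
warning. Multiclass MCC uses the covariance-form generalization computed
directly from the confusion matrix. Macro AUC averages per-class
one-vs-rest AUCs computed by the Mann–Whitney rank statistic with ties
averaged (classes absent from the truth are skipped with a warning).
Macro-ECE averages, over classes, Σ_b (n_b/N)·|acc_b − conf_b| with 10
equal-width bins on the one-vs-rest probabilities, skipping empty bins;
the per-bin calibration curves are retained for plotting.

## Synthetic data

`simulate_expression` draws baseline values from Normal(6, noise_sd) on the
log2 scale — i.e. the post-transform regime, so preprocessing's log step is
exercised separately on exponentiated variants — and shifts each of the
`n_informative` planted genes by `effect_size·noise_sd` in one randomly
chosen class (marker-gene structure). An optional disjoint gene block
receives analogous shifts along latent subtypes drawn independently of the
class labels, giving the CS component signal that DCFE cannot see.
Missingness is MCAR, each cell masked independently. Paired two-omics
cohorts are generated from one pooled patient cohort so overlapping samples
keep consistent ids and labels; methylation-like values are a logistic
squash of latent Gaussians into (0, 1). The generator is deterministic
given its seed.

What the generator does **not** emulate: negative-binomial count noise,
gene–gene correlation, batch effects, informative missingness, or realistic
methylation beta-value bimodality. Passing tests therefore demonstrate the
algebraic and statistical correctness of the machinery under idealized
Gaussian classes — not performance claims on real cohorts.

## Problem sizes and defaults used in validation

The validation suite runs at desk scale: oracle-equivalence checks on 100
random 60 × 50 matrices; planted-gene recovery on five simulated cohorts of
200 samples × 1000 genes with 30 planted genes at effect two standard
deviations (four balanced classes of 50, matching the regime the score is
designed for); stability-cutoff checks at 100 samples × 200 genes. These
sizes make the full suite run in seconds while keeping every estimator in
its intended operating range.

## Known limitations

- Global-mode CS reflects whatever structure K-means finds; in data where
  class structure dominates, CS partially duplicates DCFE rather than
  adding orthogonal signal.
- The min–max normalization before blending makes sDCFE values
  cohort-relative; scores are comparable within one ranking, not across
  datasets.
- The KNN imputer operates in memory on dense matrices; cohorts far beyond
  ~10⁴ × ~2×10⁴ will need chunked or approximate imputation.
- The importance adapter exposes only total-gain importances; SHAP or
  permutation importances are out of scope.
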
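# Methods

## Model and procedure

The package treats GRN inference as binary classification of unordered gene
pairs. The full procedure, in order:

1. **Normalization.** Raw RNA-seq counts are normalized within each sample.
   TPM: rate_g = count_g/(length_g/1000), tpm_g = rate_g/Σ rates × 10⁶, so
   each sample column sums to 10⁶. FPKM: fpkm_g = count_g × 10⁹/(length_g ×
   T) with T the column total. The "per million" denominator is the column
   sum of the count matrix — when the pipeline starts from a count matrix
   there is no external mapped-read total, and the effective length is the
   annotated gene length. Within one sample both metrics are count/length
   up to a constant, so they share a rank order. Intensity-scale data
   (microarray or the simulator's output) can be log2-transformed; the flag
   is off at the function level and enabled per run.

2. **Z-scoring.** Every gene row is standardized to mean 0, variance 1
   using the population SD (ddof 0). This convention is load-bearing: it
   makes the (1,1) joint moment of a pair exactly its Pearson correlation.
   Zero-variance genes cannot be standardized and are dropped with a
   recorded exclusion list.

3. **Pair features.** All G(G−1)/2 unordered pairs are enumerated in
   lexicographic order with the smaller gene id as x. For each pair,
   m_{n,m} = (1/S) Σ_s x_sⁿ y_sᵐ over the grid {1..7}², i.e. 49 features.
   The grid starts at order 1 (order-0 terms are constants after
   z-scoring) and {1..7}² is the unique square grid of size 49 consistent
   with m₁,₁ being the correlation. Moments are orientation-dependent
   (m_{n,m} ≠ m_{m,n}); the fixed lexicographic orientation keeps results
   deterministic, and a `symmetrize` flag averages both orientations for
   sensitivity analysis. Computation is chunked (default 8,192 pairs per
   chunk) against a precomputed gene × order × sample power tensor, so
   memory stays bounded; genome-scale tables (~18M pairs) are
   cluster-scale, and desk-scale studies use a few hundred genes.

4. **Standardization and PCA.** Each moment column is scaled to mean 0,
   SD 1 across pairs (population convention; constant columns are zeroed
   with a warning). PCA (scikit-learn, full SVD) on the standardized table
   gives orthonormal loadings; the default keeps 36 components. The PCA is
   fitted on the full candidate-pair table by default — labels are
   assigned afterwards — with the option to restrict fitting to training
   pairs; fitting on all pairs uses no label information, so the leakage
   risk is limited to distributional reuse, and the default mirrors the
   transform-then-label order of the original design. Explained variances
   use the ddof-1 convention of the underlying SVD.

5. **Labels.** Positives are pairs whose unordered form appears in the
   gold standard (the network is treated as undirected). Negatives are the
   k pairs of smallest |m₁,₁| among non-gold pairs (k = 10,000 at genome
   scale), ranked with a stable tie-break on the canonical pair id; gold
   pairs are excluded by default so no pair carries both labels. The
   balanced training matrix samples equal numbers of each class without
   replacement under a recorded seed.

6. **Classifiers.** REWKLR maximizes the concave objective
   J(α,b) = Σᵢ w_{yᵢ}[yᵢ ln pᵢ + (1−yᵢ) ln(1−pᵢ)] − (λ/2)αᵀKα with
   pᵢ = logistic((Kα)ᵢ + b) and K the σ-parameterized RBF Gram matrix, by
   damped Newton iterations (backtracking halving, J never decreases)
   until the (α,b) gradient norm is ≤ tol (default 1e-6, max 100
   iterations, diagonal jitter 1e-8 escalated on singular systems).
   The intercept is unpenalized — without it the weighted base rate cannot
   be matched in the heavy-regularization limit. Non-convergence raises an
   error carrying the final gradient norm rather than returning a dubious
   model. The two-class and one-class SVMs are scikit-learn's SVC and
   OneClassSVM behind thin config/predict wrappers; their γ-parameterized
   kernel and the REWKLR σ-parameterization are both exposed by
   `rbf_kernel`.

7. **Tuning and evaluation.** Hyperparameters are selected on a grid by
   bootstrap resampling: each resample trains in-bag and scores
   out-of-bag, the score being the mean of the two per-class accuracies
   (binary) or positive-class accuracy (one-class); ties take the first
   grid point, so grids list smoother kernels first. ROC and PR curves are
   computed at 101 evenly spaced score-quantile thresholds plus a sentinel
   above the maximum (anchoring (0,0) and (1,1)); per-threshold error bars
   are the SD over 500 bootstrap resamples of the evaluation rows
   (resampling with replacement, not subsampling). AUC is the trapezoidal
   area under the mean curve sorted by FPR; it agrees with the
   Mann–Whitney concordance count to well under 0.01 at n = 10³. One-class
   SVM yields no false-positive rate and is excluded from ROC/PR; it is
   reported by class-1 accuracy.

## Rare-event weighting (τ)

The class weights w₁ = τ/ȳ, w₀ = (1−τ)/(1−ȳ) implement the
weighted-likelihood prior correction for case-control sampling, with τ the
population event prevalence and ȳ the training prevalence. The pipeline
default is τ = "sample" (weights 1): with balanced 1:1 training and a
genome-scale prevalence of ~0.4%, the correction gives w₁ ≈ 0.009, which
shrinks 100 training positives to about one effective observation and
measurably degrades held-out ranking (AUC ~0.99 → 0.85–0.95 across seeds
in the synthetic benchmark). Prior correction is an intercept adjustment
in a correctly specified model; re-weighting an entire kernel fit at
extreme τ/ȳ instead discards the positive class. Users modelling true
prevalence can set `rewklr_tau` to `"gold_prevalence"` or an explicit
value; this mainly lowers posterior probabilities toward the population
rate (affecting 0.5-threshold accuracy, not ranking, when the classes are
separable).

## The synthetic benchmark

`synthetic_grn` draws n_tfs regulators, each with targets_per_tf targets
taken without replacement from the non-TF genes — globally by default, so
every target has exactly one regulator; `allow_shared_targets` relaxes
this (a multiply-regulated target then follows its first-listed regulator)
for configurations that need many gold pairs at desk scale. Per sample,
each regulator has a latent z ~ N(0,1); a target takes f(z) + ε with
ε ~ N(0, noise_sd²) and f drawn per edge from the link mix: linear z,
quadratic z²−1, saturating tanh(2z), repressive −z. Unregulated genes are
independent N(0,1). The latent matrix is exponentiated to a positive
intensity-like scale (hence the pipeline's log-transform for this data;
the dependence lives on the log scale), and `simulate_counts` rounds it to
pseudo-counts with random gene lengths to exercise the TPM/FPKM paths.
Everything is deterministic under the config seed.

Default conditions — 300 genes, 20 TFs × 10 targets, 300 samples, noise
SD 0.3, link mix 50% quadratic with the remainder split over the visible
shapes — define a scaled-down study in which correlation alone is a
deliberately handicapped baseline: quadratic links have |m₁,₁| ≈ 0 but a
strong E[x²y] signature. What the generator does *not* emulate:
combinatorial regulation, negative-binomial count noise, library-size
variation, batch effects, or time-course dynamics. Passing tests
demonstrate that the pipeline recovers the dependence structures it
models, not performance on real RNA-seq.

## Held-out evaluation design

The labeled balanced set is split stratified 50/50 into train/test. Two
complementary views are reported: (i) metrics on the balanced test split
(accuracies, recall/precision, ROC/PR), and (ii) a network-recovery
ranking of held-out gold pairs against 1,000 randomly drawn non-gold,
non-training pairs. The ranking deliberately does not reuse the
lowest-|m₁,₁| pairs as evaluation negatives: those are selected to have
near-zero correlation, which would hand the correlation-only baseline a
near-perfect artifactual AUC. Random candidate pairs are the standard
reference population for GRN benchmarks and make the
moments-vs-correlation comparison meaningful.

## Numerical choices and degenerate inputs

- Population (ddof 0) SD throughout z-scoring and moment standardization;
  PCA explained variance is ddof 1 (SVD convention).
- Stable sorts everywhere a tie-break matters (negative selection, ROC
  sorting); pair order is lexicographic by construction.
- All-zero samples: TPM/FPKM raise by default (configurable zero column).
  All-zero gene rows pass through normalization flagged, and drop at
  z-scoring.
- REWKLR: jitter 1e-8 on the Gram diagonal, escalated ×100 on singular
  Newton systems; objective computed via log_expit for stability.
- Bootstrap resamples missing a class (tuning, curves) are redrawn with a
  capped retry count.
- Sub-seeds for sampling, splitting, tuning, and evaluation are spawned
  from the single run seed (recorded in the report), so runs are
  reproducible end-to-end and byte-identical on rerun.

## Problem sizes

Desk-scale defaults keep the full run in seconds-to-minutes on one CPU:
300-gene benchmark (44,850 pairs × 49 moments, 300 samples), 600-gene
training-matrix demonstration (179,700 pairs, 12,000 gold edges, 20,000 ×
36 matrix), and genome-scale pair enumeration (18,243,820 index pairs)
without feature computation. The genome-scale feature table is the
documented cluster-scale path via chunked moments.

## Known limitations

- Undirected pair classification cannot orient edges; directionality comes
  from the gold standard at export time.
- The lowest-|m₁,₁| negative heuristic biases the negative class toward
  low-dependence pairs; truly dependent but uncataloged pairs may be
  mislabeled in training (the motivation for the one-class option).
- One-class SVM ranks poorly on random candidate pairs in the synthetic
  benchmark (the positive class is multimodal across link kinds, and
  random pairs fall between the modes); it is reported for completeness
  and excluded from ROC by construction.
- Seventh-order moments of heavy-tailed intensity data are noisy at small
  sample counts; the log-transform option and the across-pair
  standardization mitigate but do not remove this.
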
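# Methods

This note documents the models, numerical choices and limitations behind
`lipopanel`. Everything stated here is computed by the test suite or the
acceptance script; nothing is quoted from external results.

## Data model

A cohort is a `LipidFeatureTable`: a samples × features matrix of
non-negative intensities (missing values are explicit NaN, never 0), with
per-feature metadata (ion mode, lipid class, annotation) and per-sample
metadata (group EG = case / CG = control, clinical indexes). Feature ids
follow the `<index><POS|NEG>` convention of untargeted lipidomics exports;
the prefixed dialect (`NEG1033`) is accepted on input and normalized to the
suffix form (`1033NEG`), and two spellings of the same identity in one table
are rejected as duplicates. When LH, FSH and LH/FSH are all present the
ratio column must equal LH ÷ FSH to within 0.1%.

## Synthetic cohort generator

The generator exists because the analysis must be testable against known
ground truth. On the log2 scale each value is

x_ij = μ_j + λ·F_{i,c(j)} + Δ_j·1[case_i] + σ_j·ε_ij,  ε ~ N(0,1)

with per-feature baseline μ_j ~ U(10, 25) (log2 intensity units), noise
σ_j ~ U(0.3, 1.2), a per-sample, per-lipid-class latent factor F with
loading λ = 0.5 (this induces the within-class correlation the class-level
Mantel/Pearson analyses need), and planted shifts Δ: two "strong" features
at Δ = 2.0 and twenty "weak" ones at |Δ| ~ U(0.5, 1.5) with random sign.
Defaults emulate the study design: 152 cases vs 50 controls (the 3:1
imbalance), 1100 features, ~60% positive ion mode, class proportions
dominated by TG/PC/PE.

Design choices worth flagging:

- **Planted features share the mid-range σ (0.75).** If σ were drawn from
  U(0.3, 1.2) for planted features too, a "weak" feature drawing σ = 0.3
  would have a larger effect size (Δ/σ) than a "strong" one, contradicting
  the truth labels and making recovery unscorable. Fixing σ for planted
  features makes the |Δ| ordering the discriminability ordering; all
  unplanted features keep the random σ.
- **Clinical covariates** are Gaussian with group means following the PCOS
  hormonal profile (cases: LH, T, LH/FSH higher; FSH, Age lower; Height,
  Weight, BMI, P, PRL, E2 not shifted); SDs are plausible choices since
  cohort tables usually publish only mean (min, max). LH/FSH and BMI are
  derived, not drawn. Two indexes are linked to lipid classes — LH to the
  PI class factor, T to TG — with correlation ρ = 0.4, giving the Mantel
  stage a detectable signal.
- **Missingness is MNAR**: per feature, values below that feature's
  `missing_rate` (default 2%) quantile are censored, mimicking a detection
  limit. Within a feature, lower values are always likelier to be missing.

What the generator does *not* emulate: retention time/adduct chemistry,
batch and injection-order drift, heavy-tailed or multimodal intensity
distributions, correlated missingness across samples. Tests passing on this
generator therefore certify the statistical machinery, not performance on
any real cohort.

## Preprocessing

Features missing in more than 50% of samples in *both* groups are dropped;
remaining missing values (and exact zeros, which have no logarithm) are
imputed with half the feature's minimum observed positive value — the
standard detection-limit surrogate in metabolomics — and intensities are
log2-transformed. The train/test split is stratified by group with per-group
test counts round(0.25·n) (half-up, so 50 controls give 13); in the pipeline
the two partitions are imputed independently, which at a 2% missing rate is
indistinguishable from train-statistics imputation but keeps the stages
simple. All multivariate models consume log2 intensities; OPLS-DA
additionally autoscales (unit variance) using its own training data.

## Univariate screen

Fold change is the ratio of raw-scale group means (case ÷ control, computed
before the log transform); the per-feature p-value defaults to Welch's
unequal-variance t on log2 intensities (Mann–Whitney by option: exact
enumeration for tie-free samples of ≤ 20, normal approximation with tie
correction otherwise). Multiplicity is handled by Benjamini–Hochberg
(Bonferroni by option). The volcano rule is strict at both thresholds:
FC exactly 2.0 does not pass. A feature whose control mean is zero has an
undefined fold change and never passes.

## OPLS-DA

Single binary response y (CG = 0, EG = 1, centered). After centering and
autoscaling X (constant features dropped with a warning; Pareto or no
scaling by option), each orthogonal component is extracted as: w ∝ X'y;
t = Xw; p = X't/t't; w_o ∝ p − (w'p)w; t_o = Xw_o; p_o = X't_o/t_o't_o;
X ← X − t_o p_o'. One predictive component is then fitted on the filtered
matrix and R2Y is the fraction of the centered-y sum of squares explained by
its regression. Defaults: one orthogonal component (component counts are
rarely reported; configurable).

- **VIP** is computed over the predictive component only:
  VIP_j = √p · |w_j| / ‖w‖, hence Σ VIP² = p exactly. A variant including
  orthogonal components is deliberately not offered: with a single
  predictive component the orthogonal weights carry no class information.
- **Q2** uses stratified k-fold CV (default 7 folds, capped at the minor
  class size): PRESS accumulates out-of-fold squared error of encoded y,
  SS the squared deviation from the training-fold mean; Q2 = 1 − PRESS/SS.
- **Permutation test**: labels are permuted uniformly (default 100
  replicates), Q2 and R2Y are recomputed each time, and
  p = (#{Q2_perm ≥ Q2_obs} + 1)/(n + 1), so the smallest attainable p at
  100 permutations is 1/101 ≈ 0.0099. Under a null generator this p is
  uniform, which the test suite checks via its empirical CDF.

Autoscaling makes every feature contribute equal variance, so Q2 on a full
1100-feature table with ~22 informative features sits well below the Q2 of
a signal-enriched subset; that is a property of the scaling, not a defect.

## Association analyses

Differential features are summed per lipid class on the log2 scale and each
class column standardized (ddof = 1). The Mantel statistic is the Pearson
correlation of the strictly-lower-triangle entries of two distance matrices
— Euclidean (absolute difference, for a single column) on the class
profile, absolute difference on a clinical index — with a two-sided
permutation p, p = (#{|r_perm| ≥ |r|} + 1)/(n_perm + 1) under simultaneous
row/column permutation (default 999). An exact mode enumerating all n!
permutations (p = count/n!, identity included) is available for n ≤ 7 and is
cross-checked in the tests against both an enumeration oracle and
scikit-bio's implementation. Across (class, index) pairs a BH-adjusted
column is appended; the unadjusted p is retained. The metric choices are
this package's own — the Mantel test itself does not prescribe one.

## Ensemble selection

The candidate pool is the union of volcano passes and the top-20 VIP
features. Six selectors re-rank it; five produce rank lists (|Welch t|,
|standardized U|, |log2 FC|, VIP, random-forest impurity importance with
500 seeded trees) converted to Borda rewards (n − rank + 1)/n, and one is
already a [0,1] score (selection frequency of an L1-penalized logistic
model, C = 1, over 50 class-stratified bootstrap resamples). The
comprehensive weight is the mean reward; weight ties break toward the lower
feature index. The selector battery and the mean aggregation are design
choices — "reward features many selectors like" admits many schemes; this
is the simplest auditable one, and the pieces are individually replaceable.

Panel size comes from the AUC-accumulation curve: for k = 1..min(n, 10),
the mean AUC of an unpenalized logistic model over 10×5-fold repeated
stratified CV (splits shared across k, so gains are paired); the selected k
is the first whose gain to k+1 falls below δ = 0.01 — a reproducible
surrogate for eyeballing the elbow of the curve. All selection happens on
the training split only.

## Validation and the diagnostic panel

The chosen markers are validated by repeated stratified CV (5 folds × 20
repeats) of three models: unpenalized logistic regression; random forest
(500 trees, seeded); RBF-SVM with C = 1 and kernel bandwidth
1/(d · mean feature variance), whose decision values are mapped to
probabilities by a logistic link fitted on the training fold (Platt
scaling). Per fold, sensitivity and specificity are taken at the Youden
cutoff derived from that fold's *training* predictions — the held-out fold
never picks its own cutoff.

The panel itself is a maximum-likelihood logistic fit (Newton, tolerance
1e-8, ≤ 100 iterations; complete separation is flagged and the coefficients
capped by a barely-regularized fallback rather than raised). The decision
cutoff maximizes J = sensitivity + specificity − 1 over the training
scores; candidate cutoffs are midpoints between consecutive unique scores
(so a perfect separator yields the midpoint of the gap) plus the two
all-positive/all-negative extremes, with ties broken toward the higher
(more specific) cutoff. Classification is *strictly* p > cutoff; a score
exactly at the cutoff is negative. The expression scale entering the panel
is log2 intensity throughout — worth remembering when scoring external
measurements with `reference_panel()`, whose coefficients are a packaged
constant never claimed to be recoverable from synthetic data.

ROC curves use the full threshold sweep; the trapezoidal AUC equals the
pairwise concordance probability with half credit for ties, and the suite
verifies this identity (and the Youden maximizer) against brute-force
oracles on a thousand random instances each.

## Pipeline determinism and problem sizes

`run_pipeline` derives one sub-2³¹ seed per stage from the master seed via
`numpy.random.SeedSequence.spawn`; every stage is a pure function of
(inputs, config, stage seed) and the whole report reproduces bit for bit.
The test suite runs its heavier simulations at deliberately chosen sizes:
the planted-marker recovery check uses the full default design (202 samples
× 1100 features) over 20 master seeds; permutation-calibration checks use a
40-sample × 60-feature null design over 50 replicates; module tests use
60-sample cohorts. These sizes give the Monte-Carlo assertions comfortable
margins while keeping the default `pytest` run to a few minutes.

## Known limitations

- The ensemble's selector set, reward formula and δ = 0.01 stopping rule are
  one reasonable instantiation of "reward frequently selected features",
  not a canonical algorithm; conclusions about *which* features win can
  shift under other instantiations when candidates are nearly tied.
- OPLS-DA here is single-response, two-class only.
- The generator's Gaussian clinical covariates and log-normal intensities
  are idealizations; no batch effects, QC drift or annotation errors are
  modelled.
- Per-sample normalization (median/total intensity) is not applied by
  default; the preprocessing assumes comparably loaded samples.
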
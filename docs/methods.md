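# Methods

This note records the statistical model behind `lipidsig`, the defaults and
why they were chosen, and the design decisions taken where the underlying
protocol left room.

## Synthetic cohorts

The generator emulates a two-group (control vs cancer) lipidomics study of
the kind used for blood-based breast-cancer biomarker discovery: 256
samples balanced over the groups, 454 lipid species in 15 classes with a
skewed class-size distribution (TG/PC/LPC/PE/SM largest), and matched
EV/plasma measurements of the same subjects.

Log2 abundances follow a one-factor-per-class Gaussian model:

    z_sl = mu_l + delta_l * 1[cancer] + sigma_bio * (sqrt(rho) f_sc(l) + sqrt(1-rho) e_sl)

with per-class factor `f_sc`, within-class correlation `rho`
(default 0.3 — the magnitude of within-class lipid correlation is an
assumption, not an estimate), baseline means `mu_l` spanning ~8 log2 units,
and a planted effect `delta_l` (default log2FC = 1) on `n_informative`
lipids (default 10). Informative lipids are spread over distinct classes
whenever possible so their covariance is diagonal regardless of `rho`.
Measurements add per-(batch, lipid) multiplicative factors with log2 SD
`batch_sd` (default 0.15), technical noise (`sigma_tech_plasma = 0.15`,
`sigma_tech_ev = 0.45`; the EV value is chosen so typical linear-scale
technical CVs exceed 30%, matching the observed poorer EV reproducibility,
while plasma stays well below 30%), and a plasma concentration scale
(default 5x). Group labels are balanced within batches by construction.
QC samples are re-noised technical replicates of one pooled reference
profile per batch (five per batch by default), flagged `qc=True` and
carrying no group label. Tables are emitted on the linear scale; all
effects are specified on the log2 scale.

What the generator does **not** emulate: missing values, censored low
intensities, run-order drift, heteroscedastic ionization effects,
annotation errors, or correlated case/control confounding. Passing tests
therefore demonstrate correctness of the machinery and its calibration
under the stated model, not performance on real clinical data.

**Analytic Bayes AUC.** Under the Gaussian model the optimal rule is
linear and its AUC is `Phi(Delta / sqrt 2)` with `Delta` the Mahalanobis
separation of the group means. With independent informative lipids
`Delta^2 = sum_l delta_l^2 / (sigma_bio^2 + sigma_tech^2 + batch_sd^2)`;
a full covariance can be supplied instead. The batch variance term treats
batch factors as independent noise, which is an approximation when batches
are large; calibration checks are run with `batch_sd = 0`.

## Preprocessing

- **ISTD ratios.** Relative concentration = peak area / class-ISTD area,
  per sample. Zero areas are retained and handled by the pseudo-count at
  the log step (default 2^-20).
- **Log base 2.** The protocol says only "log-transformed"; base 2 makes
  fold-change thresholds (FC > 1.2) read directly off coefficient scales.
- **QC CVs on the linear scale** (SD/mean of replicate concentrations); a
  CV of log values is not a CV. Lipids at CV >= 30% are flagged.
- **Batch normalization = internal reference scaling + median scaling.**
  The IRS factor for (lipid, batch) is the cross-batch geometric mean of
  the pooled-QC batch means divided by that batch's mean, so reference
  means agree exactly across batches after application. The median factor
  then equalizes each biological sample's median of the batch-corrected
  values to the global median of sample medians; QC samples keep factor 1
  because they are the anchor material. Fitting in this order makes
  fit+apply exactly idempotent. (Fitting the sample-median step first and
  the IRS second — the naive reading of "median and internal reference
  scaling" — has no simultaneous fixed point: the two constraint sets
  interact through the piecewise sample median and alternation settles
  into a limit cycle. The chosen order satisfies both constraints exactly
  and is numerically equivalent for batch-effect removal.)

## Differential-abundance panel

Per lipid, an additive fixed-effect linear model on log2 concentrations
(`group` plus cohort/batch blocking dummies; single-level terms dropped)
gives the group coefficient (log2 fold change) and its t/F p-value; an
optional mixed-model variant fits a random batch intercept by REML.
Benjamini–Hochberg adjustment controls FDR. The panel filter is
`q < 0.05` and `max(FC, 1/FC) > 1.2` — direction-agnostic, since both
enriched and depleted lipids are informative — followed by inclusion of
isomer-group mates of selected lipids.

The stepwise restriction is greedy **forward** selection over m/z groups
(a group enters as the set of lipids sharing an m/z value) scored by AIC
of a maximum-likelihood logistic fit; exactly duplicated columns are
dropped from the design so duplicated lipids cannot inflate the parameter
count, and perfect separation falls back to a ridge-penalized likelihood
with a warning.

LOOCV logistic regression scores every sample with the cancer probability
of a model trained on the remaining samples. The decision threshold
maximizes accuracy over midpoints of consecutive sorted unique scores
(with +/-inf sentinels), ties breaking toward the smallest threshold
(favoring sensitivity). Note the threshold is optimized on the same
pooled LOOCV scores it is reported on; this reproduces the emulated
protocol's acknowledged optimism and is flagged here rather than fixed.
AUC uses the Mann–Whitney rank statistic (ties count 1/2). Per-subject
EV/plasma agreement is the Pearson correlation of log2 panel-lipid
profiles (the scale is not dictated by the protocol; log2 matches the
analysis scale).

## Boruta

Each iteration appends one row-permuted shadow per active feature, fits a
forest on the augmented matrix and credits a *hit* to every real feature
whose importance strictly exceeds the maximum shadow importance. After a
burn-in of 5 iterations, accumulated hits are tested each iteration
against Binomial(k, 1/2), two one-sided tests with Bonferroni factor m =
the **initial** feature count (the more conservative reading, since the
protocol does not say whether m shrinks with the active set). Confirmed
features stay in the model with frozen counts; rejected features leave the
model; remaining features are tentative and are **not** selected
downstream. Iteration stops early when nothing is undecided.

Importance backends:

- `permutation_z` (default, mirroring the original accuracy-decrease
  z-scores): a random forest is fit on 70% of the training split and
  permutation importance is measured on the held-out 30%;
  z = mean decrease / SD over repeats.
- `impurity`: sklearn random-forest Gini importance.
- `impurity_fast`: a numba-jitted extremely-randomized forest returning
  normalized Gini-decrease importances (~25 ms per fit on a 205 x 908
  shadow-augmented matrix, about 10x faster than the sklearn forest at
  equal discrimination). Tests verify both impurity backends confirm the
  same planted features.

Defaults follow the emulated protocol (100 iterations, 500 trees,
Bonferroni-adjusted p < 0.01). Resampling loops use the scaled
configuration (40 iterations, 60 trees, `impurity_fast`): the Bonferroni
floor means no decision can fall before ~16 iterations at m = 454, and
planted-feature hit rates ~0.9 reach confirmation comfortably within 40.

## LGOCV ensemble engine

- **Splits**: |test| = round(0.2 n) (so n = 256 gives 51), stratified by
  class with largest-remainder allocation — test class proportions within
  one sample of the cohort's.
- **Nested tuning**: per classifier, `tune_len` random configurations
  scored by mean accuracy over nested stratified 80/20 splits of the
  training split; ties go to the first-drawn candidate; the winner is
  refit on the full training split.
- **Fallback**: an iteration whose Boruta confirms nothing uses all
  features and is flagged; such iterations count in the selection-
  frequency denominator but contribute no selections.
- **Selection frequency**: proportion of iterations a lipid is confirmed;
  ranking by proportion, then mean Boruta importance, then lipid id. The
  top-20 signature is read off this ranking (`top_k` errors when asked
  for more lipids than were ever confirmed unless `strict=False`, which
  fills ranks from the importance tie-break — needed on clean synthetic
  data where only the planted lipids are ever confirmed).
- **Frozen hyperparameters**: within each iteration classifiers are
  ranked by test accuracy (ties share the minimum rank); among the
  iterations where a classifier achieves its best-ever rank, the run with
  the lower-median accuracy is selected (first on ties) and its tuned
  configuration is frozen. The lower-median convention makes the prose
  rule deterministic.
- **Ensemble**: majority vote, ties predicted cancer; the vote fraction
  is the continuous score for per-iteration AUC; the averaged ROC is the
  vertical mean of per-iteration curves on a fixed 101-point FPR grid.
  Certainty: high = unanimous, medium = agreement >= 80%, low otherwise.
- **Sensitivity analysis**: the frozen ensemble is re-evaluated for each
  top-k signature size; the chosen size is the smallest whose median
  accuracy is within 0.5 percentage points of the best median.
- **Classifier suite**: a pluggable registry of eight families —
  regularized logistic regression, shrinkage LDA, RBF and polynomial
  SVMs, random forest, gradient boosting, k-nearest neighbours, Gaussian
  naive Bayes — with a seed-averaged multilayer perceptron available as
  an opt-in ninth. The original 18-model roster cannot be matched
  implementation-for-implementation (several members have no open Python
  equivalent); the ensemble contract is the point and the suite size is
  configurable. SVM scores pass through a logistic squash of the margin
  so every model votes via a score in [0, 1] thresholded at 0.5.

## Compute profiles and problem sizes

Study scale (`full` profile: 2000 LGOCV iterations, 50 nested splits,
500-tree forests) is impractical for routine verification, so the test
suite and `scripts/acceptance.py` run the same algorithms at reduced
scale, chosen once as the package's verification conditions: 100 LGOCV
iterations, 3 nested splits with 2 tuning candidates, the 40-iteration /
60-tree fast-importance Boruta, and the `smoke` classifier-suite sizes.
Calibration quantities (null AUC band, recovery rates, Bayes-gap) were
sized so their Monte-Carlo error is small against the asserted bands
(e.g. the null ensemble AUC mean over 100 iterations has SE ~0.01 against
a +/-0.05 band).

One estimator subtlety: the chance-level AUC of the engine is measured
over several independent zero-effect cohorts rather than by splitting a
single null cohort many times. Conditioned on one finite cohort, the
training-split and held-out class differences are anti-correlated
(sampling without replacement), so a single cohort's mean held-out AUC
sits systematically a few points off 0.5; the expectation over cohorts is
exactly 0.5 by exchangeability.

## Numerical choices and degenerate inputs

- Constant lipid columns: fc = 1, p = 1 with a warning.
- Zero ISTD or non-positive reference means raise data errors rather than
  propagate silently.
- All randomness flows from explicit seeds through named substreams
  (`numpy` `SeedSequence`); repeated runs are bit-identical, and the CLI
  manifest (the only artifact with a timestamp) records a config hash
  that is stable under key reordering.
- Logistic fits use a very weak ridge (C = 1e6) for numerical stability;
  perfect separation therefore yields finite coefficients.

## Known limitations

- The generator's Gaussian/log-normal world is idealized (see above);
  recovery and calibration results bound what the pipeline can do under
  its own assumptions only.
- The LOOCV threshold optimization is optimistically biased by design
  (faithful reproduction; documented above).
- The mixed-model DA variant fits lipid-by-lipid and is slow on
  study-scale tables.
- `permutation_z` importance is the faithful default but is orders of
  magnitude slower than the impurity backends; in-fold use at study scale
  requires the fast backend.
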
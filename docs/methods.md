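# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices, and the limits of what the test suite demonstrates.

## Prediction pipeline

The analysis treats treatment-response prediction as a supervised problem
on n patients × 606 features (11 clinical covariates + 595 rsFC edges from
a 35×35 IC correlation network). The responder label is +1 iff the SID
score improves by ≥ 2 points after treatment; the regression target is the
continuous improvement.

Within every training fold of every cross-validation iteration, three
steps run on the training rows only:

1. per-column standardization (mean/SD of the training rows; zero-variance
   columns pass through with scale 1);
2. Spearman filtering — features with |ρ(feature, label)| ≥ α are
   retained, average ranks for ties, boundary values kept;
3. a linear SVM at C = 1 (libsvm formulation via scikit-learn): hinge-loss
   SVC for the label, ε-insensitive SVR (ε = 0.1, the solver default) for
   the improvement.

Held-out rows are transformed with the training fold's parameters and
never touch selection or fitting; the test suite asserts this exactly by
replacing held-out rows with garbage and requiring bit-identical
selections and weights.

The filter grid is 100 thresholds, 0.005 to 0.5 in steps of 0.005,
constructed from integer multiples of the step so the endpoint is exact.
Grid values are interpreted as minimum |ρ| cutoffs (not p-values): the
operating point α = 0.15 sits naturally on a correlation-magnitude scale,
and a configurable rule (`fixed`, `max_mean_accuracy`, `plateau`) selects
it from a traversal report. Interpreting the grid as p-value cutoffs
remains possible by filtering on a transformed statistic, but is not
implemented as a switch.

Classification metrics are fold-level accuracy/sensitivity/specificity and
tie-corrected rank AUC, averaged over folds within an iteration, then
mean ± SD over iterations. Regression metrics (R², MSE) are computed on
the pooled out-of-fold predictions of each iteration (pooling is the only
way R² is well-defined on 6-subject folds); both conventions are
implemented and switchable (`pooled=`). A fold whose test split contains a
single class records NaN sensitivity/specificity/AUC and is excluded from
the aggregation with a warning. When no feature survives the filter the
fold falls back to an intercept-only model (training majority class /
training mean) so the threshold traversal stays defined at high α.

**Permutation testing.** Each of B replicates permutes the labels and
reruns the *entire* pipeline (fresh fold plan, selection, fitting). The
add-one estimate p = (1 + #{null at least as good})/(1 + B) avoids p = 0;
"significant" means the observed statistic beats the 95th percentile of
the null (5th for lower-is-better statistics such as MSE). Fold plans are
not reused between the observed run and the null replicates: the paper
trail is silent on this, and fresh plans keep the null statistic's
distribution identical to the observed one under exchangeability.

**Consensus features.** Per iteration, the intersection of the 10 folds'
retained sets; the final predictive set is the intersection across all
iterations. "Retained by the fold's trained model" is the operative
notion — support vectors are samples, not features, so stability of the
filter selection is the only coherent per-fold feature event. Weights:
fold weights are averaged within an iteration (only features in every
fold's model have one), and the final weight is the absolute value of the
across-iteration mean — a rule under which sign-alternating features
legitimately cancel toward zero. Consensus sets can only shrink as
iterations are added, which the suite asserts.

**Group comparisons.** "Two-sample t-test with gender as covariate" is
implemented as the regression-adjusted t: OLS of the feature on
(intercept, group, gender), t on the group coefficient with n − 3 df. A
constant gender column is dropped (df n − 2), recovering the classical
pooled-variance t; gender collinear with group is an error. FDR
(Benjamini–Hochberg, two-tailed q = 0.05) is applied across the predictive
set only — those are the hypotheses actually tested. Group tests run on
raw edge values; whether to Fisher-transform first is exposed upstream
(`fisher=` in edge vectorization, off by default since plain correlations
are the primary dialect).

## Synthetic cohort generator

The generator emulates a two-site acupuncture study so that the full
pipeline is testable with known ground truth.

* **Clinical covariates** are truncated normals (age limited to the 18–40
  inclusion band, scale scores to their supports). The published tables
  give only mean ± SD with no distribution family; truncated normal is an
  assumption. The underlying (μ, σ) are *moment-matched* — solved so the
  truncated distribution has exactly the configured mean/SD — because
  naive truncation would inflate disease duration by ~6.5 months (its
  zero bound sits 1.3 SD below the mean) and age/BDI by smaller amounts.
* **Latent propensity** u is the standardized clinical linear predictor
  plus a unit-normal latent connectivity factor. The factor breaks the
  circularity that edges shift with propensity while the outcome depends
  on the edges; with all coefficients zero, u is pure noise.
* **Connectivity**: a block-structured base correlation matrix
  (within-network 0.35, between 0.10 over the SCN/SMN/CCN/DMN partition),
  plus `edge_effect`·u on the planted edges (default 37 edges, a fixed
  reproducible subset), plus symmetric N(0, 0.05) subject noise, projected
  to the nearest valid correlation matrix when indefinite (Higham
  alternating projections, eigenvalue floor 1e-8, one-shot eigenvalue
  clipping as fallback). Planting is continuous in u — no hard
  responder/nonresponder split — so the dichotomized label emerges from
  thresholding the continuous improvement. Note that the projection
  slightly redistributes large planted perturbations into neighboring
  edges; at the default effect size a handful of non-planted edges
  therefore carry real (weak) signal, which bounds attainable consensus
  precision slightly below 1.
* **Outcome**: improvement = 2.4 + 0.8·z(SID) − 0.5·z(duration) +
  0.05·Σ z(planted edges) + N(0, 0.8) SID points. Signs follow the
  established direction of effects (higher baseline SID and shorter
  duration → more improvement); magnitudes were chosen once to give
  ≈ 57% responders at the published cohort size (51/89 in the study),
  planted-edge point-biserial correlations ≈ 0.7 (comfortably above the
  α = 0.15 operating threshold), and baseline SID/duration correlations
  strong enough that both typically join the consensus set — mirroring
  the published 39 = 37 edges + SID + duration structure.
* **Observed scores**: SID_post = max(SID − improvement, 0). The floor
  makes the observed improvement min(improvement, SID), which couples a
  label computed from observed scores to baseline SID even under a null
  model (induced |r| ≈ 0.16 at the published SID distribution). The
  ground-truth record therefore stores the latent improvement, and
  synthetic-cohort analyses label from it (`labels_from_improvement`),
  which is exactly independent of every feature under the null;
  `assign_labels(baseline, post)` applies the observed-score rule for
  real data, and the two agree except where the floor binds.
* **Time series**: T×35 zero-mean Gaussian draws with the subject's
  target correlation (eigenfactor transform), T = 180 by default — a
  typical resting-state scan length at common repetition times. No
  hemodynamic filtering or temporal autocorrelation is simulated.
* **Motion**: bounded Gaussian random walks rescaled to mean FD 0.08 mm
  (clean, every rule passes with margin) or 0.35 mm (violating, the
  mean-FD rule fails by construction); the violating fraction is
  configurable and 0 by default, since the study-sized cohorts model the
  post-QC sample.

`null_config()` zeroes every feature coefficient and the edge effect but
keeps an intercept of 2 SID points so the labels stay balanced — the
condition under which chance-band and type-I checks are meaningful.

## Problem sizes used in the checks

The suite runs reduced but statistically meaningful sizes, chosen as the
package's own test design: calibration at the published n = 89;
signal recovery at n = 200 with 20 CV iterations through the full
time-series path, validated externally on an independently seeded n = 58
cohort (B = 99); type-I control over 200 null cohorts of n = 60 with the
11 clinical features plus 100 edges, 5-fold CV, B = 200 permutations
each; SVM objective checks on 50 tiny instances against a direct SLSQP
quadratic-programming solution of the primal.

## What passing tests do and do not show

The generator's cohorts are Gaussian, temporally white, and carry a
single planted mechanism. Passing tests demonstrate that the pipeline is
correctly implemented (leak-free, calibrated under the null, able to
recover a planted signature and transfer it across sites, with every
statistical primitive matching an independent oracle). They do not
demonstrate that real acupuncture response in FD is predictable at any
particular accuracy: real rsFC has autocorrelation, site effects,
non-Gaussian tails and confounders the generator deliberately omits.

## Known limitations

* Only the linear SVM family ships; the learner interface (`task`,
  `fit_fold`) is pluggable but alternative classifiers/regressors are out
  of scope.
* Group ICA is consumed, not estimated: inputs begin at IC time series.
* Exclusion is subject-level; no frame censoring/scrubbing.
* The FD threshold unit is taken as mm (the convention at a 0.2 cutoff);
  rotation input units default to radians (SPM rp-file dialect) with a
  degree switch.
* Consensus extraction requires the CV report to have been run with
  selection/weight storage at the operating threshold; storing the full
  100-threshold traversal at 100 iterations is memory-hungry and off by
  default.
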
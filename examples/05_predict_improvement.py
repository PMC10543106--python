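"""Predict the continuous SID improvement with epsilon-insensitive SVR.

Selects predictive features on a strong-signal cohort, then evaluates a
linear SVR under repeated 10-fold CV (R-squared and MSE on pooled
out-of-fold predictions) with a permutation test on R-squared.
"""

from acupredict import cv_engine as cv
from acupredict import syncohort as sc
from acupredict.selection_model import ThresholdGrid

cohort = sc.generate_cohort(sc.training_config(n_subjects=200, seed=11))
features = cohort.features(source="timeseries")
labels = cv.labels_from_improvement(cohort.truth.improvement)

# consensus features from a short classification run
clf_report = cv.run_repeated_cv(features, labels, ThresholdGrid((0.15,)),
                                n_folds=10, n_iterations=10, master_seed=5,
                                store_selection=True, store_weights=True)
consensus = cv.extract_consensus(clf_report, 0.15)
print(f"{consensus.size} predictive features feed the regression model")

X = features.restrict(consensus.feature_ids)
svr_report = cv.run_repeated_cv(X, labels, None, n_folds=10, n_iterations=20,
                                task="svr", master_seed=8)
r2_m, r2_sd = svr_report.summary()["r2"]
mse_m, mse_sd = svr_report.summary()["mse"]
print(f"R^2 = {r2_m[0]:.3f} +/- {r2_sd[0]:.3f}, "
      f"MSE = {mse_m[0]:.3f} +/- {mse_sd[0]:.3f} (SID points^2)")

perm = cv.permutation_test(X, labels, None, statistic="r2", task="svr",
                           B=99, n_folds=10, n_iterations=2, master_seed=8)
print(f"permutation p(R^2) = {perm.p_value:.3f} "
      f"({'significant' if perm.significant else 'not significant'})")
# R^2 > 0 means the signature explains real variance in how much each
# patient's dyspepsia score improves, beyond predicting the mean.
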
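"""Shared fixtures: small synthetic cohorts and a full signal-recovery run.

Session-scoped so the expensive end-to-end artifacts (the n=200
strong-signal cohort and its consensus extraction) are computed once and
shared between the unit, reporting and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from acupredict import cv_engine as cv
from acupredict import syncohort as sc
from acupredict.selection_model import ThresholdGrid

OPERATING_THRESHOLD = 0.15


@pytest.fixture(scope="session")
def train89():
    """Training-style cohort at the published size (n=89)."""
    return sc.generate_cohort(sc.training_config(n_subjects=89, seed=1))


@pytest.fixture(scope="session")
def signal_cohort():
    """Strong-signal cohort: 37 planted edges, n=200, full effect sizes."""
    return sc.generate_cohort(sc.training_config(n_subjects=200, seed=11))


@pytest.fixture(scope="session")
def signal_features(signal_cohort):
    """606-column features built through the full time-series path."""
    return signal_cohort.features(source="timeseries")


@pytest.fixture(scope="session")
def signal_labels(signal_cohort):
    return cv.labels_from_improvement(signal_cohort.truth.improvement)


@pytest.fixture(scope="session")
def signal_report(signal_features, signal_labels):
    """20-iteration 10-fold CV at the 0.15 operating threshold, with the
    selection sets and fold weights needed for consensus extraction."""
    return cv.run_repeated_cv(
        signal_features, signal_labels, ThresholdGrid((OPERATING_THRESHOLD,)),
        n_folds=10, n_iterations=20, task="svc", master_seed=5,
        store_selection=True, store_weights=True)


@pytest.fixture(scope="session")
def signal_consensus(signal_report):
    return cv.extract_consensus(signal_report, OPERATING_THRESHOLD)
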
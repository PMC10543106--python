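"""Filter-based feature selection and linear support-vector models.

Selection is univariate "filtering": the Spearman rank correlation between
each feature and the label, computed on training rows only, with a feature
retained when |rho| meets the threshold.  The threshold grid of 100 values
from 0.005 to 0.5 (step 0.005) is traversed to locate an operating point.
Models are soft-margin linear SVMs at C = 1 (libsvm formulation): SVC for
the responder label, epsilon-insensitive SVR for continuous improvement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.svm import SVC, SVR

__all__ = [
    "ThresholdGrid", "SelectionResult", "LinearModel",
    "make_grid", "spearman_rho", "spearman_filter",
    "train_svc", "train_svr", "predict", "decision_values",
    "svc_objective", "svr_objective", "save_model", "load_model",
]


@dataclass(frozen=True)
class ThresholdGrid:
    """Strictly increasing filter thresholds."""
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size == 0:
            raise ValueError("empty threshold grid")
        if np.any(np.diff(v) <= 0):
            raise ValueError("thresholds must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)

    def __getitem__(self, k):
        return self.values[k]


def make_grid(start: float = 0.005, stop: float = 0.5,
              step: float = 0.005) -> ThresholdGrid:
    """Inclusive arithmetic threshold grid; defaults give the canonical
    100-point sweep 0.005, 0.010, ..., 0.500.

    Grid points are built from integer multiples of the step (not by
    accumulation), so the endpoint is always present exactly.
    """
    if not (0 < start <= stop):
        raise ValueError("need 0 < start <= stop")
    if step <= 0:
        raise ValueError("step must be positive")
    n = int(round((stop - start) / step))
    if abs(start + n * step - stop) > 1e-9:
        raise ValueError("step does not evenly divide [start, stop]")
    vals = np.round(start + step * np.arange(n + 1), 12)
    vals[-1] = stop
    return ThresholdGrid(tuple(float(v) for v in vals))


@dataclass
class SelectionResult:
    threshold: float
    retained: np.ndarray        # column indices, ascending
    rho: np.ndarray             # per-feature Spearman rho (signed)
    feature_ids: list[str] | None = None

    def retained_ids(self) -> list[str]:
        if self.feature_ids is None:
            raise ValueError("selection carries no feature ids")
        return [self.feature_ids[k] for k in self.retained]


def spearman_rho(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman correlation of every column of X with y (average ranks
    for ties; constant columns get rho = 0).

    Vectorized: rank-transform once, then Pearson on ranks via one matrix
    product — the filter sits in the cross-validation hot loop.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n = X.shape[0]
    if n != y.shape[0]:
        raise ValueError("X and y disagree on sample count")
    if n < 3:
        raise ValueError("need at least 3 training rows")
    if np.all(y == y[0]):
        raise ValueError("labels are constant: the filter is undefined")
    rx = rankdata(X, axis=0)
    ry = rankdata(y)
    rx = rx - rx.mean(axis=0)
    ry = ry - ry.mean()
    sx = np.sqrt((rx ** 2).sum(axis=0))
    sy = np.sqrt((ry ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ry @ rx) / (sx * sy)
    rho[sx == 0] = 0.0
    return rho


def spearman_filter(X: np.ndarray, y: np.ndarray, threshold: float,
                    feature_ids: Sequence[str] | None = None) -> SelectionResult:
    """Retain features with |rho| >= threshold (boundary kept)."""
    rho = spearman_rho(X, y)
    retained = np.flatnonzero(np.abs(rho) >= threshold)
    return SelectionResult(float(threshold), retained, rho,
                           list(feature_ids) if feature_ids is not None else None)


@dataclass
class LinearModel:
    """Primal view of a fitted linear SVM over the retained columns."""
    kind: str                   # "svc" | "svr"
    weights: np.ndarray
    bias: float
    C: float = 1.0
    epsilon: float | None = None
    feature_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("svc", "svr"):
            raise ValueError("kind must be 'svc' or 'svr'")
        if self.C <= 0:
            raise ValueError("C must be positive")
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if self.feature_ids is not None and len(self.feature_ids) != self.weights.size:
            raise ValueError("feature_ids length does not match weights")


def _check_Xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on sample count")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in training data")
    return X, y


def train_svc(X: np.ndarray, y: np.ndarray, C: float = 1.0,
              feature_ids: Sequence[str] | None = None,
              tol: float = 1e-3) -> LinearModel:
    """Soft-margin linear SVC (libsvm) on +/-1 labels.

    ``tol`` is the solver stopping tolerance; tighten it when comparing
    objective values against a reference solution."""
    X, y = _check_Xy(X, y)
    classes = np.unique(y)
    if not np.all(np.isin(classes, (-1, 1))):
        raise ValueError("SVC labels must be +/-1")
    if classes.size < 2:
        raise ValueError("SVC needs both classes in the training data")
    svc = SVC(kernel="linear", C=C, tol=tol)
    svc.fit(X, y)
    w = svc.coef_[0].copy()
    b = float(svc.intercept_[0])
    return LinearModel("svc", w, b, C=C,
                       feature_ids=list(feature_ids) if feature_ids is not None else None)


def train_svr(X: np.ndarray, y: np.ndarray, C: float = 1.0,
              epsilon: float = 0.1,
              feature_ids: Sequence[str] | None = None,
              tol: float = 1e-3) -> LinearModel:
    """Epsilon-insensitive linear SVR (libsvm)."""
    X, y = _check_Xy(X, y)
    if X.shape[0] < 3:
        raise ValueError("SVR needs at least 3 training rows")
    svr = SVR(kernel="linear", C=C, epsilon=epsilon, tol=tol)
    svr.fit(X, y)
    w = svr.coef_[0].copy()
    b = float(svr.intercept_[0])
    return LinearModel("svr", w, b, C=C, epsilon=epsilon,
                       feature_ids=list(feature_ids) if feature_ids is not None else None)


def decision_values(model: LinearModel, X: np.ndarray) -> np.ndarray:
    """w . x + b for each row."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != model.weights.size:
        raise ValueError(
            f"X has {X.shape[1]} columns but the model was trained on "
            f"{model.weights.size} retained features")
    return X @ model.weights + model.bias


def predict(model: LinearModel, X: np.ndarray) -> np.ndarray:
    """Class labels (+/-1, ties to +1) for SVC; real predictions for SVR."""
    d = decision_values(model, X)
    if model.kind == "svc":
        return np.where(d >= 0, 1, -1)
    return d


def svc_objective(w: np.ndarray, b: float, X: np.ndarray, y: np.ndarray,
                  C: float) -> float:
    """Primal objective 0.5 ||w||^2 + C sum hinge(y (w.x + b))."""
    w = np.asarray(w, dtype=float).ravel()
    margins = y * (X @ w + b)
    return 0.5 * float(w @ w) + C * float(np.clip(1 - margins, 0, None).sum())


def svr_objective(w: np.ndarray, b: float, X: np.ndarray, y: np.ndarray,
                  C: float, epsilon: float) -> float:
    """Primal objective 0.5 ||w||^2 + C sum max(0, |y - w.x - b| - eps)."""
    w = np.asarray(w, dtype=float).ravel()
    resid = np.abs(y - (X @ w + b))
    return 0.5 * float(w @ w) + C * float(np.clip(resid - epsilon, 0, None).sum())


# --------------------------------------------------------------------------
# serialization

def save_model(model: LinearModel, path: str | Path,
               center: np.ndarray | None = None,
               scale: np.ndarray | None = None) -> None:
    """Write a model (and optional standardization parameters) as JSON."""
    doc = {
        "kind": model.kind, "C": model.C, "epsilon": model.epsilon,
        "bias": model.bias, "weights": model.weights.tolist(),
        "feature_ids": model.feature_ids,
        "center": None if center is None else np.asarray(center).tolist(),
        "scale": None if scale is None else np.asarray(scale).tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path) -> tuple[LinearModel, np.ndarray | None, np.ndarray | None]:
    doc = json.loads(Path(path).read_text())
    model = LinearModel(doc["kind"], np.asarray(doc["weights"], float),
                        float(doc["bias"]), C=float(doc["C"]),
                        epsilon=doc["epsilon"], feature_ids=doc["feature_ids"])
    center = None if doc["center"] is None else np.asarray(doc["center"], float)
    scale = None if doc["scale"] is None else np.asarray(doc["scale"], float)
    return model, center, scale
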
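"""Predictive-feature weights, network-scale aggregation and
covariate-adjusted group comparisons.

Each predictive feature's final weight is the absolute value of its mean
signed SVM weight over the cross-validation iterations (fold weights
averaged within an iteration first).  Edge weights are then summed into a
4x4 network-pair matrix over SCN/SMN/CCN/DMN.  Responder-vs-nonresponder
differences on the predictive features are tested with a two-sample
comparison adjusted for gender (OLS with a group indicator and the gender
covariate), Benjamini-Hochberg corrected across the predictive set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .connectome import NETWORKS, Feature, default_partition, validate_partition
from .cv_engine import ConsensusSet

__all__ = [
    "aggregate_weights", "network_weights", "adjusted_group_test",
    "group_comparison", "fdr_correct", "write_report", "read_report",
]


def aggregate_weights(consensus: ConsensusSet) -> pd.DataFrame:
    """Rank predictive features by |mean-over-iterations signed weight|.

    Returns a frame with one row per consensus feature: the mean signed
    weight across iterations, the final (absolute) weight, and the
    descending-weight rank.  Sign cancellation across iterations is a
    property of this rule: a feature whose fold weights alternate in sign
    can end with weight ~0.
    """
    if consensus.size == 0:
        raise ValueError("consensus set is empty: nothing to aggregate")
    trace = np.asarray(consensus.weight_trace, dtype=float)
    if trace.shape[1] != consensus.size or not np.all(np.isfinite(trace)):
        raise ValueError("weight trace incomplete for the consensus set")
    mean_signed = trace.mean(axis=0)
    final = np.abs(mean_signed)
    order = np.argsort(-final, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(1, final.size + 1)
    ids = (consensus.feature_ids if consensus.feature_ids is not None
           else [str(k) for k in consensus.feature_indices])
    return pd.DataFrame({
        "feature_id": ids,
        "column": consensus.feature_indices,
        "mean_signed_weight": mean_signed,
        "weight": final,
        "rank": rank,
    })


def network_weights(summary: pd.DataFrame, registry: Sequence[Feature],
                    partition: Mapping[int, str] | None = None,
                    ) -> tuple[pd.DataFrame, float]:
    """Sum predictive-edge weights into the 4x4 network-pair matrix.

    Clinical features are excluded from the matrix; their summed weight is
    returned separately.  Conservation holds: the matrix total (counting
    each off-diagonal cell once) equals the summed edge weights.
    """
    partition = dict(partition) if partition is not None else default_partition()
    validate_partition(partition)
    reg = {f.feature_id: f for f in registry}
    mat = pd.DataFrame(0.0, index=list(NETWORKS), columns=list(NETWORKS))
    clinical_total = 0.0
    for _, row in summary.iterrows():
        feat = reg.get(row["feature_id"])
        if feat is None:
            raise KeyError(f"feature '{row['feature_id']}' not in registry")
        if feat.kind == "clinical":
            clinical_total += float(row["weight"])
            continue
        i, j = feat.endpoints
        a, b = partition[i], partition[j]
        mat.loc[a, b] += float(row["weight"])
        if a != b:
            mat.loc[b, a] += float(row["weight"])
    return mat, clinical_total


def adjusted_group_test(values: np.ndarray, responder: np.ndarray,
                        gender: np.ndarray) -> tuple[float, float]:
    """Two-sample comparison of one feature adjusted for gender.

    OLS of the feature on (intercept, responder indicator, gender); the
    returned t and two-tailed p belong to the group coefficient (df =
    n - 3).  A constant gender column is dropped (df = n - 2), recovering
    the classical pooled-variance two-sample t.  A gender column collinear
    with the group indicator is an error.
    """
    v = np.asarray(values, dtype=float).ravel()
    r = np.asarray(responder).ravel()
    g = np.asarray(gender, dtype=float).ravel()
    if not (v.size == r.size == g.size):
        raise ValueError("values, responder and gender differ in length")
    if v.size <= 3:
        raise ValueError("need more than 3 subjects")
    grp = (r == 1).astype(float)
    if grp.min() == grp.max():
        raise ValueError("both responder groups must be present")
    cols = [np.ones_like(v), grp]
    if g.min() != g.max():
        resid = g - np.column_stack(cols) @ np.linalg.lstsq(
            np.column_stack(cols), g, rcond=None)[0]
        if np.max(np.abs(resid)) < 1e-10:
            raise ValueError("gender is collinear with the responder group; "
                             "the adjusted comparison is not identified")
        cols.append(g)
    design = np.column_stack(cols)
    fit = sm.OLS(v, design).fit()
    return float(fit.tvalues[1]), float(fit.pvalues[1])


def fdr_correct(p_values: np.ndarray, q: float = 0.05
                ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and significance flags.

    Adjusted p = min over k' >= k of (m * p_(k') / k'), capped at 1;
    significant iff adjusted p < q.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, p_adj < q


def group_comparison(X: np.ndarray, feature_ids: Sequence[str],
                     responder: np.ndarray, gender: np.ndarray,
                     q: float = 0.05) -> pd.DataFrame:
    """Gender-adjusted responder-vs-nonresponder test per predictive
    feature, BH-corrected across the tested (predictive) set only."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != len(feature_ids):
        raise ValueError("X columns and feature_ids disagree")
    t_stats, p_vals = [], []
    for k in range(X.shape[1]):
        t, p = adjusted_group_test(X[:, k], responder, gender)
        t_stats.append(t)
        p_vals.append(p)
    p_adj, sig = fdr_correct(np.asarray(p_vals), q=q)
    direction = np.where(np.asarray(t_stats) >= 0,
                         "responders_higher", "responders_lower")
    return pd.DataFrame({
        "feature_id": list(feature_ids),
        "t": t_stats, "p": p_vals, "p_fdr": p_adj,
        "significant": sig, "direction": direction,
    })


# --------------------------------------------------------------------------
# report bundle

_SECTIONS = ("qc", "cv_summary", "permutation", "consensus_features",
             "network_weights", "group_stats", "config")


def write_report(out_dir: str | Path, *,
                 qc: pd.DataFrame | None = None,
                 cv_summary: pd.DataFrame | None = None,
                 permutation: Mapping | None = None,
                 consensus_features: pd.DataFrame | None = None,
                 network_matrix: pd.DataFrame | None = None,
                 clinical_weight_total: float | None = None,
                 group_stats: pd.DataFrame | None = None,
                 operating_threshold: float | None = None,
                 config: Mapping | None = None) -> Path:
    """Emit the versioned JSON + TSV analysis bundle.

    Missing sections are recorded as absent rather than failing, so a
    partial run still leaves a readable report.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    present = {}
    tables = {"qc": qc, "cv_summary": cv_summary,
              "consensus_features": consensus_features,
              "network_weights": network_matrix, "group_stats": group_stats}
    for name, frame in tables.items():
        present[name] = frame is not None
        if frame is not None:
            frame.to_csv(out_dir / f"{name}.tsv", sep="\t",
                         index=name == "network_weights",
                         float_format="%.17g")
    doc = {
        "report_version": 1,
        "sections_present": present,
        "operating_threshold": operating_threshold,
        "clinical_weight_total": clinical_weight_total,
        "permutation": dict(permutation) if permutation is not None else None,
        "config": dict(config) if config is not None else None,
    }
    (out_dir / "report.json").write_text(json.dumps(doc, indent=1, default=_json_default))
    return out_dir


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def read_report(out_dir: str | Path) -> dict:
    """Round-trip read of a bundle written by :func:`write_report`."""
    out_dir = Path(out_dir)
    doc = json.loads((out_dir / "report.json").read_text())
    out = {"meta": doc}
    for name, present in doc["sections_present"].items():
        if present:
            out[name] = pd.read_csv(out_dir / f"{name}.tsv", sep="\t",
                                    index_col=0 if name == "network_weights" else None)
    return out
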
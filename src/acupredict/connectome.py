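"""Individual functional-network construction and feature assembly.

The analysis represents each patient's resting-state brain as a 35x35
correlation matrix over independent components (ICs) grouped into four
canonical networks — subcortical (SCN, 6 ICs), sensorimotor (SMN, 10),
cognitive control (CCN, 10) and default mode (DMN, 9).  The strict upper
triangle of that matrix (595 edges) plus 11 clinical covariates gives the
606-column feature table consumed by the prediction pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

N_COMPONENTS = 35
N_EDGES = N_COMPONENTS * (N_COMPONENTS - 1) // 2  # 595

#: Clinical feature columns, in canonical order.  Demographics, baseline
#: dyspepsia metrics, baseline emotional scales, plus disease duration.
CLINICAL_FEATURES: tuple[str, ...] = (
    "gender", "age", "weight", "height", "duration",
    "SID", "NDSI", "NDLQI", "SAS", "SDS", "BDI",
)

NETWORKS: tuple[str, ...] = ("SCN", "SMN", "CCN", "DMN")


def default_partition() -> dict[int, str]:
    """Component -> network map with the canonical 6/10/10/9 split.

    Components are 1-based: 1-6 SCN, 7-16 SMN, 17-26 CCN, 27-35 DMN.
    """
    part: dict[int, str] = {}
    for c in range(1, 7):
        part[c] = "SCN"
    for c in range(7, 17):
        part[c] = "SMN"
    for c in range(17, 27):
        part[c] = "CCN"
    for c in range(27, 36):
        part[c] = "DMN"
    return part


def validate_partition(partition: Mapping[int, str]) -> None:
    if sorted(partition) != list(range(1, N_COMPONENTS + 1)):
        raise ValueError("partition must map components 1..35 exactly")
    bad = {v for v in partition.values()} - set(NETWORKS)
    if bad:
        raise ValueError(f"unknown network labels: {sorted(bad)}")


def edge_pairs() -> list[tuple[int, int]]:
    """Strict upper-triangle (i, j) pairs in row-major order, 1-based."""
    return [(i, j) for i in range(1, N_COMPONENTS + 1)
            for j in range(i + 1, N_COMPONENTS + 1)]


def edge_id(i: int, j: int) -> str:
    if not (1 <= i < j <= N_COMPONENTS):
        raise ValueError(f"invalid edge ({i}, {j}): need 1 <= i < j <= {N_COMPONENTS}")
    return f"rsfc_{i:02d}_{j:02d}"


def edge_index(i: int, j: int) -> int:
    """Position of edge (i, j) in the canonical length-595 vector."""
    if not (1 <= i < j <= N_COMPONENTS):
        raise ValueError(f"invalid edge ({i}, {j})")
    i0, j0 = i - 1, j - 1
    return i0 * N_COMPONENTS - i0 * (i0 + 1) // 2 + (j0 - i0 - 1)


@dataclass(frozen=True)
class Feature:
    """One column of the feature table.

    ``endpoints`` is the 1-based IC pair for edge features and ``None`` for
    clinical features; ``networks`` names the endpoint networks.
    """
    feature_id: str
    kind: str  # "clinical" | "edge"
    endpoints: tuple[int, int] | None = None
    networks: tuple[str, str] | None = None


def build_registry(partition: Mapping[int, str] | None = None,
                   clinical: Sequence[str] = CLINICAL_FEATURES) -> list[Feature]:
    """Full 606-column registry: clinical columns then the 595 edges.

    Pass ``clinical=CLINICAL_FEATURES_STRICT`` (10 columns, no duration)
    for the narrower clinical-feature reading.
    """
    partition = dict(partition) if partition is not None else default_partition()
    validate_partition(partition)
    reg = [Feature(name, "clinical") for name in clinical]
    for i, j in edge_pairs():
        reg.append(Feature(edge_id(i, j), "edge", (i, j),
                           (partition[i], partition[j])))
    return reg


#: 10-column clinical registry (gender/age/weight/height + SID/NDSI/NDLQI +
#: SAS/SDS/BDI), for the reading that excludes disease duration.
CLINICAL_FEATURES_STRICT: tuple[str, ...] = tuple(
    c for c in CLINICAL_FEATURES if c != "duration")


@dataclass
class ConnectivityMatrix:
    """A subject's 35x35 Pearson-correlation network."""
    values: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_COMPONENTS, N_COMPONENTS):
            raise ValueError(f"expected {N_COMPONENTS}x{N_COMPONENTS}, got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-10):
            raise ValueError("connectivity matrix must have unit diagonal")
        self.values = v


def build_connectivity(timeseries: np.ndarray | pd.DataFrame,
                       subject_id: str = "") -> ConnectivityMatrix:
    """Pearson-correlate the 35 IC time series of one subject.

    Parameters
    ----------
    timeseries
        T x 35 array (T >= 36), one column per IC.

    Raises
    ------
    ValueError
        If a component's time series is constant (correlation undefined)
        or the table has the wrong shape.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2 or ts.shape[1] != N_COMPONENTS:
        raise ValueError(f"expected T x {N_COMPONENTS} time-series table, got {ts.shape}")
    if ts.shape[0] < N_COMPONENTS + 1:
        raise ValueError(f"need at least {N_COMPONENTS + 1} timepoints, got {ts.shape[0]}")
    const = np.flatnonzero(ts.max(axis=0) == ts.min(axis=0))
    if const.size:
        raise ValueError(
            "constant time series for component(s) "
            + ", ".join(str(c + 1) for c in const))
    corr = np.corrcoef(ts, rowvar=False)
    np.fill_diagonal(corr, 1.0)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return ConnectivityMatrix(corr, subject_id)


def vectorize_edges(matrix: ConnectivityMatrix | np.ndarray,
                    fisher: bool = False) -> np.ndarray:
    """Extract the 595 upper-triangle edges in canonical order.

    With ``fisher=True`` each correlation r is mapped to arctanh(r)
    (Fisher z), clipping |r| at 1 - 1e-6 to keep the transform finite.
    """
    v = matrix.values if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix, float)
    iu = np.triu_indices(N_COMPONENTS, k=1)
    edges = v[iu]
    if fisher:
        edges = np.arctanh(np.clip(edges, -1 + 1e-6, 1 - 1e-6))
    return edges


def matrix_from_edges(edges: np.ndarray) -> np.ndarray:
    """Reassemble a unit-diagonal symmetric matrix from a 595-edge vector."""
    edges = np.asarray(edges, dtype=float)
    if edges.shape != (N_EDGES,):
        raise ValueError(f"expected {N_EDGES} edges, got {edges.shape}")
    m = np.eye(N_COMPONENTS)
    iu = np.triu_indices(N_COMPONENTS, k=1)
    m[iu] = edges
    m[(iu[1], iu[0])] = edges
    return m


@dataclass
class FeatureMatrix:
    """n_subjects x p feature table with its column registry.

    ``center``/``scale`` are populated by :func:`standardize` and record
    the reference-row statistics so the identical affine transform can be
    applied to held-out subjects.
    """
    values: np.ndarray
    registry: list[Feature]
    subject_ids: list[str]
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.values.shape[1] != len(self.registry):
            raise ValueError(
                f"{self.values.shape[1]} columns but registry has {len(self.registry)}")
        if self.values.shape[0] != len(self.subject_ids):
            raise ValueError("row count does not match subject_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.registry]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column_index(self, feature_ids: Iterable[str]) -> np.ndarray:
        lookup = {f.feature_id: k for k, f in enumerate(self.registry)}
        missing = [fid for fid in feature_ids if fid not in lookup]
        if missing:
            raise KeyError(f"unknown feature columns: {missing}")
        return np.array([lookup[fid] for fid in feature_ids], dtype=int)

    def restrict(self, feature_ids: Sequence[str]) -> "FeatureMatrix":
        idx = self.column_index(feature_ids)
        return FeatureMatrix(self.values[:, idx],
                             [self.registry[k] for k in idx],
                             list(self.subject_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids,
                            columns=self.feature_ids)


def assemble_features(subjects: Sequence, edges: Sequence[np.ndarray],
                      partition: Mapping[int, str] | None = None,
                      clinical: Sequence[str] = CLINICAL_FEATURES,
                      ) -> tuple[FeatureMatrix, np.ndarray, np.ndarray]:
    """Join clinical covariates and edge vectors into one feature table.

    Parameters
    ----------
    subjects
        QC-passing subject records; each must expose the clinical fields
        (``gender``, ``age`` ... see :data:`CLINICAL_FEATURES`) plus
        ``SID_baseline`` and ``SID_post``.
    edges
        One length-595 edge vector per subject, same order.

    Returns
    -------
    (features, sid_baseline, sid_post)
        The outcome scores ride alongside the feature table so the label
        rule can be applied downstream; they are never feature columns
        themselves (``SID`` is the baseline score only).
    """
    if len(subjects) != len(edges):
        raise ValueError("subjects and edge vectors differ in length")
    if len(subjects) == 0:
        raise ValueError("no subjects supplied")
    rows, ids, base, post = [], [], [], []
    for rec, ev in zip(subjects, edges):
        ev = np.asarray(ev, dtype=float)
        if ev.shape != (N_EDGES,):
            raise ValueError(
                f"subject {getattr(rec, 'subject_id', '?')}: edge vector "
                f"shape {ev.shape}, expected ({N_EDGES},)")
        clin = []
        for name in clinical:
            attr = "SID_baseline" if name == "SID" else name
            val = getattr(rec, attr, None)
            if val is None:
                raise ValueError(
                    f"subject {getattr(rec, 'subject_id', '?')}: missing "
                    f"clinical field '{name}'")
            clin.append(float(val))
        rows.append(np.concatenate([clin, ev]))
        ids.append(str(rec.subject_id))
        base.append(float(rec.SID_baseline))
        post.append(float(rec.SID_post))
    reg = build_registry(partition, clinical=clinical)
    fm = FeatureMatrix(np.vstack(rows), reg, ids)
    return fm, np.asarray(base), np.asarray(post)


def write_features(features: FeatureMatrix, out_dir) -> None:
    """Write features.tsv (subjects x columns) and registry.json."""
    import json
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    features.to_frame().to_csv(out_dir / "features.tsv", sep="\t",
                               float_format="%.17g")
    reg = [{"feature_id": f.feature_id, "kind": f.kind,
            "endpoints": list(f.endpoints) if f.endpoints else None,
            "networks": list(f.networks) if f.networks else None}
           for f in features.registry]
    (out_dir / "registry.json").write_text(json.dumps(reg, indent=1))


def read_features(out_dir) -> FeatureMatrix:
    """Load a feature table written by :func:`write_features`."""
    import json
    from pathlib import Path

    out_dir = Path(out_dir)
    frame = pd.read_csv(out_dir / "features.tsv", sep="\t", index_col=0)
    reg = [Feature(d["feature_id"], d["kind"],
                   tuple(d["endpoints"]) if d["endpoints"] else None,
                   tuple(d["networks"]) if d["networks"] else None)
           for d in json.loads((out_dir / "registry.json").read_text())]
    return FeatureMatrix(frame.values, reg, [str(s) for s in frame.index])


def standardize_array(X: np.ndarray, reference_rows: np.ndarray,
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center/scale every column by reference-row mean and SD.

    Zero-variance columns pass through with scale 1 (centered only), so a
    constant feature cannot blow up the transform.  Returns the transformed
    copy of the full matrix plus (center, scale).
    """
    reference_rows = np.asarray(reference_rows)
    if reference_rows.size == 0:
        raise ValueError("reference row set is empty")
    ref = X[reference_rows]
    center = ref.mean(axis=0)
    scale = ref.std(axis=0, ddof=1) if ref.shape[0] > 1 else np.ones(X.shape[1])
    scale = np.where(scale > 0, scale, 1.0)
    return (X - center) / scale, center, scale


def standardize(features: FeatureMatrix,
                reference_rows: np.ndarray | None = None) -> FeatureMatrix:
    """Standardized copy of a feature table (reference rows default to all)."""
    if reference_rows is None:
        reference_rows = np.arange(features.n_subjects)
    Xs, center, scale = standardize_array(features.values, reference_rows)
    return FeatureMatrix(Xs, list(features.registry), list(features.subject_ids),
                         center=center, scale=scale)
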
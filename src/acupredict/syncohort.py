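"""Synthetic cohorts with the statistical structure the prediction
pipeline assumes.

The generator emulates a two-site acupuncture study in functional
dyspepsia: per-subject clinical covariates drawn from truncated normals
calibrated to the published cohort tables, a 35x35 correlation-structured
connectivity matrix with a group effect planted on a configurable edge
subset, an outcome model in which higher baseline symptom score (SID),
shorter disease duration and higher planted-edge connectivity drive larger
post-treatment SID improvement, plus rigid-body motion traces for the QC
stage.  Every stochastic element is driven by a single seed, so a config
reproduces its cohort bit-for-bit.

Simulated mechanism
-------------------
Each subject carries a latent treatment propensity

    u = (b_SID * z_SID + b_dur * z_dur + g) / norm,   g ~ N(0, 1)

the standardized clinical linear predictor plus a unit-normal latent
connectivity factor (the factor breaks the circularity between edges that
depend on propensity and an outcome that depends on edges).  Planted edges
shift continuously with u (``edge_effect * u``), subject noise is added
symmetrically, and the matrix is projected to the nearest valid correlation
matrix.  The latent improvement is

    imp = intercept + b_SID * z_SID + b_dur * z_dur
          + sum_e c_e * z_edge_e + noise,

and the responder label (+1 iff imp >= 2 points) emerges from the
post-hoc dichotomization of the continuous improvement, not from a planted
hard split.  The observed post score is SID_post = max(SID - imp, 0); the
ground-truth record keeps the latent improvement, whose labels are exactly
independent of every feature when all coefficients are zero.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.correlation_tools import corr_clipped

from . import connectome, motion_qc
from ._seeds import subseed as _subseed
from .connectome import N_COMPONENTS, N_EDGES, default_partition, edge_id

__all__ = [
    "SimConfig", "SubjectRecord", "OutcomeModel", "Cohort", "GroundTruth",
    "training_config", "validation_config", "null_config",
    "generate_cohort", "generate_timeseries", "generate_motion",
    "write_cohort", "default_planted_edges", "default_base_connectivity",
    "nearest_correlation", "TABLE1_TRAINING", "TABLE1_VALIDATION",
]

# Published cohort tables (mean, SD) for the two sites.
TABLE1_TRAINING: dict[str, tuple[float, float]] = {
    "age": (22.08, 2.16), "height": (160.90, 6.85), "weight": (51.27, 7.55),
    "duration": (42.49, 33.16), "SID": (3.75, 1.46), "NDSI": (44.70, 14.23),
    "NDLQI": (77.04, 9.4), "SAS": (42.25, 8.1), "SDS": (44.06, 10.0),
    "BDI": (7.88, 5.02),
}
TABLE1_VALIDATION: dict[str, tuple[float, float]] = {
    "age": (21.95, 2.49), "height": (165.12, 9.09), "weight": (56.98, 10.61),
    "duration": (33.81, 23.8), "SID": (3.93, 1.63), "NDSI": (46.07, 18.9),
    "NDLQI": (77.31, 10.79), "SAS": (42.79, 9.64), "SDS": (45.38, 11.2),
    "BDI": (7.05, 5.14),
}

#: Support of each clinical variable (inclusion criteria give the age band;
#: the scales are nonnegative; height/weight are left effectively unbounded).
CLINICAL_BOUNDS: dict[str, tuple[float, float]] = {
    "age": (18.0, 40.0), "height": (100.0, np.inf), "weight": (25.0, np.inf),
    "duration": (0.0, np.inf), "SID": (0.0, np.inf), "NDSI": (0.0, np.inf),
    "NDLQI": (0.0, np.inf), "SAS": (20.0, 80.0), "SDS": (20.0, 80.0),
    "BDI": (0.0, np.inf),
}

CLINICAL_VARIABLES = tuple(TABLE1_TRAINING)  # draw order is part of the seed contract


@dataclass(frozen=True)
class OutcomeModel:
    """Linear improvement model on standardized predictors (SID points).

    ``edge_coef`` applies to every planted edge; pass ``edge_coefs`` to
    override per edge (aligned with ``SimConfig.planted_edges``).
    """
    intercept: float = 2.4
    coef_sid: float = 0.8
    coef_duration: float = -0.5
    edge_coef: float = 0.05
    edge_coefs: tuple[float, ...] | None = None

    def coefs_for(self, n_edges: int) -> np.ndarray:
        if self.edge_coefs is not None:
            if len(self.edge_coefs) != n_edges:
                raise ValueError("edge_coefs length must match planted_edges")
            return np.asarray(self.edge_coefs, dtype=float)
        return np.full(n_edges, self.edge_coef, dtype=float)

    def is_null(self) -> bool:
        return (self.coef_sid == 0 and self.coef_duration == 0
                and self.edge_coef == 0 and not self.edge_coefs)


def default_planted_edges(n_edges: int = 37, seed: int = 7) -> tuple[tuple[int, int], ...]:
    """A fixed, reproducible subset of the 595 edges carrying the effect.

    The default 37 edges are sampled once with a dedicated seed so that
    training- and validation-style configs share the same planted set.
    """
    if not 0 <= n_edges <= N_EDGES:
        raise ValueError(f"n_edges must be in [0, {N_EDGES}]")
    pairs = connectome.edge_pairs()
    rng = np.random.default_rng(seed)
    idx = rng.choice(N_EDGES, size=n_edges, replace=False)
    return tuple(pairs[k] for k in sorted(idx))


def default_base_connectivity(within: float = 0.35, between: float = 0.10) -> np.ndarray:
    """Block-structured baseline correlation matrix over the 4 networks."""
    part = default_partition()
    labels = np.array([part[c] for c in range(1, N_COMPONENTS + 1)])
    same = labels[:, None] == labels[None, :]
    base = np.where(same, within, between)
    np.fill_diagonal(base, 1.0)
    return base


@dataclass
class SimConfig:
    """Full generative specification of one synthetic cohort."""
    n_subjects: int
    seed: int
    site_label: str = "site1"
    clinical_means: dict[str, float] = field(
        default_factory=lambda: {k: v[0] for k, v in TABLE1_TRAINING.items()})
    clinical_sds: dict[str, float] = field(
        default_factory=lambda: {k: v[1] for k, v in TABLE1_TRAINING.items()})
    female_fraction: float = 72 / 89
    n_timepoints: int = 180
    base_connectivity: np.ndarray = field(default_factory=default_base_connectivity)
    planted_edges: tuple[tuple[int, int], ...] = field(default_factory=default_planted_edges)
    edge_effect: float = 0.4
    outcome: OutcomeModel = field(default_factory=OutcomeModel)
    noise_sd: float = 0.8
    conn_noise_sd: float = 0.05
    motion_violation_fraction: float = 0.0

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory: cohorts must be reproducible")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ValueError("female_fraction must lie in [0, 1]")
        if self.n_timepoints < 60:
            raise ValueError("n_timepoints must be >= 60")
        if self.noise_sd < 0 or self.conn_noise_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        if not 0.0 <= self.motion_violation_fraction <= 1.0:
            raise ValueError("motion_violation_fraction must lie in [0, 1]")
        for name in CLINICAL_VARIABLES:
            if name not in self.clinical_means or name not in self.clinical_sds:
                raise ValueError(f"missing clinical mean/SD for '{name}'")
            if self.clinical_sds[name] <= 0:
                raise ValueError(f"clinical SD for '{name}' must be > 0")
        b = np.asarray(self.base_connectivity, dtype=float)
        if b.shape != (N_COMPONENTS, N_COMPONENTS):
            raise ValueError("base_connectivity must be 35x35")
        if not np.allclose(b, b.T, atol=1e-10):
            raise ValueError("base_connectivity must be symmetric")
        if not np.allclose(np.diag(b), 1.0, atol=1e-10):
            raise ValueError("base_connectivity must have unit diagonal")
        valid = set(connectome.edge_pairs())
        bad = [e for e in self.planted_edges if tuple(e) not in valid]
        if bad:
            raise ValueError(f"planted edges outside the upper triangle: {bad}")

    def planted_edge_ids(self) -> list[str]:
        return [edge_id(i, j) for i, j in self.planted_edges]


@dataclass
class SubjectRecord:
    """One patient: clinical covariates, outcomes, motion trace."""
    subject_id: str
    site: str
    gender: int          # 0 = female, 1 = male
    age: float           # years
    height: float        # cm
    weight: float        # kg
    duration: float      # months
    SID_baseline: float  # points
    NDSI: float
    NDLQI: float
    SAS: float
    SDS: float
    BDI: float
    SID_post: float
    motion: np.ndarray | None = None
    motion_violates: bool = False
    motion_ref: str | None = None
    timeseries_ref: str | None = None


@dataclass
class GroundTruth:
    """What the generator planted, for recovery scoring."""
    planted_edges: tuple[tuple[int, int], ...]
    planted_edge_ids: list[str]
    intercept: float
    coef_sid: float
    coef_duration: float
    edge_coefs: np.ndarray
    propensity: np.ndarray      # latent u per subject
    improvement: np.ndarray     # latent SID improvement per subject
    responder: np.ndarray       # +1 / -1 from latent improvement
    seed: int


@dataclass
class Cohort:
    config: SimConfig
    subjects: list[SubjectRecord]
    connectivity: np.ndarray    # n_subjects x 35 x 35 target matrices
    truth: GroundTruth

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def timeseries_for(self, k: int) -> np.ndarray:
        """IC time series for subject k (deterministic in the cohort seed)."""
        return generate_timeseries(self.connectivity[k], self.config.n_timepoints,
                                   seed=_subseed(self.config.seed, 1000 + k))

    def features(self, source: str = "target", fisher: bool = False
                 ) -> connectome.FeatureMatrix:
        """Assemble the 606-column feature table for the whole cohort.

        ``source="target"`` reads edges off the subjects' assigned
        connectivity matrices; ``source="timeseries"`` regenerates IC time
        series and runs the full Pearson network-construction path.
        """
        if source == "target":
            mats = self.connectivity
        elif source == "timeseries":
            mats = np.stack([
                connectome.build_connectivity(self.timeseries_for(k)).values
                for k in range(self.n_subjects)])
        else:
            raise ValueError("source must be 'target' or 'timeseries'")
        edges = [connectome.vectorize_edges(m, fisher=fisher) for m in mats]
        fm, _, _ = connectome.assemble_features(self.subjects, edges)
        return fm

    def gender(self) -> np.ndarray:
        return np.array([s.gender for s in self.subjects])


# --------------------------------------------------------------------------
# calibrated truncated normals

def _truncnorm_params(mean: float, sd: float, lower: float, upper: float
                      ) -> tuple[float, float]:
    """Underlying (mu, sigma) whose truncation to [lower, upper] has the
    requested mean and SD (moment matching).

    Naive truncation of N(mean, sd) inflates the mean whenever a bound sits
    within ~2 SDs (disease duration: +6.5 months at the published values),
    so the generator solves for the underlying parameters instead.
    """
    a0 = (lower - mean) / sd
    b0 = (upper - mean) / sd
    if a0 < -6 and b0 > 6:  # truncation numerically irrelevant
        return mean, sd

    def moments(p):
        mu, log_sigma = p
        sigma = np.exp(log_sigma)
        a, b = (lower - mu) / sigma, (upper - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.root(moments, [mean, np.log(sd)], method="hybr")
    if not sol.success:  # pragma: no cover - well-behaved for sane inputs
        raise RuntimeError(f"truncated-normal calibration failed: {sol.message}")
    mu, sigma = sol.x[0], float(np.exp(sol.x[1]))
    return mu, sigma


def _draw_clinical(name: str, mean: float, sd: float, n: int,
                   rng: np.random.Generator) -> np.ndarray:
    lower, upper = CLINICAL_BOUNDS[name]
    mu, sigma = _truncnorm_params(mean, sd, lower, upper)
    a, b = (lower - mu) / sigma, (upper - mu) / sigma
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n, random_state=rng)


# --------------------------------------------------------------------------
# correlation-matrix handling

def nearest_correlation(m: np.ndarray, tol: float = 1e-8,
                        max_iter: int = 200) -> np.ndarray:
    """Project a symmetric matrix to the nearest valid correlation matrix.

    Higham-style alternating projections between the positive-semidefinite
    cone and the unit-diagonal affine set, with Dykstra's correction;
    stops when successive iterates agree to ``tol`` and the smallest
    eigenvalue is above ``-tol``.  Falls back to one-shot eigenvalue
    clipping if the loop fails to converge, and raises if even that leaves
    the matrix indefinite.
    """
    y = np.asarray(m, dtype=float).copy()
    y = (y + y.T) / 2.0
    ds = np.zeros_like(y)
    for _ in range(max_iter):
        r = y - ds
        w, v = np.linalg.eigh(r)
        x = (v * np.clip(w, 0.0, None)) @ v.T
        ds = x - r
        y_next = x.copy()
        np.fill_diagonal(y_next, 1.0)
        delta = np.max(np.abs(y_next - y))
        y = y_next
        if delta < tol and np.linalg.eigvalsh(y).min() >= -tol:
            break
    if np.linalg.eigvalsh(y).min() < -1e-8:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            y = corr_clipped(m, threshold=tol)
        if np.linalg.eigvalsh(y).min() < -1e-8:
            raise ValueError(
                "matrix not positive semidefinite after projection "
                f"(min eigenvalue {np.linalg.eigvalsh(y).min():.3e})")
    y = (y + y.T) / 2.0
    off = ~np.eye(y.shape[0], dtype=bool)
    y[off] = np.clip(y[off], -1.0, 1.0)
    np.fill_diagonal(y, 1.0)
    return y


def _valid_correlation(c: np.ndarray) -> np.ndarray:
    """Clip, symmetrize and (only if needed) project to PSD."""
    c = (c + c.T) / 2.0
    off = ~np.eye(N_COMPONENTS, dtype=bool)
    c[off] = np.clip(c[off], -0.999, 0.999)
    np.fill_diagonal(c, 1.0)
    if np.linalg.eigvalsh(c).min() >= -1e-8:
        return c
    return nearest_correlation(c)


# --------------------------------------------------------------------------
# generators

def generate_cohort(config: SimConfig) -> Cohort:
    """Draw a full synthetic cohort. Deterministic given ``config.seed``."""
    config.validate()
    n = config.n_subjects
    rng = np.random.default_rng(config.seed)

    clinical = {name: _draw_clinical(name, config.clinical_means[name],
                                     config.clinical_sds[name], n, rng)
                for name in CLINICAL_VARIABLES}
    gender = (rng.random(n) >= config.female_fraction).astype(int)  # 1 = male

    z_sid = (clinical["SID"] - config.clinical_means["SID"]) / config.clinical_sds["SID"]
    z_dur = (clinical["duration"] - config.clinical_means["duration"]) / config.clinical_sds["duration"]
    out = config.outcome
    latent = rng.standard_normal(n)
    lp = out.coef_sid * z_sid + out.coef_duration * z_dur
    norm = np.sqrt(out.coef_sid ** 2 + out.coef_duration ** 2 + 1.0)
    propensity = (lp + latent) / norm

    base = np.asarray(config.base_connectivity, dtype=float)
    mask = np.zeros((N_COMPONENTS, N_COMPONENTS))
    for i, j in config.planted_edges:
        mask[i - 1, j - 1] = mask[j - 1, i - 1] = 1.0

    mats = np.empty((n, N_COMPONENTS, N_COMPONENTS))
    for k in range(n):
        noise = rng.normal(0.0, config.conn_noise_sd,
                           size=(N_COMPONENTS, N_COMPONENTS))
        noise = (noise + noise.T) / np.sqrt(2.0)
        c = base + config.edge_effect * propensity[k] * mask + noise
        mats[k] = _valid_correlation(c)

    # outcome model on the *realized* (post-projection) edge values
    edge_coefs = out.coefs_for(len(config.planted_edges))
    edge_sd = max(np.hypot(config.edge_effect, config.conn_noise_sd), 1e-12)
    edge_term = np.zeros(n)
    for (i, j), c_e in zip(config.planted_edges, edge_coefs):
        z_edge = (mats[:, i - 1, j - 1] - base[i - 1, j - 1]) / edge_sd
        edge_term += c_e * z_edge
    improvement = (out.intercept + lp + edge_term
                   + config.noise_sd * rng.standard_normal(n))
    responder = np.where(improvement >= 2.0, 1, -1)
    sid_post = np.maximum(clinical["SID"] - improvement, 0.0)

    n_violate = int(round(config.motion_violation_fraction * n))
    violators = set(rng.choice(n, size=n_violate, replace=False).tolist()) \
        if n_violate else set()

    subjects = []
    for k in range(n):
        violate = k in violators
        trace = generate_motion(config.n_timepoints, violate=violate,
                                seed=_subseed(config.seed, k))
        subjects.append(SubjectRecord(
            subject_id=f"{config.site_label}_{k + 1:03d}",
            site=config.site_label, gender=int(gender[k]),
            age=float(clinical["age"][k]), height=float(clinical["height"][k]),
            weight=float(clinical["weight"][k]),
            duration=float(clinical["duration"][k]),
            SID_baseline=float(clinical["SID"][k]),
            NDSI=float(clinical["NDSI"][k]), NDLQI=float(clinical["NDLQI"][k]),
            SAS=float(clinical["SAS"][k]), SDS=float(clinical["SDS"][k]),
            BDI=float(clinical["BDI"][k]), SID_post=float(sid_post[k]),
            motion=trace, motion_violates=violate))

    truth = GroundTruth(
        planted_edges=tuple(tuple(e) for e in config.planted_edges),
        planted_edge_ids=config.planted_edge_ids(),
        intercept=out.intercept, coef_sid=out.coef_sid,
        coef_duration=out.coef_duration, edge_coefs=edge_coefs,
        propensity=propensity, improvement=improvement,
        responder=responder, seed=config.seed)
    return Cohort(config=config, subjects=subjects, connectivity=mats, truth=truth)


def generate_timeseries(target: np.ndarray, n_timepoints: int, seed: int) -> np.ndarray:
    """T x 35 zero-mean Gaussian draw with the target correlation structure.

    The empirical correlation of the output converges to ``target`` as T
    grows.  Fails if the target is not positive semidefinite.
    """
    target = np.asarray(target, dtype=float)
    if target.shape != (N_COMPONENTS, N_COMPONENTS):
        raise ValueError("target must be 35x35")
    w, v = np.linalg.eigh((target + target.T) / 2.0)
    if w.min() < -1e-8:
        raise ValueError(
            f"target matrix is not positive semidefinite (min eigenvalue {w.min():.3e})")
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_timepoints, N_COMPONENTS))
    return z @ factor.T


def generate_motion(n_timepoints: int, violate: bool, seed: int) -> np.ndarray:
    """T x 6 bounded random-walk motion trace (mm, mm, mm, rad, rad, rad).

    Non-violating traces are rescaled to mean FD 0.08 mm with maximum
    translation capped at 0.5 mm and rotation at ~0.6 degrees, so every QC
    rule passes; violating traces are rescaled to mean FD 0.35 mm, so the
    mean-FD rule (at least) fails.
    """
    if n_timepoints < 2:
        raise ValueError("n_timepoints must be >= 2")
    rng = np.random.default_rng(seed)
    steps = np.hstack([rng.normal(0.0, 0.02, (n_timepoints, 3)),
                       rng.normal(0.0, 0.0004, (n_timepoints, 3))])
    trace = np.cumsum(steps, axis=0)
    trace -= trace[0]
    fd = motion_qc.framewise_displacement(trace)
    mean_fd = fd.mean()
    if mean_fd <= 0:  # pragma: no cover - zero-probability for Gaussian steps
        raise RuntimeError("degenerate motion draw")
    target_fd = 0.35 if violate else 0.08
    trace = trace * (target_fd / mean_fd)
    if not violate:
        max_trans = np.abs(trace[:, :3]).max()
        max_rot = np.abs(trace[:, 3:]).max()
        shrink = min(1.0, 0.5 / max_trans if max_trans > 0 else 1.0,
                     np.deg2rad(0.6) / max_rot if max_rot > 0 else 1.0)
        trace = trace * shrink
    return trace


# --------------------------------------------------------------------------
# cohort factories (the study conditions)

def training_config(n_subjects: int = 89, seed: int = 0, **overrides) -> SimConfig:
    """Training-test-site conditions: published clinical table, 17/72
    male/female split, 37 planted edges with the default effect sizes."""
    cfg = SimConfig(n_subjects=n_subjects, seed=seed, site_label="train",
                    female_fraction=72 / 89)
    return replace(cfg, **overrides) if overrides else cfg


def validation_config(n_subjects: int = 58, seed: int = 1, **overrides) -> SimConfig:
    """Independent-validation-site conditions: second clinical column,
    24/34 male/female split, same planted edges and effect sizes."""
    cfg = SimConfig(
        n_subjects=n_subjects, seed=seed, site_label="valid",
        clinical_means={k: v[0] for k, v in TABLE1_VALIDATION.items()},
        clinical_sds={k: v[1] for k, v in TABLE1_VALIDATION.items()},
        female_fraction=34 / 58)
    return replace(cfg, **overrides) if overrides else cfg


def null_config(n_subjects: int = 89, seed: int = 0, **overrides) -> SimConfig:
    """No planted effects: every feature coefficient and the edge effect are
    zero; the intercept of 2 points keeps the responder split balanced, and
    the latent labels are exactly independent of every feature."""
    cfg = training_config(n_subjects=n_subjects, seed=seed,
                          edge_effect=0.0,
                          outcome=OutcomeModel(intercept=2.0, coef_sid=0.0,
                                               coef_duration=0.0, edge_coef=0.0))
    return replace(cfg, **overrides) if overrides else cfg


# --------------------------------------------------------------------------
# on-disk layout

def write_cohort(cohort: Cohort, out_dir: str | Path,
                 write_timeseries: bool = True) -> Path:
    """Write subjects.tsv, rp_*.txt, ts_*.tsv and truth.json.

    All numeric output is full double precision, so a rewritten cohort is
    bit-identical for identical configs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, s in enumerate(cohort.subjects):
        rp = out_dir / f"rp_{s.subject_id}.txt"
        np.savetxt(rp, s.motion, fmt="%.17g")
        s.motion_ref = rp.name
        if write_timeseries:
            ts = out_dir / f"ts_{s.subject_id}.tsv"
            np.savetxt(ts, cohort.timeseries_for(k), fmt="%.17g", delimiter="\t")
            s.timeseries_ref = ts.name
        rows.append({
            "subject_id": s.subject_id, "site": s.site, "gender": s.gender,
            "age": s.age, "height": s.height, "weight": s.weight,
            "duration": s.duration, "SID_baseline": s.SID_baseline,
            "NDSI": s.NDSI, "NDLQI": s.NDLQI, "SAS": s.SAS, "SDS": s.SDS,
            "BDI": s.BDI, "SID_post": s.SID_post,
            "motion_ref": s.motion_ref, "timeseries_ref": s.timeseries_ref or "",
        })
    pd.DataFrame(rows).to_csv(out_dir / "subjects.tsv", sep="\t", index=False,
                              float_format="%.17g")
    truth = cohort.truth
    with open(out_dir / "truth.json", "w") as fh:
        json.dump({
            "seed": truth.seed,
            "planted_edges": [list(e) for e in truth.planted_edges],
            "planted_edge_ids": truth.planted_edge_ids,
            "intercept": truth.intercept, "coef_sid": truth.coef_sid,
            "coef_duration": truth.coef_duration,
            "edge_coefs": truth.edge_coefs.tolist(),
            "propensity": truth.propensity.tolist(),
            "improvement": truth.improvement.tolist(),
            "responder": truth.responder.tolist(),
        }, fh, indent=1)
    return out_dir


def read_subjects(path: str | Path) -> pd.DataFrame:
    """Load a subjects.tsv written by :func:`write_cohort`."""
    return pd.read_csv(Path(path), sep="\t")
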
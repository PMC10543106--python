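"""Head-motion quality control from rigid-body realignment parameters.

Subjects are excluded — at the subject level, no frame censoring — when any
of four criteria fires: maximum absolute translation > 2 mm, maximum
absolute rotation > 2 degrees, mean framewise displacement (FD) > 0.2 mm, or
more than 30% of frames with FD > 0.2 mm.  FD follows the Power convention:
the sum of absolute backward differences of the six parameters, with
rotations converted to arc length on a 50 mm sphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

DEFAULT_HEAD_RADIUS_MM = 50.0

# rule tokens, in report order
RULE_TRANSLATION = "max_translation"
RULE_ROTATION = "max_rotation"
RULE_MEAN_FD = "mean_fd"
RULE_FD_FRACTION = "fd_fraction"


@dataclass(frozen=True)
class QCConfig:
    """Exclusion thresholds and dialect switches.

    ``rotation_units`` describes the *input* trace: SPM ``rp_*.txt`` files
    carry radians ("rad"); set "deg" for degree-valued traces.  The 2-degree
    rotation rule converts internally either way.  ``include_first_frame``
    keeps the defined-as-zero leading FD value in the mean and in the
    denominator of the FD fraction; switch off to drop it.
    """
    head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM
    rotation_units: str = "rad"
    max_translation_mm: float = 2.0
    max_rotation_deg: float = 2.0
    fd_threshold_mm: float = 0.2
    max_mean_fd_mm: float = 0.2
    max_fd_fraction: float = 0.30
    include_first_frame: bool = True

    def __post_init__(self) -> None:
        if self.rotation_units not in ("rad", "deg"):
            raise ValueError("rotation_units must be 'rad' or 'deg'")


@dataclass
class QCDecision:
    subject_id: str
    max_abs_translation: float  # mm
    max_abs_rotation: float     # degrees
    mean_fd: float              # mm
    frac_fd_gt_thresh: float
    excluded: bool
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.excluded != bool(self.reasons):
            raise ValueError("excluded flag inconsistent with reasons list")


def _as_trace(trace: np.ndarray) -> np.ndarray:
    t = np.asarray(trace, dtype=float)
    if t.ndim != 2 or t.shape[1] != 6:
        raise ValueError(f"motion trace must be T x 6, got {t.shape}")
    if t.shape[0] < 2:
        raise ValueError("motion trace needs at least 2 timepoints")
    if not np.all(np.isfinite(t)):
        raise ValueError("motion trace contains non-finite values")
    return t


def framewise_displacement(trace: np.ndarray,
                           head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM,
                           rotation_units: str = "rad") -> np.ndarray:
    """Per-frame FD series (first element 0).

    FD_t = sum_i |d_i(t) - d_i(t-1)| + r * sum_j |theta_j(t) - theta_j(t-1)|
    with translations d in mm, rotations theta in radians and head radius r.
    """
    t = _as_trace(trace)
    trans = t[:, :3]
    rot = t[:, 3:]
    if rotation_units == "deg":
        rot = np.deg2rad(rot)
    elif rotation_units != "rad":
        raise ValueError("rotation_units must be 'rad' or 'deg'")
    d = np.abs(np.diff(trans, axis=0)).sum(axis=1)
    r = np.abs(np.diff(rot, axis=0)).sum(axis=1) * head_radius_mm
    fd = np.concatenate([[0.0], d + r])
    return fd


def apply_exclusion(trace: np.ndarray, subject_id: str = "",
                    config: QCConfig = QCConfig()) -> QCDecision:
    """Evaluate all four motion rules on one subject's trace."""
    t = _as_trace(trace)
    rot = t[:, 3:]
    rot_deg = rot if config.rotation_units == "deg" else np.rad2deg(rot)
    max_trans = float(np.abs(t[:, :3]).max())
    max_rot = float(np.abs(rot_deg).max())

    fd = framewise_displacement(t, config.head_radius_mm, config.rotation_units)
    if not config.include_first_frame:
        fd = fd[1:]
    mean_fd = float(fd.mean())
    frac = float(np.mean(fd > config.fd_threshold_mm))

    reasons = []
    if max_trans > config.max_translation_mm:
        reasons.append(RULE_TRANSLATION)
    if max_rot > config.max_rotation_deg:
        reasons.append(RULE_ROTATION)
    if mean_fd > config.max_mean_fd_mm:
        reasons.append(RULE_MEAN_FD)
    if frac > config.max_fd_fraction:
        reasons.append(RULE_FD_FRACTION)
    return QCDecision(subject_id, max_trans, max_rot, mean_fd, frac,
                      bool(reasons), reasons)


def read_motion_file(path: str | Path) -> np.ndarray:
    """Load a 6-column whitespace-delimited realignment-parameter file."""
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 columns, found {arr.shape[1]}")
    return arr


def qc_report(traces: Mapping[str, np.ndarray] | Iterable[tuple[str, np.ndarray]],
              config: QCConfig = QCConfig()) -> pd.DataFrame:
    """One QCDecision row per subject."""
    items = traces.items() if isinstance(traces, Mapping) else traces
    rows = []
    for sid, tr in items:
        d = apply_exclusion(tr, sid, config)
        rows.append({
            "subject_id": d.subject_id,
            "max_abs_translation_mm": d.max_abs_translation,
            "max_abs_rotation_deg": d.max_abs_rotation,
            "mean_fd_mm": d.mean_fd,
            "frac_fd_gt_0p2": d.frac_fd_gt_thresh,
            "excluded": d.excluded,
            "reasons": ";".join(d.reasons),
        })
    return pd.DataFrame(rows)


def qc_directory(motion_dir: str | Path, config: QCConfig = QCConfig(),
                 out: str | Path | None = None) -> pd.DataFrame:
    """Run QC over every ``rp_*.txt`` in a directory; optionally write TSV."""
    motion_dir = Path(motion_dir)
    traces = []
    for path in sorted(motion_dir.glob("rp_*.txt")):
        sid = path.stem[len("rp_"):]
        traces.append((sid, read_motion_file(path)))
    if not traces:
        raise FileNotFoundError(f"no rp_*.txt files under {motion_dir}")
    report = qc_report(traces, config)
    if out is not None:
        report.to_csv(out, sep="\t", index=False)
    return report
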
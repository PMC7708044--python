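"""Stiffness extraction from tethered-particle displacement time series.

The pipeline mirrors the flow-stretching measurement analysis:

1. quality control — particles whose displacement under reversed flow does
   not mirror the forward response are excluded (badly tethered);
2. unstretched length ``L0`` — mean displacement at the 10 pN plateau minus
   the pre-flow baseline (the tether is straightened but not yet stretched
   at 10 pN);
3. stiffness — ordinary least squares of plateau-mean force on plateau-mean
   displacement over plateaus above 15 pN (enthalpic regime), with apparent
   stiffness = slope x L0.

Per-plateau aggregation drops the first 2 s of each step (mechanical
settling) and averages the remainder; both choices are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .flow import ForceSchedule
from .mechanics import StiffnessResult

#: Phase codes.
PRE, FORWARD, REVERSE = 0, 1, 2

#: Seconds discarded at the start of each force step before averaging.
DEFAULT_SETTLE_S = 2.0

#: Plateaus strictly above this force (pN) enter the stiffness fit.
DEFAULT_FORCE_THRESHOLD_PN = 15.0

#: Relative mismatch tolerance of the symmetric-reversal QC.
DEFAULT_QC_TOLERANCE = 0.2


def sample_schedule(schedule: ForceSchedule, frame_rate: float = 5.0,
                    pre_duration_s: float = 5.0):
    """Per-frame ``(time, force, phase)`` arrays for a force schedule.

    The pre-flow segment has zero applied force; forward then reverse steps
    follow, each sampled at ``frame_rate`` frames/s.
    """
    if frame_rate <= 0:
        raise ValidationError("frame_rate must be > 0")
    forces, phases = [], []
    segs = [(0.0, pre_duration_s, PRE)] if pre_duration_s > 0 else []
    segs += [(f, d, FORWARD) for f, d in schedule.steps]
    segs += [(f, d, REVERSE) for f, d in schedule.reverse_steps]
    for f, dur, ph in segs:
        n = int(round(dur * frame_rate))
        forces.extend([f] * n)
        phases.extend([ph] * n)
    n_total = len(forces)
    time = np.arange(n_total) / frame_rate
    return time, np.asarray(forces, float), np.asarray(phases, np.int8)


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled particle displacement with applied-force annotation.

    ``displacement`` is |current - initial position| in nm, so it is
    non-negative in both flow directions.
    """

    time: np.ndarray          # s
    displacement: np.ndarray  # nm
    force: np.ndarray         # pN, piecewise constant
    phase: np.ndarray         # PRE / FORWARD / REVERSE per frame

    def __post_init__(self) -> None:
        t = np.asarray(self.time, float)
        d = np.asarray(self.displacement, float)
        f = np.asarray(self.force, float)
        p = np.asarray(self.phase, np.int8)
        if not t.shape == d.shape == f.shape == p.shape:
            raise ValidationError("trajectory arrays must align")
        if t.size < 2:
            raise ValidationError("trajectory too short")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValidationError("sampling must be uniform")
        if np.any(d < 0):
            raise ValidationError("displacement must be >= 0")
        for name, arr in (("time", t), ("displacement", d),
                          ("force", f), ("phase", p)):
            object.__setattr__(self, name, arr)

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time,
                             "displacement_nm": self.displacement,
                             "force_pN": self.force,
                             "phase": self.phase})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path,
                 schedule: ForceSchedule | None = None,
                 frame_rate: float = 5.0,
                 pre_duration_s: float = 5.0) -> "Trajectory":
        """Read a trajectory CSV.

        Accepts either the full four-column format written by
        :meth:`to_csv`, or a bare ``time_s`` + (``displacement_nm`` or
        ``x_nm``/``y_nm``) table, in which case forces and phases are
        reconstructed from ``schedule``.
        """
        df = pd.read_csv(path)
        if "displacement_nm" in df.columns:
            disp = df["displacement_nm"].to_numpy(float)
        elif {"x_nm", "y_nm"} <= set(df.columns):
            x = df["x_nm"].to_numpy(float)
            y = df["y_nm"].to_numpy(float)
            disp = np.hypot(x - x[0], y - y[0])
        else:
            raise ValidationError(
                "CSV needs displacement_nm or x_nm/y_nm columns")
        if {"force_pN", "phase"} <= set(df.columns):
            force = df["force_pN"].to_numpy(float)
            phase = df["phase"].to_numpy(np.int8)
        else:
            if schedule is None:
                raise ValidationError(
                    "CSV lacks force annotation; a schedule is required")
            _, force, phase = sample_schedule(schedule, frame_rate,
                                              pre_duration_s)
            if len(force) != len(disp):
                raise ValidationError(
                    f"schedule implies {len(force)} frames, CSV has "
                    f"{len(disp)}")
        return cls(time=df["time_s"].to_numpy(float), displacement=disp,
                   force=force, phase=phase)


@dataclass(frozen=True)
class Plateau:
    phase: int
    force: float
    mean_displacement: float
    n_frames: int


def plateaus(traj: Trajectory,
             settle_s: float = DEFAULT_SETTLE_S) -> list[Plateau]:
    """Plateau means of contiguous constant-force segments (per phase),
    discarding the first ``settle_s`` seconds of each segment."""
    skip = int(round(settle_s * traj.frame_rate))
    out: list[Plateau] = []
    change = np.flatnonzero(np.diff(traj.force) != 0)
    change = np.concatenate([change,
                             np.flatnonzero(np.diff(traj.phase) != 0)])
    bounds = np.unique(np.concatenate([[0], change + 1, [traj.time.size]]))
    for a, b in zip(bounds, bounds[1:]):
        if traj.phase[a] == PRE:
            continue
        lo = a + min(skip, max(0, (b - a) - 1))
        out.append(Plateau(phase=int(traj.phase[a]),
                           force=float(traj.force[a]),
                           mean_displacement=float(
                               np.mean(traj.displacement[lo:b])),
                           n_frames=int(b - lo)))
    return out


@dataclass(frozen=True)
class QCResult:
    """Outcome of the symmetric-reversal quality check."""

    status: str            # "pass" | "fail" | "not_evaluable"
    score: float | None    # max relative mismatch over matched force levels
    matched_forces: tuple[float, ...] = ()

    @property
    def passed(self) -> bool:
        return self.status == "pass"


def qc_symmetric_reversal(traj: Trajectory,
                          tolerance: float = DEFAULT_QC_TOLERANCE,
                          settle_s: float = DEFAULT_SETTLE_S) -> QCResult:
    """Compare plateau displacement at matched force levels between flow
    directions; a well-tethered particle mirrors its forward response."""
    pl = plateaus(traj, settle_s)
    fwd = {p.force: p.mean_displacement for p in pl if p.phase == FORWARD}
    rev = {p.force: p.mean_displacement for p in pl if p.phase == REVERSE}
    matched = sorted(set(fwd) & set(rev))
    if not matched:
        return QCResult(status="not_evaluable", score=None)
    score = max(abs(fwd[f] - rev[f]) / abs(fwd[f]) for f in matched
                if fwd[f] != 0)
    status = "pass" if score <= tolerance else "fail"
    return QCResult(status=status, score=score,
                    matched_forces=tuple(matched))


def unstretched_length(traj: Trajectory, anchor_offset: float = 0.0,
                       reference_force: float = 10.0,
                       settle_s: float = DEFAULT_SETTLE_S) -> float:
    """Unstretched tether length ``L0`` (nm): mean displacement at the
    reference (10 pN) forward plateau minus the pre-flow baseline, minus any
    known anchor offset."""
    pre = traj.displacement[traj.phase == PRE]
    baseline = float(np.mean(pre)) if pre.size else 0.0
    for p in plateaus(traj, settle_s):
        if p.phase == FORWARD and np.isclose(p.force, reference_force):
            return p.mean_displacement - baseline - anchor_offset
    raise ValidationError(
        f"schedule has no {reference_force} pN forward plateau")


def fit_stiffness(traj: Trajectory, L0: float,
                  force_threshold: float = DEFAULT_FORCE_THRESHOLD_PN,
                  settle_s: float = DEFAULT_SETTLE_S) -> StiffnessResult:
    """Apparent stiffness from the enthalpic regime.

    OLS of plateau-mean force on plateau-mean displacement over forward
    plateaus with force strictly above the threshold; stiffness =
    slope x L0.
    """
    pts = [(p.mean_displacement, p.force) for p in plateaus(traj, settle_s)
           if p.phase == FORWARD and p.force > force_threshold]
    if len(pts) < 3:
        raise InsufficientDataError(
            f"need >= 3 plateaus above {force_threshold} pN, got {len(pts)}")
    x = np.array([p[0] for p in pts])
    f = np.array([p[1] for p in pts])
    slope, _ = np.polyfit(x, f, 1)
    return StiffnessResult(apparent_stiffness=float(slope) * L0, L0=L0,
                           slope=float(slope))


def analyze_trajectory(traj: Trajectory,
                       qc_tolerance: float = DEFAULT_QC_TOLERANCE,
                       force_threshold: float = DEFAULT_FORCE_THRESHOLD_PN,
                       anchor_offset: float = 0.0,
                       settle_s: float = DEFAULT_SETTLE_S) -> dict:
    """Full per-particle pipeline: QC, L0, stiffness.

    The stiffness is reported regardless of QC status (cohort summaries
    filter on QC); keys: ``qc``, ``L0_nm``, ``stiffness_pN``, ``slope``.
    """
    qc = qc_symmetric_reversal(traj, qc_tolerance, settle_s)
    L0 = unstretched_length(traj, anchor_offset, settle_s=settle_s)
    res = fit_stiffness(traj, L0, force_threshold, settle_s)
    return {"qc": qc, "L0_nm": L0, "stiffness_pN": res.apparent_stiffness,
            "slope_pN_per_nm": res.slope}


def summarize_cohort(trajectories: Iterable[Trajectory],
                     qc_tolerance: float = DEFAULT_QC_TOLERANCE,
                     **kwargs) -> pd.DataFrame:
    """Per-particle results table for a cohort (column ``qc_pass`` marks the
    particles a measurement would keep)."""
    rows = []
    for i, traj in enumerate(trajectories):
        r = analyze_trajectory(traj, qc_tolerance=qc_tolerance, **kwargs)
        rows.append({"particle": i, "qc_status": r["qc"].status,
                     "qc_pass": r["qc"].passed, "qc_score": r["qc"].score,
                     "L0_nm": r["L0_nm"],
                     "stiffness_pN": r["stiffness_pN"]})
    return pd.DataFrame(rows)
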
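"""Reading, calibrating and aligning 2-D tracking tables.

The canonical on-disk dialect mirrors what video trackers emit: one row per
frame with the insect position in pixels plus the four tracked arena
landmark points (corners, or diameter endpoints for the circular arena):

    frame,time_s,x_px,y_px,lm1_x,lm1_y,lm2_x,lm2_y,lm3_x,lm3_y,lm4_x,lm4_y

A minimal 3-column form ``time_s,x_cm,y_cm`` is accepted for data already
expressed in the canonical cm frame (cool spot at the origin).
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .arena import Arena, CalibrationTransform, calibrate_from_landmarks

__all__ = [
    "Trajectory",
    "TrialRecording",
    "TrackingFormatError",
    "TrackingQualityError",
    "read_tracking_table",
    "write_tracking_table",
    "align_to_spot",
    "speed_series",
]

log = logging.getLogger(__name__)

TRACKER_HEADER = (
    "frame,time_s,x_px,y_px,lm1_x,lm1_y,lm2_x,lm2_y,lm3_x,lm3_y,lm4_x,lm4_y"
)
MINIMAL_HEADER = "time_s,x_cm,y_cm"

TRIAL_DURATION_S = 300.0
CONDITIONS = ("heated", "unheated", "blinded")


class TrackingFormatError(ValueError):
    """Unparseable or unrecognised tracking file."""


class TrackingQualityError(ValueError):
    """Tracking file too degraded to analyse (e.g. > 20% missing frames)."""


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped 2-D positions in the canonical cm frame."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fps: float = 30.0

    def __post_init__(self) -> None:
        t, x, y = (np.asarray(a, dtype=float) for a in (self.t, self.x, self.y))
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if not (len(t) == len(x) == len(y)):
            raise ValueError("t, x, y must have equal lengths")
        if len(t) and t[0] < 0:
            raise ValueError("time must start at or after 0")
        if len(t) > 1 and not (np.diff(t) > 0).all():
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) > 1 else 0.0

    @property
    def median_dt(self) -> float:
        """Actual median frame interval; preferred over 1/fps for thresholds."""
        if len(self) < 2:
            return 1.0 / self.fps
        return float(np.median(np.diff(self.t)))

    def positions(self) -> np.ndarray:
        return np.stack([self.x, self.y], axis=1)


@dataclass(frozen=True)
class TrialRecording:
    """One trial: a calibrated trajectory plus its experimental context."""

    trajectory: Trajectory
    arena: Arena
    animal_id: str
    trial_index: int
    condition: str = "heated"

    def __post_init__(self) -> None:
        if not (1 <= self.trial_index <= 10):
            raise ValueError("trial_index must be in 1..10 (10 trials per session)")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.trajectory.duration_s > TRIAL_DURATION_S * 1.05:
            raise ValueError("trajectory exceeds the 300 s trial duration (+5% slack)")


def _interpolate_gaps(
    t: np.ndarray, x: np.ndarray, y: np.ndarray, max_gap_s: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fill short missing-coordinate runs; keep the longest segment otherwise.

    Missing samples are NaN in x/y. Runs of NaN spanning <= max_gap_s are
    linearly interpolated in time; longer runs split the recording and only
    the longest contiguous piece is kept (with a warning).
    """
    missing = ~(np.isfinite(x) & np.isfinite(y))
    if not missing.any():
        return t, x, y
    # identify missing runs
    idx = np.flatnonzero(missing)
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    long_runs = []
    for run in splits:
        lo = run[0] - 1
        hi = run[-1] + 1
        gap_s = (t[hi] if hi < len(t) else t[-1]) - (t[lo] if lo >= 0 else t[0])
        if lo < 0 or hi >= len(t) or gap_s > max_gap_s:
            long_runs.append(run)
    ok = np.isfinite(x) & np.isfinite(y)
    x = np.interp(t, t[ok], x[ok])
    y = np.interp(t, t[ok], y[ok])
    if long_runs:
        # split at the long gaps, keep the longest contiguous segment
        bad = np.zeros(len(t), dtype=bool)
        for run in long_runs:
            bad[run] = True
        good_idx = np.flatnonzero(~bad)
        segments = np.split(good_idx, np.flatnonzero(np.diff(good_idx) > 1) + 1)
        best = max(segments, key=lambda s: t[s[-1]] - t[s[0]] if len(s) else -1.0)
        warnings.warn(
            f"gap(s) longer than {max_gap_s} s: keeping longest segment "
            f"({t[best[-1]] - t[best[0]]:.1f} s of {t[-1] - t[0]:.1f} s)",
            stacklevel=3,
        )
        t, x, y = t[best], x[best], y[best]
    return t, x, y


def read_tracking_table(
    path,
    arena: Arena,
    calibration: CalibrationTransform | None = None,
    *,
    animal_id: str = "unknown",
    trial_index: int = 1,
    condition: str = "heated",
    fps: float = 30.0,
    max_gap_s: float = 0.5,
    max_missing_frac: float = 0.2,
) -> TrialRecording:
    """Read one tracking CSV and return a calibrated :class:`TrialRecording`.

    For the full tracker dialect, ``calibration`` is fitted from the median
    landmark positions when not supplied. The minimal 3-column dialect is
    taken as already being in the canonical cm frame.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        body = fh.read()
    if header == TRACKER_HEADER:
        df = pd.read_csv(io.StringIO(body), header=None, names=header.split(","))
        t = df["time_s"].to_numpy(float)
        missing_frac = (~np.isfinite(df[["x_px", "y_px"]].to_numpy(float)).all(axis=1)).mean()
        if missing_frac > max_missing_frac:
            raise TrackingQualityError(
                f"{missing_frac:.0%} of frames missing (limit {max_missing_frac:.0%})"
            )
        if calibration is None:
            lms = np.nanmedian(
                df[[f"lm{i}_{ax}" for i in (1, 2, 3, 4) for ax in "xy"]]
                .to_numpy(float)
                .reshape(-1, 4, 2),
                axis=0,
            )
            calibration = calibrate_from_landmarks(lms, arena)
        t2, xr, yr = _interpolate_gaps(
            t, df["x_px"].to_numpy(float), df["y_px"].to_numpy(float), max_gap_s
        )
        pos = calibration.apply(np.stack([xr, yr], axis=1))
        traj = Trajectory(t2, pos[:, 0], pos[:, 1], fps=fps)
    elif header == MINIMAL_HEADER:
        log.info("reading %s in pre-calibrated (cm) mode", path)
        df = pd.read_csv(io.StringIO(body), header=None, names=header.split(","))
        t = df["time_s"].to_numpy(float)
        t2, xr, yr = _interpolate_gaps(
            t, df["x_cm"].to_numpy(float), df["y_cm"].to_numpy(float), max_gap_s
        )
        traj = Trajectory(t2, xr, yr, fps=fps)
    else:
        raise TrackingFormatError(f"unrecognised header: {header!r}")
    return TrialRecording(traj, arena, animal_id, trial_index, condition)


def write_tracking_table(path, traj: Trajectory, *, landmarks_px=None, calibration=None) -> None:
    """Write a trajectory in the canonical dialect.

    Without ``calibration`` the minimal cm dialect is written. With a
    calibration (cm -> px is its inverse) and 4 landmark pixel positions,
    the full tracker dialect is emitted.
    """
    if calibration is None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(MINIMAL_HEADER + "\n")
            for t, x, y in zip(traj.t, traj.x, traj.y):
                fh.write(f"{t:.6f},{x:.6f},{y:.6f}\n")
        return
    inv = calibration.invert()
    px = inv.apply(traj.positions())
    lm = np.asarray(landmarks_px, dtype=float).reshape(4, 2)
    lm_csv = ",".join(f"{v:.6f}" for v in lm.ravel())
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(TRACKER_HEADER + "\n")
        for i, (t, (x, y)) in enumerate(zip(traj.t, px)):
            fh.write(f"{i},{t:.6f},{x:.6f},{y:.6f},{lm_csv}\n")


def align_to_spot(traj: Trajectory, spot_center) -> Trajectory:
    """Translate so the cool spot sits at (0, 0); a pure isometry."""
    cx, cy = float(spot_center[0]), float(spot_center[1])
    return replace(traj, x=traj.x - cx, y=traj.y - cy)


def speed_series(traj: Trajectory) -> np.ndarray:
    """Per-frame speed (cm/s) via central differences on the time stamps."""
    if len(traj) < 2:
        raise ValueError("speed requires at least 2 frames")
    vx = np.gradient(traj.x, traj.t)
    vy = np.gradient(traj.y, traj.t)
    return np.hypot(vx, vy)
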
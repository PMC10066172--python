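"""Approach-path isolation and wall-distance featurization.

For every successful stay, the last 3 s of trajectory preceding the first
on-spot frame form an *approach path*. Each path is converted to a 1-D
series of per-frame minimum distances to the arena perimeter and min-max
scaled to [0, 1], giving shape-comparable time series for strategy
clustering regardless of arena geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arena import Arena, distance_to_perimeter
from .metrics import Stay
from .trajectory import TrialRecording

__all__ = [
    "ApproachPath",
    "WallDistanceSeries",
    "extract_approach_paths",
    "wall_distance_series",
    "minmax_scale",
]

APPROACH_WINDOW_S = 3.0
MAX_ON_SPOT_FRAC = 0.95


@dataclass(frozen=True)
class ApproachPath:
    """The trajectory window ending at a successful stay's first on-spot frame."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    animal_id: str
    trial_index: int
    stay_index: int
    shape_kind: str

    def __len__(self) -> int:
        return len(self.t)

    def positions(self) -> np.ndarray:
        return np.stack([self.x, self.y], axis=1)


@dataclass(frozen=True)
class WallDistanceSeries:
    """Per-frame wall distance of one approach path, raw (cm) and scaled [0,1]."""

    raw_values: np.ndarray
    values: np.ndarray
    path: ApproachPath | None = None

    def __len__(self) -> int:
        return len(self.values)


def extract_approach_paths(
    rec: TrialRecording,
    stays: list[Stay],
    window_s: float = APPROACH_WINDOW_S,
    max_on_spot_frac: float = MAX_ON_SPOT_FRAC,
) -> list[ApproachPath]:
    """Isolate the pre-arrival window for each successful stay.

    The window covers ``[start - window_s, start)``. Windows truncated by
    the trial start (insufficient history) are dropped, as are windows
    whose on-spot fraction exceeds ``max_on_spot_frac`` — those capture
    jitter on the spot edge rather than an approach.
    """
    traj = rec.trajectory
    t = traj.t
    spot_r = rec.arena.cool_spot_radius
    out = []
    for k, stay in enumerate(stays):
        lo = stay.start_s - window_s
        if lo < t[0] - 1e-9:
            continue
        sel = (t >= lo - 1e-9) & (t < stay.start_s - 1e-9)
        if not sel.any():
            continue
        xs, ys = traj.x[sel], traj.y[sel]
        on_frac = float((np.hypot(xs, ys) <= spot_r).mean())
        if on_frac > max_on_spot_frac:
            continue
        out.append(
            ApproachPath(
                t=t[sel].copy(),
                x=xs.copy(),
                y=ys.copy(),
                animal_id=rec.animal_id,
                trial_index=rec.trial_index,
                stay_index=k,
                shape_kind=rec.arena.shape_kind,
            )
        )
    return out


def wall_distance_series(path: ApproachPath, arena: Arena) -> WallDistanceSeries:
    """Featurize a path as its per-frame minimum distance to the perimeter."""
    raw = np.asarray(distance_to_perimeter(arena, path.positions()), dtype=float)
    return WallDistanceSeries(raw_values=raw, values=minmax_scale(raw), path=path)


def minmax_scale(series) -> np.ndarray:
    """Scale to [0, 1] by the series' own extrema: (v - min) / (max - min).

    A constant series maps to all zeros (pinned at its own minimum), which
    avoids division by zero.
    """
    v = np.asarray(series, dtype=float)
    if v.size == 0:
        raise ValueError("cannot scale an empty series")
    lo, hi = v.min(), v.max()
    if hi - lo < 1e-300:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)
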
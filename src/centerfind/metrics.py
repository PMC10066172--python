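"""Per-trial behavioral measures for the center-finding task.

A *stay* is an on-spot bout of at least 5 s — the criterion for a
successful approach. Latency is the time from trial start to the first
on-spot frame (censored at the trial duration when the spot is never
reached). Movement characteristics: total path length, time in rest
(speed below threshold), wall-following time (within a band of the
perimeter) and the proportion of time on the cool spot. Occupancy maps
pool recordings into a per-cell fraction-of-time grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arena import Arena, contains, distance_to_perimeter
from .trajectory import TrialRecording, speed_series

__all__ = [
    "Stay",
    "TrialMetrics",
    "on_spot_mask",
    "detect_stays",
    "latency_first_arrival",
    "movement_metrics",
    "occupancy_map",
    "METRICS_COLUMNS",
]

STAY_MIN_DURATION_S = 5.0
STAY_MAX_GAP_S = 0.2
REST_SPEED_CMS = 0.5
WALL_BAND_CM = 2.0

METRICS_COLUMNS = [
    "animal_id",
    "trial_index",
    "condition",
    "shape",
    "latency_s",
    "censored",
    "prop_on_spot",
    "distance_cm",
    "rest_s",
    "wall_follow_s",
    "n_successful_stays",
]


@dataclass(frozen=True)
class Stay:
    """A successful on-spot bout.

    ``start_s`` is the time of the first on-spot frame; ``end_s`` extends one
    frame interval past the last on-spot frame, so a bout of n frames at
    interval dt has duration n*dt (each frame credits one interval).
    """

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("stay must have positive duration")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class TrialMetrics:
    latency_s: float
    censored: bool
    prop_on_spot: float
    distance_cm: float
    rest_s: float
    wall_follow_s: float
    n_successful_stays: int


def on_spot_mask(rec: TrialRecording) -> np.ndarray:
    """True where the animal's center is within the cool-spot disc (closed)."""
    r = np.hypot(rec.trajectory.x, rec.trajectory.y)
    return r <= rec.arena.cool_spot_radius


def detect_stays(
    mask: np.ndarray,
    frame_times: np.ndarray,
    min_duration_s: float = STAY_MIN_DURATION_S,
    max_gap_s: float = STAY_MAX_GAP_S,
) -> list[Stay]:
    """Find successful stays: maximal on-spot runs with short gaps bridged.

    Off-spot interruptions no longer than ``max_gap_s`` (tracker jitter at
    the spot edge) are bridged before applying the duration threshold. Each
    frame credits one frame interval, so a run of n on-frames at interval
    dt lasts n*dt and bridged gaps contribute their elapsed time.
    """
    mask = np.asarray(mask, dtype=bool)
    t = np.asarray(frame_times, dtype=float)
    if len(mask) != len(t):
        raise ValueError("mask and frame_times must have equal length")
    if not mask.any():
        return []
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
    idx = np.flatnonzero(mask)
    # off-gap between successive on-frames, excluding the one-frame step
    gaps = t[idx[1:]] - t[idx[:-1]] - dt
    breaks = np.flatnonzero(gaps > max_gap_s + 1e-12)
    runs = np.split(idx, breaks + 1)
    stays = []
    for run in runs:
        start, end = t[run[0]], t[run[-1]] + dt
        if end - start >= min_duration_s - 1e-12:
            stays.append(Stay(start, end))
    return stays


def latency_first_arrival(
    rec: TrialRecording, trial_duration_s: float = 300.0
) -> tuple[float, bool]:
    """Latency to the first on-spot frame; ``(duration, True)`` if censored."""
    mask = on_spot_mask(rec)
    t = rec.trajectory.t
    if mask.any():
        return float(t[np.argmax(mask)] - t[0]), False
    return trial_duration_s, True


def movement_metrics(
    rec: TrialRecording,
    rest_speed_cms: float = REST_SPEED_CMS,
    wall_band_cm: float = WALL_BAND_CM,
    trial_duration_s: float = 300.0,
) -> TrialMetrics:
    """All per-trial movement characteristics in one pass."""
    traj = rec.trajectory
    t = traj.t
    dt = traj.median_dt

    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    distance = float(np.hypot(dx, dy).sum())

    speeds = speed_series(traj) if len(traj) >= 2 else np.zeros(len(traj))
    rest_s = float((speeds < rest_speed_cms).sum() * dt)

    wall_d = distance_to_perimeter(rec.arena, traj.positions())
    wall_follow_s = float((wall_d <= wall_band_cm).sum() * dt)

    mask = on_spot_mask(rec)
    prop = float(mask.mean()) if len(mask) else 0.0

    latency, censored = latency_first_arrival(rec, trial_duration_s)
    stays = detect_stays(mask, t)
    return TrialMetrics(
        latency_s=latency,
        censored=censored,
        prop_on_spot=min(prop, 1.0),
        distance_cm=distance,
        rest_s=rest_s,
        wall_follow_s=wall_follow_s,
        n_successful_stays=len(stays),
    )


def occupancy_map(
    recs: list[TrialRecording], bin_cm: float = 1.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled occupancy grid: fraction of frames per cell, outside-arena masked.

    Returns ``(grid, x_edges, y_edges)`` where ``grid[i, j]`` is the time
    fraction for cell (x bin i, y bin j); cells whose centers fall outside
    the arena are NaN. In-arena cells sum to 1.
    """
    if not recs:
        raise ValueError("occupancy_map needs at least one recording")
    shapes = {r.arena.shape_kind for r in recs}
    if len(shapes) > 1:
        raise ValueError(f"recordings mix arena shapes: {sorted(shapes)}")
    arena = recs[0].arena
    if arena.is_circle:
        lim = arena.radius
        xmin = ymin = -lim
        xmax = ymax = lim
    else:
        v = arena.vertices
        xmin, ymin = v.min(axis=0)
        xmax, ymax = v.max(axis=0)
    x_edges = np.arange(np.floor(xmin), np.ceil(xmax) + bin_cm, bin_cm)
    y_edges = np.arange(np.floor(ymin), np.ceil(ymax) + bin_cm, bin_cm)

    xs = np.concatenate([r.trajectory.x for r in recs])
    ys = np.concatenate([r.trajectory.y for r in recs])
    grid, _, _ = np.histogram2d(xs, ys, bins=[x_edges, y_edges])
    total = grid.sum()
    if total == 0:
        raise ValueError("no frames to pool")
    grid /= total

    cx = (x_edges[:-1] + x_edges[1:]) / 2
    cy = (y_edges[:-1] + y_edges[1:]) / 2
    centers = np.stack(np.meshgrid(cx, cy, indexing="ij"), axis=-1).reshape(-1, 2)
    inside = np.asarray(contains(arena, centers)).reshape(len(cx), len(cy))
    grid[~inside] = np.nan
    return grid, x_edges, y_edges
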
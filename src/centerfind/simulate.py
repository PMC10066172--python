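"""Synthetic center-finding sessions with known ground truth.

Generates arena-constrained trajectories that emulate the behavior seen in
heated-arena experiments: a thigmotactic exploration phase, one of four
approach-strategy archetypes, stay/leave dynamics on the cool spot, and
trial-over-trial learning (decreasing latency, increasing time-on-spot)
that is linear on the analysis scales (sqrt proportion, log latency).
Because every trial is built from a known plan, every pipeline stage can
be validated without real tracking data.

Movement model
--------------
Positions are parameterized radially from the cool spot: ``p = r * (cos
th, sin th)`` with ``r = rho(th) - w``, where ``rho`` is the boundary
distance in direction ``th`` (all four arenas are convex and star-shaped
from the spot) and ``w`` a target wall-distance profile in cm. Heading
and wall-distance noise are AR(1) (discrete Ornstein-Uhlenbeck) processes,
the minimal correlated-random-walk structure. Containment is guaranteed
by clamping ``r`` inside ``[0, rho]``; this plays the role of a reflective
boundary in the radial coordinate.

Approach archetypes (wall-distance profile ``g`` over the 3 s window,
scaled between the wall band and the spot):

* ``wall_then_direct`` — flat at the wall, then a straight late run in.
* ``spiral_inward`` — concave inward spiral; wall distance rises fast
  early, saturating near the spot.
* ``arch_ventures`` — an arch out toward the middle and back to the wall,
  then a final run to the spot.
* ``center_out_return`` — starts on the spot, ventures out, returns.

A ``separation`` level blends each archetype profile with a common linear
ramp: 1.0 keeps the archetypes fully distinct, 0.0 collapses all four to
identical parameters (the null benchmark for cluster recovery).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .arena import (
    Arena,
    CalibrationTransform,
    SHAPE_SPECS,
    build_arena,
    canonical_landmarks,
)
from .trajectory import Trajectory, TrialRecording, write_tracking_table

__all__ = [
    "ARCHETYPES",
    "StrategyArchetype",
    "SessionConfig",
    "gen_strategy_path",
    "gen_cluster_benchmark",
    "gen_session",
    "SessionResult",
]

ARCHETYPES = (
    "wall_then_direct",
    "spiral_inward",
    "arch_ventures",
    "center_out_return",
)

SEPARATION_LEVELS = {"high": 1.0, "low": 0.4, "zero": 0.0}


@dataclass(frozen=True)
class StrategyArchetype:
    """Kinematic parameters of one approach strategy."""

    name: str
    angular_rate: float  # rad/s drift of the position angle
    wall_offset_cm: float = 0.8  # distance kept from the wall when hugging it
    profile_jitter: float = 0.06  # per-path jitter of profile shape parameters
    noise_sd: float = 0.02  # AR(1) noise sd on the normalized profile
    mixture_weight: float = 0.25


DEFAULT_ARCHETYPES: dict[str, StrategyArchetype] = {
    # weights reflect the field observation that the wall-following-then-
    # direct strategy dominates, followed by the gradual/spiral approach
    "wall_then_direct": StrategyArchetype("wall_then_direct", 0.37, mixture_weight=0.45),
    "spiral_inward": StrategyArchetype("spiral_inward", 0.50, mixture_weight=0.25),
    "arch_ventures": StrategyArchetype("arch_ventures", 0.30, mixture_weight=0.12),
    "center_out_return": StrategyArchetype("center_out_return", 0.25, mixture_weight=0.18),
}


@dataclass(frozen=True)
class SessionConfig:
    """Study conditions for one synthetic session (one arena shape).

    Defaults mirror the experimental design: 15 animals per shape, 10
    trials of 300 s at 30 fps. Learning is linear on the transformed
    scales: ``sqrt(prop) = prop_start + prop_slope * (trial - 1)`` and
    ``log(latency + 1) = lat_log_start + lat_log_slope * (trial - 1)``,
    plus animal-level intercept variation and trial-level noise.
    """

    shape: str = "circle"
    n_animals: int = 15
    n_trials: int = 10
    trial_s: float = 300.0
    fps: float = 30.0
    seed: int = 0
    condition: str = "heated"
    has_cool_spot: bool = True
    # learning dynamics on the transformed scales
    prop_slope: float = 0.026
    prop_start: float = 0.15
    prop_noise_sd: float = 0.05
    prop_animal_sd: float = 0.04
    lat_log_slope: float = -0.185
    lat_log_start: float = 5.0
    lat_noise_sd: float = 0.30
    lat_animal_sd: float = 0.25
    archetypes: dict = field(default_factory=lambda: dict(DEFAULT_ARCHETYPES))

    def __post_init__(self) -> None:
        if self.shape not in SHAPE_SPECS:
            raise ValueError(f"shape must be one of {sorted(SHAPE_SPECS)}")
        if min(self.n_animals, self.n_trials) < 1 or self.trial_s <= 0 or self.fps <= 0:
            raise ValueError("all counts and durations must be positive")


@dataclass
class SessionResult:
    """In-memory synthetic session: recordings plus the ground-truth plan."""

    config: SessionConfig
    arena: Arena
    recordings: list
    truth: pd.DataFrame
    approach_truth: pd.DataFrame


# ---------------------------------------------------------------------------
# geometry helpers


def boundary_radius(arena: Arena, theta) -> np.ndarray:
    """Distance from the origin (cool spot) to the boundary along ``theta``."""
    th = np.atleast_1d(np.asarray(theta, dtype=float))
    if arena.is_circle:
        out = np.full(th.shape, arena.radius)
        return out
    u = np.stack([np.cos(th), np.sin(th)], axis=1)  # (m, 2)
    a = arena.vertices
    e = np.roll(a, -1, axis=0) - a
    cross_ue = u[:, None, 0] * e[None, :, 1] - u[:, None, 1] * e[None, :, 0]
    cross_ae = a[None, :, 0] * e[None, :, 1] - a[None, :, 1] * e[None, :, 0]
    cross_au = a[None, :, 0] * u[:, None, 1] - a[None, :, 1] * u[:, None, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = cross_ae / cross_ue
        s = cross_au / cross_ue
    valid = (s >= -1e-9) & (s <= 1 + 1e-9) & (t > 0)
    t = np.where(valid, t, np.inf)
    return t.min(axis=1)


def _ar1(rng: np.random.Generator, n: int, sd: float, phi: float = 0.97) -> np.ndarray:
    """Stationary AR(1) noise (discrete OU): smooth correlated wander."""
    if n == 0:
        return np.zeros(0)
    eps = rng.normal(0.0, sd * math.sqrt(1 - phi**2), size=n)
    eps[0] = rng.normal(0.0, sd)
    return lfilter([1.0], [1.0, -phi], eps)


# ---------------------------------------------------------------------------
# archetype profiles


def _archetype_profile(name: str, tau: np.ndarray, rng: np.random.Generator,
                       jitter: float) -> np.ndarray:
    """Noise-free normalized wall-distance profile g(tau) in [0, 1]."""
    j = lambda center, scale: center + scale * (rng.uniform() - 0.5) * 2 * jitter / 0.06
    if name == "wall_then_direct":
        f = min(max(j(0.52, 0.06), 0.3), 0.7)
        g = np.where(tau < f, 0.0, (tau - f) / (1.0 - f))
    elif name == "spiral_inward":
        # gradual, hesitant approach: concave rise with advance-retreat
        # dips (intermittent locomotion), the signature that distinguishes
        # it from a committed late dash under time warping
        lam = max(j(2.2, 0.15), 1.0)
        g = (1.0 - np.exp(-lam * tau)) / (1.0 - math.exp(-lam))
        amp = min(max(j(0.22, 0.02), 0.05), 0.35)
        phase = (rng.uniform() - 0.5) * 0.2
        g = g + amp * np.sin(2 * np.pi * 3.0 * tau + phase - np.pi / 2)
        g = np.clip(g, 0.0, 1.0)
    elif name == "arch_ventures":
        a_mid = min(max(j(0.50, 0.04), 0.3), 0.75)
        t1, t2 = 0.55, 0.72
        g = np.where(
            tau < t1,
            a_mid * np.sin(np.pi * tau / t1),
            np.where(tau < t2, 0.0, (tau - t2) / (1.0 - t2)),
        )
    elif name == "center_out_return":
        depth = min(max(j(0.8, 0.04), 0.5), 0.98)
        g = 1.0 - depth * np.sin(np.pi * tau)
    else:
        raise ValueError(f"unknown archetype {name!r}")
    return g


def gen_strategy_path(
    archetype: str | StrategyArchetype,
    arena: Arena,
    duration_s: float = 3.0,
    seed: int | None = None,
    fps: float = 30.0,
    separation: float | str = "high",
    theta0: float | None = None,
) -> Trajectory:
    """One approach-strategy trajectory window ending on the cool spot.

    ``separation`` blends the archetype wall-distance profile with a common
    linear ramp (1.0 = archetype as-is, 0.0 = all archetypes identical).
    Deterministic for a given seed.
    """
    if isinstance(archetype, str):
        archetype = DEFAULT_ARCHETYPES[archetype]
    s = SEPARATION_LEVELS.get(separation, separation) if isinstance(separation, str) else float(separation)
    rng = np.random.default_rng(seed)
    n = max(2, int(round(duration_s * fps)))
    dt = 1.0 / fps
    tau = np.arange(n) / (n - 1)

    g_arch = _archetype_profile(archetype.name, tau, rng, archetype.profile_jitter)
    g = s * g_arch + (1.0 - s) * tau
    g = g + _ar1(rng, n, archetype.noise_sd)
    g = np.clip(g, 0.0, 1.05)

    direction = rng.choice([-1.0, 1.0])
    th0 = rng.uniform(0, 2 * np.pi) if theta0 is None else theta0
    th = th0 + direction * archetype.angular_rate * np.arange(n) * dt
    th = th + _ar1(rng, n, 0.15)

    rho = boundary_radius(arena, th)
    w_near = archetype.wall_offset_cm
    w_far = rho - 1.5  # wall distance when sitting at the spot center region
    w = w_near + g * (w_far - w_near)
    r = np.clip(rho - w, 0.3, rho - 0.3)
    # construction contract: the path ends on the spot (and starts there for
    # the center-out-and-return strategy)
    r[-1] = min(r[-1], 1.5)
    if archetype.name == "center_out_return" and s >= 0.5:
        r[0] = min(r[0], 1.5)

    t = np.arange(n) * dt
    return Trajectory(t, r * np.cos(th), r * np.sin(th), fps=fps)


def gen_cluster_benchmark(
    n_per_archetype: int = 40,
    arena: Arena | None = None,
    separation: float | str = "high",
    seed: int = 0,
    fps: float = 30.0,
    window_s: float = 3.0,
) -> tuple[list[Trajectory], np.ndarray]:
    """Balanced labeled approach windows from the four archetypes.

    Returns ``(trajectories, labels)`` with labels indexing ``ARCHETYPES``.
    The validation harness for DTW + PAM cluster recovery.
    """
    if n_per_archetype < 1:
        raise ValueError("need at least one path per archetype")
    if arena is None:
        arena = build_arena(SHAPE_SPECS["circle"])
    rng = np.random.default_rng(seed)
    paths, labels = [], []
    for li, name in enumerate(ARCHETYPES):
        for _ in range(n_per_archetype):
            child = int(rng.integers(0, 2**31 - 1))
            paths.append(
                gen_strategy_path(
                    name, arena, duration_s=window_s, seed=child, fps=fps,
                    separation=separation,
                )
            )
            labels.append(li)
    return paths, np.asarray(labels)


# ---------------------------------------------------------------------------
# full sessions


def plan_session(cfg: SessionConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the per-trial targets (the ground truth) for one session."""
    rows = []
    names = [n for n in cfg.archetypes if n != "center_out_return"]
    weights = np.array([cfg.archetypes[n].mixture_weight for n in names])
    weights = weights / weights.sum()
    for a in range(cfg.n_animals):
        animal = f"{cfg.shape[:4]}{a + 1:02d}"
        prop_icept = cfg.prop_start + rng.normal(0, cfg.prop_animal_sd)
        lat_icept = cfg.lat_log_start + rng.normal(0, cfg.lat_animal_sd)
        for trial in range(1, cfg.n_trials + 1):
            sqrt_prop = prop_icept + cfg.prop_slope * (trial - 1) + rng.normal(0, cfg.prop_noise_sd)
            log_lat = lat_icept + cfg.lat_log_slope * (trial - 1) + rng.normal(0, cfg.lat_noise_sd)
            latency = float(np.clip(math.exp(log_lat) - 1.0, 5.0, cfg.trial_s * 0.97))
            prop = float(np.clip(sqrt_prop, 0.0, 0.95) ** 2)
            # on-spot time cannot exceed the time remaining after arrival
            prop = min(prop, (cfg.trial_s - latency) / cfg.trial_s * 0.98)
            rows.append(
                {
                    "animal_id": animal,
                    "trial_index": trial,
                    "shape": cfg.shape,
                    "condition": cfg.condition,
                    "target_latency_s": latency if cfg.has_cool_spot else float("nan"),
                    "target_prop": prop if cfg.has_cool_spot else 0.0,
                    "first_archetype": (
                        str(rng.choice(names, p=weights)) if cfg.has_cool_spot else ""
                    ),
                    "render_seed": int(rng.integers(0, 2**31 - 1)),
                }
            )
    return pd.DataFrame(rows)


def _exploration(arena, n, dt, rng, spot_clear=3.5):
    """Thigmotactic wander: wall-hugging with occasional inward loops."""
    if n == 0:
        return np.zeros(0), np.zeros(0)
    direction = rng.choice([-1.0, 1.0])
    th = rng.uniform(0, 2 * np.pi) + direction * 0.35 * np.arange(n) * dt
    th = th + _ar1(rng, n, 0.4)
    w = 0.9 + np.abs(_ar1(rng, n, 1.6))
    rho = boundary_radius(arena, th)
    r = np.clip(rho - w, spot_clear, rho - 0.3)
    return r, th


def _render_trial(
    arena: Arena, cfg: SessionConfig, plan_row: dict, rng: np.random.Generator
) -> tuple[Trajectory, list[dict]]:
    """Construct one trial trajectory realizing the planned targets exactly.

    The on-spot frame budget is scheduled explicitly (arrival frame, stay
    bouts, excursions), so the realized latency and time-on-spot proportion
    match the plan to within one frame.
    """
    n = int(round(cfg.trial_s * cfg.fps))
    dt = 1.0 / cfg.fps
    windows: list[dict] = []

    if not cfg.has_cool_spot or not np.isfinite(plan_row["target_latency_s"]):
        r, th = _exploration(arena, n, dt, rng)
        t = np.arange(n) * dt
        return Trajectory(t, r * np.cos(th), r * np.sin(th), fps=cfg.fps), windows

    lat_f = int(round(plan_row["target_latency_s"] / dt))
    lat_f = min(max(lat_f, 1), n - 2)
    n_app = min(int(round(3.0 * cfg.fps)), lat_f + 1)  # frames ending at arrival
    n_exp = lat_f + 1 - n_app

    r_exp, th_exp = _exploration(arena, n_exp, dt, rng)

    app = gen_strategy_path(
        cfg.archetypes[plan_row["first_archetype"]],
        arena,
        duration_s=n_app * dt,
        seed=int(rng.integers(0, 2**31 - 1)),
        fps=cfg.fps,
        separation="high",
        theta0=float(th_exp[-1]) if n_exp else None,
    )
    r_app = np.hypot(app.x, app.y)
    th_app = np.arctan2(app.y, app.x)
    # keep pre-arrival frames strictly off the spot so latency is exact
    r_app[:-1] = np.maximum(r_app[:-1], arena.cool_spot_radius + 0.05)
    r_app[-1] = 1.5
    if n_exp:  # short crossfade so the two phases join continuously
        k = min(10, n_app // 3)
        blend = np.linspace(1.0, 0.0, k)
        r_app[:k] = blend * r_exp[-1] + (1 - blend) * r_app[:k]

    # schedule the remaining on-spot frames as bouts separated by excursions
    n_on_total = int(round(plan_row["target_prop"] * n))
    m = n - lat_f - 1  # frames after the arrival frame
    n_on_rem = int(np.clip(n_on_total - 1, 0, m))
    segs: list[tuple[str, int]] = []
    if n_on_rem >= m - int(2.0 / dt):
        segs.append(("on", m))
        n_off = m - n_on_rem  # ignored: almost fully on
    else:
        nb = int(np.clip(round(n_on_rem * dt / 40.0), 1, 6))
        bout = [n_on_rem // nb] * nb
        bout[0] += n_on_rem - sum(bout)
        n_off = m - n_on_rem
        exc = [n_off // nb] * nb
        exc[-1] += n_off - sum(exc)
        for b, e in zip(bout, exc):
            if b > 0:
                segs.append(("on", b))
            if e > 0:
                segs.append(("off", e))

    r_rest = np.empty(m)
    th_rest = np.empty(m)
    pos = 0
    th_cur = th_app[-1]
    spot_r = arena.cool_spot_radius
    for kind, length in segs:
        if kind == "on":
            r_rest[pos : pos + length] = np.clip(
                1.2 + _ar1(rng, length, 0.5), 0.1, spot_r - 0.6
            )
            th_rest[pos : pos + length] = th_cur + _ar1(rng, length, 0.8)
        else:
            tau = np.linspace(0, 1, length)
            rho_here = float(boundary_radius(arena, np.array([th_cur]))[0])
            r_far = rng.uniform(0.5, 0.9) * rho_here
            prof = spot_r + 0.1 + (r_far - spot_r - 0.1) * np.sin(np.pi * tau)
            drift = rng.choice([-1.0, 1.0]) * 0.3 * np.arange(length) * dt
            th_e = th_cur + drift + _ar1(rng, length, 0.2)
            rho_e = boundary_radius(arena, th_e)
            r_rest[pos : pos + length] = np.clip(prof, spot_r + 0.05, rho_e - 0.3)
            th_rest[pos : pos + length] = th_e
            th_cur = th_e[-1]
            windows.append({"kind": "return", "end_frame": lat_f + pos + length})
        pos += length

    r = np.concatenate([r_exp, r_app, r_rest])
    th = np.concatenate([th_exp, th_app, th_rest])
    t = np.arange(n) * dt
    windows.insert(
        0, {"kind": plan_row["first_archetype"], "end_frame": lat_f}
    )
    return Trajectory(t, r * np.cos(th), r * np.sin(th), fps=cfg.fps), windows


def gen_session(cfg: SessionConfig, out_dir: str | Path | None = None) -> SessionResult:
    """Generate one full synthetic session.

    In-memory by default; with ``out_dir`` the session is also written in
    the canonical layout ``<out>/<shape>/<animal>/trial<k>.csv`` (full
    tracker dialect through a synthetic camera) plus ``truth.json``.
    Deterministic for a given config.
    """
    arena = build_arena(SHAPE_SPECS[cfg.shape])
    rng = np.random.default_rng(cfg.seed)
    plan = plan_session(cfg, rng)

    # synthetic camera for the pixel dialect: ~10 px/cm, rotated and offset
    cam_rot = rng.uniform(-0.3, 0.3)
    cam = CalibrationTransform(
        scale=0.1, rotation=cam_rot, translation=np.array([0.0, 0.0]), rms_residual=0.0
    )
    landmarks_px = cam.invert().apply(canonical_landmarks(arena))

    recordings = []
    approach_rows = []
    for row in plan.to_dict("records"):
        traj, windows = _render_trial(arena, cfg, row, np.random.default_rng(row["render_seed"]))
        rec = TrialRecording(
            traj, arena, row["animal_id"], row["trial_index"], cfg.condition
        )
        recordings.append(rec)
        for w in windows:
            approach_rows.append(
                {
                    "animal_id": row["animal_id"],
                    "trial_index": row["trial_index"],
                    "shape": cfg.shape,
                    "archetype": "center_out_return" if w["kind"] == "return" else w["kind"],
                    "arrival_frame": w["end_frame"],
                }
            )
        if out_dir is not None:
            d = Path(out_dir) / cfg.shape / row["animal_id"]
            d.mkdir(parents=True, exist_ok=True)
            write_tracking_table(
                d / f"trial{row['trial_index']:02d}.csv",
                traj,
                landmarks_px=landmarks_px,
                calibration=cam,
            )
    approach_truth = pd.DataFrame(
        approach_rows,
        columns=["animal_id", "trial_index", "shape", "archetype", "arrival_frame"],
    )
    if out_dir is not None:
        truth = {
            "config": {k: v for k, v in asdict(cfg).items() if k != "archetypes"},
            "camera": {"scale_cm_per_px": cam.scale, "rotation_rad": cam.rotation},
            "plan": plan.to_dict("records"),
            "approaches": approach_truth.to_dict("records"),
        }
        with open(Path(out_dir) / cfg.shape / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(truth, fh, indent=1, default=float)
    return SessionResult(cfg, arena, recordings, plan, approach_truth)
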
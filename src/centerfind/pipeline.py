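"""Stage orchestration: session discovery, metrics, slopes, clustering.

The on-disk session layout is ``<root>/<shape>/<animal>/trial<k>.csv`` in
the tracking dialect, as produced by :func:`centerfind.simulate.gen_session`
or by converting real tracker output. Each stage consumes the previous
stage's outputs and writes plain CSV/JSON (plots are conveniences; the
numeric files are the contract surface).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import asdict
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .approach import extract_approach_paths, wall_distance_series
from .arena import SHAPE_SPECS, build_arena
from .clustering import cluster_counts, pam_cluster, validity_scan
from .config import PipelineConfig
from .dtw import DTWConfig, dtw_matrix
from .metrics import METRICS_COLUMNS, detect_stays, movement_metrics, occupancy_map, on_spot_mask
from .stats import RESPONSES, estimate_learning_slope
from .trajectory import TrialRecording, read_tracking_table

__all__ = [
    "discover_session",
    "load_session",
    "metrics_table",
    "analyze",
    "cluster",
    "write_report",
]

log = logging.getLogger(__name__)


def discover_session(session_dir) -> list[dict]:
    """List (shape, animal, trial, path) entries under a session root."""
    root = Path(session_dir)
    entries = []
    for shape in sorted(SHAPE_SPECS):
        shape_dir = root / shape
        if not shape_dir.is_dir():
            continue
        for animal_dir in sorted(p for p in shape_dir.iterdir() if p.is_dir()):
            for f in sorted(animal_dir.glob("trial*.csv")):
                m = re.search(r"trial(\d+)", f.name)
                if m:
                    entries.append(
                        {
                            "shape": shape,
                            "animal_id": animal_dir.name,
                            "trial_index": int(m.group(1)),
                            "path": f,
                        }
                    )
    return entries


def load_session(session_dir, cfg: PipelineConfig, condition: str = "heated") -> list[TrialRecording]:
    """Read every trial CSV of a session into calibrated recordings."""
    entries = discover_session(session_dir)
    if not entries:
        raise FileNotFoundError(f"no session data under {session_dir}")
    recs = []
    arenas = {}
    for e in entries:
        arena = arenas.setdefault(e["shape"], build_arena(SHAPE_SPECS[e["shape"]]))
        recs.append(
            read_tracking_table(
                e["path"],
                arena,
                animal_id=e["animal_id"],
                trial_index=e["trial_index"],
                condition=condition,
                fps=cfg.fps,
            )
        )
    return recs


def metrics_table(recs: list[TrialRecording], cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Tidy per-trial metrics: one row per (animal, trial)."""
    cfg = cfg or PipelineConfig()
    rows = []
    for rec in recs:
        m = movement_metrics(
            rec,
            rest_speed_cms=cfg.rest_speed_cms,
            wall_band_cm=cfg.wall_band_cm,
            trial_duration_s=cfg.trial_s,
        )
        rows.append(
            {
                "animal_id": rec.animal_id,
                "trial_index": rec.trial_index,
                "condition": rec.condition,
                "shape": rec.arena.shape_kind,
                "latency_s": m.latency_s,
                "censored": m.censored,
                "prop_on_spot": m.prop_on_spot,
                "distance_cm": m.distance_cm,
                "rest_s": m.rest_s,
                "wall_follow_s": m.wall_follow_s,
                "n_successful_stays": m.n_successful_stays,
            }
        )
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


def analyze(recs: list[TrialRecording], cfg: PipelineConfig, out_dir) -> dict:
    """Metrics CSV + per-shape learning slopes JSON + occupancy grids."""
    if not recs:
        raise ValueError("empty session: nothing to analyze")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = metrics_table(recs, cfg)
    df.to_csv(out / "metrics.csv", index=False)
    log.info(
        "analyzed %d trials (%d censored latencies)", len(df), int(df["censored"].sum())
    )

    slopes = []
    for shape in sorted(df["shape"].unique()):
        for response in RESPONSES:
            try:
                s = estimate_learning_slope(
                    df,
                    shape,
                    response,
                    log_offset=cfg.log_latency_offset_s,
                    n_bootstrap=cfg.n_bootstrap,
                    seed=cfg.seed,
                )
            except ValueError as exc:
                log.warning("slope %s/%s skipped: %s", shape, response, exc)
                continue
            rec = asdict(s)
            rec["per_animal_slopes"] = [float(v) for v in s.per_animal_slopes]
            slopes.append(rec)
    with open(out / "slopes.json", "w", encoding="utf-8") as fh:
        json.dump({"version": __version__, "slopes": slopes}, fh, indent=1, default=float)

    grids = {}
    for shape in sorted({r.arena.shape_kind for r in recs}):
        shape_recs = [r for r in recs if r.arena.shape_kind == shape]
        grid, xe, ye = occupancy_map(shape_recs, bin_cm=cfg.occupancy_bin_cm)
        grids[shape] = grid
        np.savetxt(out / f"occupancy_{shape}.csv", grid, delimiter=",", fmt="%.8g")
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(
            np.where(np.isnan(grid), 0, grid).T,
            origin="lower",
            extent=[xe[0], xe[-1], ye[0], ye[-1]],
            cmap="inferno",
        )
        ax.set_title(f"occupancy: {shape}")
        fig.savefig(out / f"occupancy_{shape}.png", dpi=120)
        plt.close(fig)

    cfg.to_yaml(out / "config.yaml")
    return {"metrics": df, "slopes": slopes, "occupancy": grids}


def _approach_features(recs, cfg: PipelineConfig):
    """Extract approach paths and their scaled wall-distance series."""
    paths, series = [], []
    for rec in recs:
        mask = on_spot_mask(rec)
        stays = detect_stays(
            mask, rec.trajectory.t, min_duration_s=cfg.stay_min_s, max_gap_s=cfg.stay_max_gap_s
        )
        for p in extract_approach_paths(
            rec, stays, window_s=cfg.approach_window_s, max_on_spot_frac=cfg.max_on_spot_frac
        ):
            paths.append(p)
            series.append(wall_distance_series(p, rec.arena))
    return paths, series


def cluster(recs: list[TrialRecording], cfg: PipelineConfig, out_dir) -> dict:
    """Approach isolation -> featurization -> DTW -> PAM -> reports."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths, series = _approach_features(recs, cfg)
    if len(paths) < cfg.k:
        raise ValueError(
            f"only {len(paths)} approach paths found; need at least k={cfg.k}"
        )
    # long-format export of the features
    feat_rows = []
    for i, (p, w) in enumerate(zip(paths, series)):
        for f in range(len(p)):
            feat_rows.append(
                (p.animal_id, p.trial_index, p.stay_index, f, p.t[f], p.x[f], p.y[f],
                 w.raw_values[f], w.values[f])
            )
    pd.DataFrame(
        feat_rows,
        columns=["animal_id", "trial_index", "stay_index", "frame", "t_s",
                 "x_cm", "y_cm", "wall_dist_cm", "wall_dist_scaled"],
    ).to_csv(out / "approach_paths.csv", index=False)

    dtw_cfg = DTWConfig(cfg.dtw_step_pattern, cfg.dtw_window, cfg.dtw_normalize)
    d = dtw_matrix([w.values for w in series], dtw_cfg)
    np.savetxt(out / "dtw_matrix.csv", d, delimiter=",", fmt="%.8g")

    result = pam_cluster(d, k=cfg.k, seed=cfg.seed)
    labels_df = pd.DataFrame(
        {
            "animal_id": [p.animal_id for p in paths],
            "trial_index": [p.trial_index for p in paths],
            "stay_index": [p.stay_index for p in paths],
            "shape": [p.shape_kind for p in paths],
            "cluster": result.labels,
            "is_medoid": [i in set(result.medoid_indices) for i in range(len(paths))],
        }
    )
    labels_df.to_csv(out / "clusters.csv", index=False)

    counts = cluster_counts(result, [p.shape_kind for p in paths])
    counts.to_csv(out / "cluster_counts.csv")
    scan = validity_scan(d, cfg.k_scan, seed=cfg.seed)
    scan.to_csv(out / "validity_scan.csv", index=False)

    fig, axes = plt.subplots(1, cfg.k, figsize=(3 * cfg.k, 3))
    for c, ax in enumerate(np.atleast_1d(axes)):
        p = paths[result.medoid_indices[c]]
        ax.plot(p.x, p.y, "r-")
        ax.set_title(f"cluster {c} medoid")
        ax.set_aspect("equal")
    fig.savefig(out / "medoids.png", dpi=120)
    plt.close(fig)

    cfg.to_yaml(out / "config.yaml")
    log.info("clustered %d approach paths into k=%d", len(paths), cfg.k)
    return {"paths": paths, "distance_matrix": d, "result": result,
            "counts": counts, "scan": scan}


def write_report(analysis: dict, clustering: dict | None, out_dir) -> Path:
    """One JSON summary of slopes, counts and validity for downstream use."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {
        "version": __version__,
        "n_trials": int(len(analysis["metrics"])),
        "slopes": [
            {k: v for k, v in s.items() if k != "per_animal_slopes"}
            for s in analysis["slopes"]
        ],
    }
    if clustering is not None:
        report["cluster_sizes"] = (
            pd.Series(clustering["result"].labels).value_counts().sort_index().to_dict()
        )
        report["validity_scan"] = clustering["scan"].to_dict("records")
        report["counts_by_shape"] = {
            str(k): {str(c): int(v) for c, v in row.items()}
            for k, row in clustering["counts"].iterrows()
        }
    path = out / "report.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, default=float)
    return path
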
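"""K-medoid (PAM) clustering on a precomputed distance matrix.

Partitioning Around Medoids with greedy BUILD initialization and steepest-
descent SWAP, operating purely on pairwise distances: no triangle
inequality is assumed (DTW violates it) and no coordinates are needed.
Medoids — the members minimizing total within-cluster distance — double as
representative trajectories. Cluster numbering is canonicalized by
descending cluster size so labels are stable across runs.

Also: a distance-matrix silhouette (with the 0/0 -> 0 convention), a
within/between cost ratio, a k-scan to support choosing the cluster count,
and cluster-by-group contingency counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClusteringResult",
    "pam_cluster",
    "cluster_validity",
    "validity_scan",
    "cluster_counts",
    "silhouette_samples_precomputed",
]


@dataclass(frozen=True)
class ClusteringResult:
    distance_matrix: np.ndarray
    labels: np.ndarray  # cluster index per series, 0..k-1, canonicalized
    medoid_indices: np.ndarray  # one per cluster, medoid_indices[c] has label c
    k: int
    total_cost: float
    validity: dict = field(default_factory=dict)
    seed: int | None = None


def _check_matrix(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have zero diagonal")
    return d


def _build(d: np.ndarray, k: int) -> list[int]:
    """Greedy BUILD: first medoid minimizes total distance; each further
    medoid maximizes the decrease in total nearest-medoid cost (ties to the
    lowest index)."""
    n = len(d)
    first = int(np.argmin(d.sum(axis=1)))
    medoids = [first]
    nearest = d[first].copy()
    while len(medoids) < k:
        # gain of adding candidate c: sum of max(0, nearest - d[c])
        gains = np.maximum(nearest[None, :] - d, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        cand = int(np.argmax(gains))
        medoids.append(cand)
        nearest = np.minimum(nearest, d[cand])
    return medoids


def pam_cluster(
    dist_matrix, k: int = 4, seed: int | None = None, max_iter: int = 200
) -> ClusteringResult:
    """PAM: BUILD then steepest-descent SWAP until no swap lowers the cost.

    Deterministic given the matrix: exact cost ties are broken toward the
    lowest (medoid, candidate) index pair; ``seed`` is recorded for
    provenance only. Labels are renumbered by descending cluster size.
    """
    d = _check_matrix(dist_matrix)
    n = len(d)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of series n={n}")

    medoids = sorted(_build(d, k))
    cost = d[medoids].min(axis=0).sum()
    for _ in range(max_iter):
        sub = d[medoids]  # (k, n)
        order = np.argsort(sub, axis=0)
        nearest = sub[order[0], np.arange(n)]
        second = sub[order[1], np.arange(n)] if k > 1 else np.full(n, np.inf)
        which = order[0]  # index into medoids of each point's nearest medoid

        best_delta = -1e-12
        best_swap = None
        non_medoids = [h for h in range(n) if h not in medoids]
        if not non_medoids:
            break
        d_h = d[non_medoids]  # (n-k, n)
        for mi in range(k):
            mine = which == mi
            # removing medoid mi: its points fall back to their second choice
            base = np.where(mine, second, nearest)
            delta = np.minimum(d_h, base[None, :]).sum(axis=1) - cost
            j = int(np.argmin(delta))
            if delta[j] < best_delta:
                best_delta = float(delta[j])
                best_swap = (mi, non_medoids[j])
        if best_swap is None:
            break
        mi, h = best_swap
        medoids[mi] = h
        cost += best_delta
        medoids = sorted(medoids)
        cost = d[medoids].min(axis=0).sum()

    med = np.array(medoids)
    raw_labels = np.argmin(d[med], axis=0)
    # medoids label themselves (argmin already guarantees it: d[m, m] = 0)
    sizes = np.bincount(raw_labels, minlength=k)
    order = np.lexsort((med, -sizes))  # descending size, ties by medoid index
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[raw_labels]
    med = med[order]
    return ClusteringResult(
        distance_matrix=d,
        labels=labels,
        medoid_indices=med,
        k=k,
        total_cost=float(cost),
        seed=seed,
    )


def silhouette_samples_precomputed(d: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-sample silhouette from a distance matrix.

    a(i): mean distance to own cluster (excluding self); b(i): minimum over
    other clusters of the mean distance. s = (b - a)/max(a, b) with the
    0/0 -> 0 convention; singleton clusters score 0.
    """
    d = _check_matrix(d)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    n = len(d)
    s = np.zeros(n)
    means = np.stack([d[:, labels == c].mean(axis=1) for c in uniq], axis=1)
    sizes = np.array([(labels == c).sum() for c in uniq])
    for i in range(n):
        ci = np.flatnonzero(uniq == labels[i])[0]
        size = sizes[ci]
        if size == 1:
            s[i] = 0.0
            continue
        a = means[i, ci] * size / (size - 1)  # exclude self (d[i,i]=0)
        b = np.min(np.delete(means[i], ci))
        denom = max(a, b)
        s[i] = 0.0 if denom <= 0 else (b - a) / denom
    return s


def cluster_validity(dist_matrix, labels) -> dict:
    """Validity indices: mean silhouette and within/between cost ratio."""
    d = _check_matrix(dist_matrix)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("validity indices need at least 2 clusters")
    sil = silhouette_samples_precomputed(d, labels)
    same = labels[:, None] == labels[None, :]
    off = ~np.eye(len(d), dtype=bool)
    within = d[same & off]
    between = d[~same]
    wb = 0.0
    if within.size and between.size and between.mean() > 0:
        wb = float(within.mean() / between.mean())
    return {
        "mean_silhouette": float(sil.mean()),
        "silhouette_samples": sil,
        "within_between_ratio": wb,
    }


def validity_scan(dist_matrix, k_range=range(2, 9), seed: int | None = None) -> pd.DataFrame:
    """PAM at each k in ``k_range`` with validity indices, for k selection."""
    rows = []
    for k in k_range:
        res = pam_cluster(dist_matrix, k=k, seed=seed)
        v = cluster_validity(dist_matrix, res.labels)
        rows.append(
            {
                "k": k,
                "total_cost": res.total_cost,
                "mean_silhouette": v["mean_silhouette"],
                "within_between_ratio": v["within_between_ratio"],
            }
        )
    return pd.DataFrame(rows)


def cluster_counts(result: ClusteringResult, grouping) -> pd.DataFrame:
    """Contingency of cluster x group, plus each group's modal cluster.

    ``grouping`` is a sequence aligned with the clustered series (e.g. the
    arena shape of each approach path). Returns a tidy frame with one row
    per group: counts per cluster and the modal cluster.
    """
    labels = np.asarray(result.labels)
    groups = np.asarray(grouping)
    if len(labels) != len(groups):
        raise ValueError("labels and grouping must be aligned")
    if len(labels) == 0:
        return pd.DataFrame()
    df = pd.DataFrame({"cluster": labels, "group": groups})
    table = df.value_counts(["group", "cluster"]).unstack(fill_value=0)
    table = table.reindex(columns=range(result.k), fill_value=0)
    table["modal_cluster"] = table[list(range(result.k))].idxmax(axis=1)
    return table
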
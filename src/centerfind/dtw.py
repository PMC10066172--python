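"""Dynamic time warping for 1-D series.

Classic dynamic-programming DTW with absolute-difference local cost and a
choice of step pattern:

* ``symmetric1`` — ``D[i,j] = c(i,j) + min(D[i-1,j], D[i,j-1], D[i-1,j-1])``
* ``symmetric2`` — the diagonal step is weighted twice:
  ``D[i,j] = min(D[i-1,j] + c, D[i,j-1] + c, D[i-1,j-1] + 2c)``

Both are symmetric in their arguments. An optional Sakoe-Chiba band
restricts |i - j|; ``normalize="path_length"`` divides by len(a) + len(b)
(the natural normalizer for symmetric2). Series are compared at native
length — DTW exists precisely to absorb speed differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["DTWConfig", "dtw_distance", "dtw_matrix"]

_INF = np.inf


@dataclass(frozen=True)
class DTWConfig:
    step_pattern: str = "symmetric2"
    window: int | None = None  # Sakoe-Chiba half-band width in frames
    normalize: str = "none"  # or "path_length"

    def __post_init__(self) -> None:
        if self.step_pattern not in ("symmetric1", "symmetric2"):
            raise ValueError("step_pattern must be symmetric1 or symmetric2")
        if self.normalize not in ("none", "path_length"):
            raise ValueError("normalize must be none or path_length")
        if self.window is not None and self.window < 0:
            raise ValueError("window must be non-negative")


@njit(cache=False)
def _dtw_kernel(a, b, sym2, window):  # pragma: no cover - exercised via wrapper
    n, m = len(a), len(b)
    prev = np.full(m + 1, _INF)
    cur = np.full(m + 1, _INF)
    prev[0] = 0.0
    for i in range(1, n + 1):
        cur[:] = _INF
        jlo, jhi = 1, m
        if window >= 0:
            jlo = max(1, i - window)
            jhi = min(m, i + window)
        for j in range(jlo, jhi + 1):
            c = abs(a[i - 1] - b[j - 1])
            diag = prev[j - 1] + (2.0 * c if sym2 else c)
            up = prev[j] + c
            left = cur[j - 1] + c
            best = diag
            if up < best:
                best = up
            if left < best:
                best = left
            cur[j] = best
        prev, cur = cur, prev
    return prev[m]


def dtw_distance(a, b, cfg: DTWConfig = DTWConfig()) -> float:
    """DTW distance between two 1-D series under ``cfg``.

    Raises on empty series, non-finite values, or a Sakoe-Chiba band too
    narrow to connect series of different lengths.
    """
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("DTW requires non-empty series")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("DTW requires finite values")
    if cfg.window is not None and cfg.window < abs(len(a) - len(b)):
        raise ValueError(
            f"Sakoe-Chiba window {cfg.window} < length difference "
            f"{abs(len(a) - len(b))}: no feasible warping path"
        )
    w = -1 if cfg.window is None else int(cfg.window)
    d = float(_dtw_kernel(a, b, cfg.step_pattern == "symmetric2", w))
    if cfg.normalize == "path_length":
        d /= len(a) + len(b)
    return d


def dtw_matrix(series_list, cfg: DTWConfig = DTWConfig()) -> np.ndarray:
    """Symmetric pairwise DTW distance matrix (zero diagonal).

    Each unordered pair is computed once.
    """
    series = [np.ascontiguousarray(s, dtype=np.float64) for s in series_list]
    n = len(series)
    if n < 2:
        raise ValueError("need at least 2 series")
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = dtw_distance(series[i], series[j], cfg)
    return out
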
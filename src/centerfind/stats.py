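"""Statistical layer: learning slopes, rank tests, chi-square.

Learning over trials is quantified on transformed scales — the on-spot
time proportion is square-root transformed and the arrival latency is log
transformed (both to normalize their skewed distributions). The slope of
the transformed response against trial number is estimated by a
transparent two-stage procedure: ordinary least squares per animal, then
the arena-level slope is the mean of per-animal slopes with a t-based 95%
CI (and optionally a nonparametric bootstrap over animals). This targets
the same estimand as a random-intercept-and-slope mixed model — the mean
per-trial change — while remaining fully specifiable and simulation-
testable.

Group comparisons use a two-sided Mann-Whitney U test (exact by
enumeration for small untied samples, normal approximation with tie and
continuity corrections otherwise) with Bonferroni adjustment across the
comparison family. The looming-response control is a 2x2 chi-square.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "LearningSlope",
    "TestResult",
    "transform_response",
    "estimate_learning_slope",
    "mann_whitney_u",
    "bonferroni",
    "chi_square_2x2",
]

LOG_LATENCY_OFFSET_S = 1.0
RESPONSES = ("prop_on_spot_sqrt", "latency_log")


@dataclass(frozen=True)
class LearningSlope:
    """Per-trial change of a transformed response in one arena."""

    shape: str
    response: str
    slope: float
    se: float
    ci95: tuple[float, float]
    n_animals: int
    per_animal_slopes: np.ndarray
    bootstrap_ci95: tuple[float, float] | None = None


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    p_adjusted: float | None = None


def transform_response(values, kind: str, log_offset: float = LOG_LATENCY_OFFSET_S):
    """Element-wise sqrt (proportions) or ln(v + offset) (latencies)."""
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValueError("responses must be non-negative")
    if kind in ("sqrt", "prop_on_spot_sqrt"):
        return np.sqrt(v)
    if kind in ("log", "latency_log"):
        return np.log(v + log_offset)
    raise ValueError(f"unknown transform {kind!r}")


def estimate_learning_slope(
    metrics: pd.DataFrame,
    shape: str,
    response: str,
    *,
    log_offset: float = LOG_LATENCY_OFFSET_S,
    n_bootstrap: int = 0,
    seed: int | None = None,
    min_trials: int = 3,
) -> LearningSlope:
    """Two-stage learning-slope estimate for one arena shape.

    ``metrics`` is the tidy per-trial table (columns ``animal_id``,
    ``trial_index``, ``shape``, ``prop_on_spot``, ``latency_s``). Stage 1
    fits OLS of the transformed response on trial number per animal; stage
    2 averages the per-animal slopes (se = sd/sqrt(n), CI via the t
    quantile). ``n_bootstrap`` > 0 adds a percentile bootstrap CI over
    animals. Animals with fewer than ``min_trials`` usable trials are
    dropped with a warning; if all are dropped an error is raised.
    """
    if response not in RESPONSES:
        raise ValueError(f"response must be one of {RESPONSES}")
    col = "prop_on_spot" if response == "prop_on_spot_sqrt" else "latency_s"
    sub = metrics[metrics["shape"] == shape]
    if sub.empty:
        raise ValueError(f"no rows for shape {shape!r}")
    slopes = []
    for animal, g in sub.groupby("animal_id"):
        g = g.dropna(subset=[col])
        if len(g) < min_trials:
            import warnings

            warnings.warn(f"animal {animal}: fewer than {min_trials} usable trials, dropped")
            continue
        y = transform_response(g[col].to_numpy(), response, log_offset)
        x = g["trial_index"].to_numpy(float)
        slopes.append(np.polyfit(x, y, 1)[0])
    if not slopes:
        raise ValueError("no animal has enough usable trials")
    s = np.asarray(slopes)
    n = len(s)
    mean = float(s.mean())
    sd = float(s.std(ddof=1)) if n > 1 else 0.0
    se = sd / math.sqrt(n) if n > 1 else 0.0
    tq = sps.t.ppf(0.975, n - 1) if n > 1 else 0.0
    ci = (mean - tq * se, mean + tq * se)
    boot_ci = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        resamples = rng.integers(0, n, size=(n_bootstrap, n))
        boot_means = s[resamples].mean(axis=1)
        boot_ci = tuple(np.percentile(boot_means, [2.5, 97.5]))
    return LearningSlope(
        shape=shape,
        response=response,
        slope=mean,
        se=se,
        ci95=ci,
        n_animals=n,
        per_animal_slopes=s,
        bootstrap_ci95=boot_ci,
    )


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x, with midranks for ties."""
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def mann_whitney_u(x, y, exact_max_n: int = 12) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact p by enumerating all rank assignments when n1 + n2 <= ``exact_max_n``
    and the pooled sample has no ties; otherwise the normal approximation
    with tie correction and a 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)

    if n1 + n2 <= exact_max_n and not has_ties:
        # enumerate which positions of the sorted pool belong to sample x
        ranks = np.arange(1, n1 + n2 + 1)
        us = []
        for comb in combinations(range(n1 + n2), n1):
            r1 = ranks[list(comb)].sum()
            us.append(r1 - n1 * (n1 + 1) / 2.0)
        us = np.asarray(us)
        # two-sided: double the smaller tail (distribution is symmetric)
        p_lo = (us <= u + 1e-12).mean()
        p_hi = (us >= u - 1e-12).mean()
        p = min(1.0, 2.0 * min(p_lo, p_hi))
        return TestResult(statistic=u, p_value=float(p), method="mann-whitney-exact")

    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return TestResult(statistic=u, p_value=1.0, method="mann-whitney-normal")
    z = (abs(u - mu) - 0.5) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * sps.norm.sf(max(z, 0.0)))
    return TestResult(statistic=u, p_value=float(p), method="mann-whitney-normal")


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p); m defaults to the family size."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    m = len(p) if m is None else m
    return np.minimum(1.0, m * p)


def chi_square_2x2(table, continuity_correction: bool = False) -> TestResult:
    """Pearson chi-square for a 2x2 count table.

    Closed form N(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); with the Yates
    correction, |ad - bc| is reduced by N/2 first. p from the upper tail of
    chi-square with 1 df. Raises on any zero margin.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must hold non-negative integer counts")
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    margins = [a + b, c + d, a + c, b + d]
    if any(m == 0 for m in margins):
        raise ValueError("all margins must be positive")
    det = abs(a * d - b * c)
    if continuity_correction:
        det = max(det - n / 2.0, 0.0)
    stat = n * det**2 / np.prod(margins)
    p = float(sps.chi2.sf(stat, df=1))
    method = "chi-square-2x2" + ("-yates" if continuity_correction else "")
    return TestResult(statistic=float(stat), p_value=p, method=method)
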
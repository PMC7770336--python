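"""Statistical layer: two-cluster assignment of leading-site positions,
per-cluster normal fits, logistic membership-vs-HR curves, per-heart
dominance classification, and percent HR-change summaries.

Clustering uses exact 1-D k-means: the globally optimal partition is
found by dynamic programming over the sorted values (optimal 1-D clusters
are contiguous in sorted order), so there is no random initialization and
results are fully deterministic. The cluster with the larger center is
labeled superior (sSAN), the other inferior (iSAN).
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit

from .types import ClusterSummary, DominanceCall

logger = logging.getLogger(__name__)

__all__ = [
    "kmeans_1d",
    "fit_cluster_normals",
    "fit_logistic",
    "build_cluster_summary",
    "classify_dominance",
    "percent_change",
    "summarize_experiment",
]

SUPERIOR = "superior"
INFERIOR = "inferior"


def kmeans_1d(y_values: Sequence[float], k: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Exact 1-D k-means by dynamic programming.

    Returns ``(assignments, centers)`` with centers sorted ascending and
    assignments indexing into them. The partition attains the global
    minimum of the within-cluster sum of squares.
    """
    y = np.asarray(y_values, dtype=float)
    if y.ndim != 1 or len(y) < k:
        raise ValueError(f"need at least k={k} values")
    if len(np.unique(y)) < k:
        raise ValueError("degenerate clustering: fewer distinct values than clusters")
    order = np.argsort(y, kind="stable")
    x = y[order]
    n = len(x)

    # prefix sums for O(1) within-segment SSE
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def sse(i: int, j: int) -> float:
        """Sum of squared deviations of x[i:j] about its mean."""
        m = j - i
        s = s1[j] - s1[i]
        return (s2[j] - s2[i]) - s * s / m

    INF = float("inf")
    cost = np.full((k + 1, n + 1), INF)
    split = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, arg = INF, c - 1
            for i in range(c - 1, j):
                v = cost[c - 1, i] + sse(i, j)
                if v < best:
                    best, arg = v, i
            cost[c, j] = best
            split[c, j] = arg

    boundaries = [n]
    j = n
    for c in range(k, 0, -1):
        j = split[c, j]
        boundaries.append(j)
    boundaries = boundaries[::-1]

    labels_sorted = np.empty(n, dtype=int)
    centers = np.empty(k)
    for c in range(k):
        i, j = boundaries[c], boundaries[c + 1]
        labels_sorted[i:j] = c
        centers[c] = x[i:j].mean()

    assignments = np.empty(n, dtype=int)
    assignments[order] = labels_sorted
    return assignments, centers


def fit_cluster_normals(
    y_values: Sequence[float], assignments: Sequence[int]
) -> dict[int, tuple[float, float]]:
    """Sample mean and sd (n-1 denominator) per cluster label.

    Singleton clusters get sigma = 0 with a warning.
    """
    y = np.asarray(y_values, dtype=float)
    a = np.asarray(assignments)
    out: dict[int, tuple[float, float]] = {}
    for label in np.unique(a):
        vals = y[a == label]
        if len(vals) == 0:
            raise ValueError(f"cluster {label} is empty")
        if len(vals) == 1:
            warnings.warn(f"cluster {label} has a single member; sigma set to 0")
            out[int(label)] = (float(vals[0]), 0.0)
        else:
            out[int(label)] = (float(vals.mean()), float(vals.std(ddof=1)))
    return out


def _separated(hr: np.ndarray, labels: np.ndarray) -> bool:
    """Perfect separation of a 1-D covariate: label intervals do not overlap."""
    h0, h1 = hr[labels == 0], hr[labels == 1]
    return bool(h0.max() < h1.min() or h1.max() < h0.min())


def fit_logistic(
    hr_bpm: Sequence[float],
    labels: Sequence[int],
    ridge_lambda: float = 1e-3,
) -> tuple[float, float, bool]:
    """Logistic fit of P(superior | HR): returns (beta0, beta1, separation_flag).

    Unseparated data get the plain maximum-likelihood fit. Perfectly
    separated data (where unpenalized ML diverges) get a ridge penalty
    ``0.5 * ridge_lambda * beta1_std**2`` on the slope in standardized-HR
    units, which bounds the slope; the fit is then flagged.
    """
    hr = np.asarray(hr_bpm, dtype=float)
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("need both superior (1) and inferior (0) labels")
    if len(hr) != len(y):
        raise ValueError("hr and labels length mismatch")

    sep = _separated(hr, y)
    if not sep:
        model = sm.Logit(y, sm.add_constant(hr))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, maxiter=200)
        if np.all(np.isfinite(res.params)):
            b0, b1 = res.params
            return float(b0), float(b1), False
        sep = True  # quasi-separation: fall through to penalized fit

    m, s = hr.mean(), hr.std()
    if s == 0:
        raise ValueError("HR covariate is constant")
    z = (hr - m) / s

    def nll(beta: np.ndarray) -> float:
        eta = beta[0] + beta[1] * z
        # log(1 + exp(-y_signed * eta)), stable
        ysgn = 2.0 * y - 1.0
        return float(np.logaddexp(0.0, -ysgn * eta).sum() + 0.5 * ridge_lambda * beta[1] ** 2)

    res = minimize(nll, x0=np.zeros(2), method="BFGS")
    b0z, b1z = res.x
    beta1 = b1z / s
    beta0 = b0z - b1z * m / s
    return float(beta0), float(beta1), True


def membership_curve(beta0: float, beta1: float, hr_bpm: np.ndarray) -> np.ndarray:
    """P(superior | HR) of a fitted logistic curve."""
    return expit(beta0 + beta1 * np.asarray(hr_bpm, dtype=float))


def build_cluster_summary(
    y_au: Sequence[float], hr_bpm: Sequence[float], ridge_lambda: float = 1e-3
) -> ClusterSummary:
    """Cluster pooled sites into superior/inferior and fit the statistics."""
    y = np.asarray(y_au, dtype=float)
    assignments, centers = kmeans_1d(y, k=2)
    sup_idx = int(np.argmax(centers))
    labels = np.where(assignments == sup_idx, SUPERIOR, INFERIOR)
    normals = fit_cluster_normals(y, assignments)
    inf_idx = 1 - sup_idx
    beta0, beta1, sep = fit_logistic(
        hr_bpm, (assignments == sup_idx).astype(int), ridge_lambda=ridge_lambda
    )
    return ClusterSummary(
        assignments=labels,
        mu_sup=normals[sup_idx][0],
        sigma_sup=normals[sup_idx][1],
        mu_inf=normals[inf_idx][0],
        sigma_inf=normals[inf_idx][1],
        beta0=beta0,
        beta1=beta1,
        separation_flag=sep,
    )


def classify_dominance(
    records: pd.DataFrame,
    threshold: float = 0.95,
    heart_col: str = "heart_id",
    cluster_col: str = "cluster",
) -> list[DominanceCall]:
    """Per-heart dominance calls from cluster-labeled beats.

    ``fraction_superior`` is the share of the heart's beats (pooled across
    conditions) assigned to the superior cluster; >= threshold is
    sSAN_only, <= 1 - threshold is iSAN_only, anything between is dual.
    """
    if records.empty:
        raise ValueError("no records to classify")
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0.5, 1]")
    calls = []
    for heart_id, grp in records.groupby(heart_col, sort=True):
        frac = float((grp[cluster_col] == SUPERIOR).mean())
        if frac >= threshold:
            call = "sSAN_only"
        elif frac <= 1.0 - threshold:
            call = "iSAN_only"
        else:
            call = "dual"
        calls.append(DominanceCall(heart_id=str(heart_id), call=call, fraction_superior=frac))
    return calls


def percent_change(baseline_bpm: float, treated_bpm: float) -> float:
    """Signed percent HR change from baseline, to one decimal."""
    if baseline_bpm <= 0:
        raise ValueError("baseline HR must be positive")
    return round(100.0 * (treated_bpm - baseline_bpm) / baseline_bpm, 1)


def summarize_experiment(
    records: pd.DataFrame,
    cluster_summary: ClusterSummary,
    threshold: float = 0.95,
) -> dict:
    """Condition-level HR summaries, cluster parameters, dominance calls.

    ``records`` is the beats table (one row per beat) with at least
    ``hr_bpm``, ``condition`` and ``y_au`` columns; a ``heart_id`` column
    is added (single heart) when absent.
    """
    if records.empty:
        raise ValueError("no records to summarize")
    df = records.copy()
    if "heart_id" not in df.columns:
        df["heart_id"] = "H1"
    df["cluster"] = cluster_summary.assignments

    by_cond = (
        df.groupby("condition")["hr_bpm"]
        .agg(n="size", hr_mean="mean", hr_sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    dominance = classify_dominance(df, threshold=threshold)
    dominance_df = pd.DataFrame(
        [
            {"heart_id": d.heart_id, "call": d.call, "fraction_superior": d.fraction_superior}
            for d in dominance
        ]
    )
    return {
        "per_condition": by_cond,
        "clusters": cluster_summary.to_dict(),
        "dominance": dominance_df,
    }
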
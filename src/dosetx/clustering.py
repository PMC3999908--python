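"""K-means clustering of fold-change profiles under Pearson-correlation
distance, with Figure-of-Merit (FOM) model selection.

Distance between profiles is 1 - Pearson r (range [0, 2]); centroids are
arithmetic means of member profiles, the correlation distance being used
for assignment only — the behaviour of the common "k-means with Pearson
metric" tools. Empty clusters are re-seeded with the point farthest from
its current centroid, which keeps runs deterministic for a given seed.

The FOM is the leave-one-condition-out estimate of predictive error: for
each held-out condition the genes are clustered on the remaining
conditions and scored by the root-mean-square deviation of the held-out
values from their cluster means, averaged over conditions and adjusted by
the sqrt(n / (n - k)) small-cluster correction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def correlation_distance(a, b, on_constant: str = "error") -> float:
    """1 - Pearson correlation between two equal-length profiles.

    A constant profile has no defined correlation; ``on_constant`` selects
    between raising (default) and the neutral fallback distance 1.0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("profiles must be 1-D, equal length >= 2")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        if on_constant == "fallback":
            return 1.0
        raise ValueError("correlation undefined for a constant profile")
    r = float(np.dot(a - a.mean(), b - b.mean()) / (len(a) * sa * sb))
    return 1.0 - r


def _distance_matrix(x: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Correlation distances between rows of x and rows of centroids."""
    xc = x - x.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(xc, axis=1)
    cc = centroids - centroids.mean(axis=1, keepdims=True)
    cn = np.linalg.norm(cc, axis=1)
    xn = np.where(xn == 0, np.nan, xn)
    cn = np.where(cn == 0, np.nan, cn)
    r = (xc / xn[:, None]) @ (cc / cn[:, None]).T
    d = 1.0 - r
    return np.where(np.isnan(d), 1.0, d)  # constant profile -> neutral distance


@dataclass
class ClusterResult:
    k: int
    assignments: pd.Series      # gene -> cluster index (0-based)
    centroids: pd.DataFrame     # cluster x condition mean profiles
    inertia: float              # total correlation distance to assigned centroid
    seed: int
    restarts: int


def _lloyd(x: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100):
    n = x.shape[0]
    centroids = x[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    for _ in range(max_iter):
        d = _distance_matrix(x, centroids)
        new_labels = d.argmin(axis=1)
        # repair empty clusters with the farthest point from its centroid
        for c in range(k):
            if not np.any(new_labels == c):
                far = d[np.arange(n), new_labels].argmax()
                new_labels[far] = c
                d[far, :] = 0  # pin: cannot be stolen again this round
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            centroids[c] = x[labels == c].mean(axis=0)
    inertia = float(_distance_matrix(x, centroids)[np.arange(n), labels].sum())
    return labels, centroids, inertia


def kmeans_profiles(
    fc: pd.DataFrame, k: int, seed: int = 0, restarts: int = 20
) -> ClusterResult:
    """Best-of-``restarts`` k-means on the rows of a fold-change table.

    Rows are put in canonical (index-sorted) order before seeding so the
    result does not depend on input row order.
    """
    if not 1 <= k <= len(fc):
        raise ValueError(f"k={k} out of range for {len(fc)} genes")
    fc = fc.sort_index()
    x = fc.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, restarts)):
        labels, centroids, inertia = _lloyd(x, k, rng)
        if best is None or inertia < best[2]:
            best = (labels, centroids, inertia)
    labels, centroids, inertia = best
    return ClusterResult(
        k=k,
        assignments=pd.Series(labels, index=fc.index, name="cluster"),
        centroids=pd.DataFrame(centroids, columns=fc.columns),
        inertia=inertia,
        seed=seed,
        restarts=restarts,
    )


def figure_of_merit(
    fc: pd.DataFrame, k_range, seed: int = 0, restarts: int = 5
) -> pd.Series:
    """Adjusted leave-one-condition-out FOM for each candidate k."""
    n, m = fc.shape
    if m < 2:
        raise ValueError("FOM needs >= 2 conditions")
    out = {}
    for k in k_range:
        if k > n:
            raise ValueError(f"k={k} exceeds {n} genes")
        total = 0.0
        for j, cond in enumerate(fc.columns):
            rest = fc.drop(columns=cond)
            res = kmeans_profiles(rest, k, seed=seed + j, restarts=restarts)
            held = fc[cond].reindex(res.assignments.index).to_numpy()
            labels = res.assignments.to_numpy()
            sq = 0.0
            for c in range(k):
                member = held[labels == c]
                sq += ((member - member.mean()) ** 2).sum()
            total += np.sqrt(sq / n)
        raw = total / m
        adjust = np.sqrt((n - k) / n) if k < n else 0.0
        out[k] = raw / adjust if adjust > 0 else 0.0
    return pd.Series(out, name="FOM")
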
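"""Stage-one statistics: per-gene linear contrasts with empirical-Bayes
variance moderation, Benjamini-Hochberg FDR control, and DEG selection.

The model is a per-gene group-means fit over the 12 (or, under the pooled
control convention, 7) condition groups. The contrast of interest is
"drug at potency d minus control", where the control mean is either the
grand mean over all control arrays (pooled convention) or the same-potency
control group (matched convention). Residual variances are shrunk toward a
prior variance s0^2 with prior degrees of freedom d0, both estimated by
the closed-form method of moments on log residual variances; the moderated
t then has d0 + df degrees of freedom.

A gene is called differentially expressed when |log2 fold change| > 0.5
and the BH-adjusted p (computed over the full transcript count) is < 0.05,
both strict.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .datamodel import ExpressionMatrix

#: cap used when the moment estimate of the prior df diverges
PRIOR_DF_CAP = 1e6


def _group_columns(
    expr: ExpressionMatrix, convention: str
) -> dict[tuple[str, int | None], list[str]]:
    """Map condition group -> sample columns. Pooled: one control group."""
    groups: dict[tuple[str, int | None], list[str]] = {}
    for s in expr.samples:
        if convention == "pooled" and s.agent == "control":
            key = ("control", None)
        else:
            key = (s.agent, s.potency)
        groups.setdefault(key, []).append(s.sample_id)
    return groups


def fit_contrast(
    expr: ExpressionMatrix,
    potency: int,
    convention: str = "pooled",
) -> pd.DataFrame:
    """Per-gene OLS group-means fit and drug-vs-control contrast.

    Returns a frame indexed by gene with columns ``coef`` (log2 fold
    change), ``residual_sd``, ``residual_df`` and ``stderr_scale`` (the
    unit-variance multiplier ``sqrt(1/n_drug + 1/n_control)``).
    """
    if convention not in ("pooled", "matched"):
        raise ValueError(f"unknown control convention {convention!r}")
    groups = _group_columns(expr, convention)
    drug_key = ("drug", potency)
    ctrl_key = ("control", None) if convention == "pooled" else ("control", potency)
    for key in (drug_key, ctrl_key):
        if key not in groups or not groups[key]:
            raise ValueError(f"contrast group {key} is empty")
    x = expr.data
    n_total = x.shape[1]
    n_groups = len(groups)
    rss = np.zeros(x.shape[0])
    means: dict[tuple[str, int | None], np.ndarray] = {}
    for key, cols in groups.items():
        sub = x[cols].to_numpy()
        mu = sub.mean(axis=1)
        means[key] = mu
        rss += ((sub - mu[:, None]) ** 2).sum(axis=1)
    residual_df = n_total - n_groups
    if residual_df < 1:
        raise ValueError("design leaves no residual degrees of freedom")
    s2 = rss / residual_df
    coef = means[drug_key] - means[ctrl_key]
    scale = np.sqrt(1.0 / len(groups[drug_key]) + 1.0 / len(groups[ctrl_key]))
    return pd.DataFrame(
        {
            "coef": coef,
            "residual_sd": np.sqrt(s2),
            "residual_df": residual_df,
            "stderr_scale": scale,
        },
        index=x.index,
    )


@dataclass
class ModeratedStats:
    """Moderated statistics for one contrast across all genes."""

    table: pd.DataFrame  # coef, residual_sd, residual_df, stderr_scale,
    #                      posterior_sd, t, p_value, adj_p
    prior_df: float
    prior_var: float


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) / y < 1e-8:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) to scaled-chi-square variances.

    Works on the log variances with the standard digamma/trigamma bias
    corrections; a non-positive excess-variance moment means no evidence of
    variance heterogeneity and yields an (effectively) infinite prior df,
    returned as the cap.
    """
    ok = s2 > 0
    if not np.any(ok):
        raise ValueError(
            "all residual variances are zero; moderation is undefined "
            "(zero-noise input?)"
        )
    s2, df = s2[ok], df[ok]
    n = len(s2)
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    if n < 2:
        return PRIOR_DF_CAP, float(s2.mean())
    evar = float(np.mean((e - emean) ** 2 * n / (n - 1) - special.polygamma(1, df / 2.0)))
    if evar <= 0:
        # no evidence of variance heterogeneity: one shared variance
        return PRIOR_DF_CAP, float(s2.mean())
    d0 = 2.0 * _trigamma_inverse(evar)
    if not np.isfinite(d0) or d0 > PRIOR_DF_CAP:
        return PRIOR_DF_CAP, float(s2.mean())
    s0sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0sq


def empirical_bayes_moderate(
    fits: pd.DataFrame,
    bh_m: int | None = None,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> ModeratedStats:
    """Shrink per-gene variances toward the estimated prior and test.

    ``prior_df``/``prior_var`` may be forced (``prior_df = 0`` reproduces the
    ordinary t). ``bh_m`` sets the BH adjustment denominator (defaults to
    the number of genes supplied; pass the full transcriptome size when
    testing a subset).
    """
    if len(fits) < 2 and prior_df is None:
        raise ValueError("need >= 2 genes to estimate the variance prior")
    s2 = fits["residual_sd"].to_numpy() ** 2
    df = fits["residual_df"].to_numpy(dtype=float)
    if prior_df is None or prior_var is None:
        d0_est, s0_est = estimate_prior(s2, df)
        d0 = d0_est if prior_df is None else prior_df
        s0sq = s0_est if prior_var is None else prior_var
    else:
        d0, s0sq = prior_df, prior_var
    if d0 > 0:
        post_var = (d0 * s0sq + df * s2) / (d0 + df)
        # zero-variance genes fall back on the prior entirely
        post_var = np.where(s2 > 0, post_var, s0sq)
    else:
        post_var = s2.copy()
    if np.any(post_var <= 0):
        raise ValueError("zero posterior variance; cannot form moderated t")
    se = np.sqrt(post_var) * fits["stderr_scale"].to_numpy()
    t = fits["coef"].to_numpy() / se
    total_df = np.minimum(d0 + df, PRIOR_DF_CAP)
    p = 2.0 * stats.t.sf(np.abs(t), total_df)
    adj = bh_adjust(p, m=bh_m)
    table = fits.copy()
    table["posterior_sd"] = np.sqrt(post_var)
    table["t"] = t
    table["p_value"] = p
    table["adj_p"] = adj
    return ModeratedStats(table=table, prior_df=float(d0), prior_var=float(s0sq))


def bh_adjust(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``m`` is the multiplicity denominator; it may exceed ``len(p_values)``
    when only a subset of the tested family is supplied (the adjustment is
    then performed as if the remaining p-values were all 1).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if m is None:
        m = n
    if m < n:
        raise ValueError(f"m={m} smaller than number of p-values ({n})")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def select_degs(
    stats_table: pd.DataFrame,
    fc_threshold: float = 0.5,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Strict-threshold DEG call: |coef| > fc_threshold and adj_p < p_threshold.

    Returns the selected rows with a ``direction`` column, sorted by fold
    change ascending (strongest down-regulation first).
    """
    if fc_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    sel = stats_table[
        (stats_table["coef"].abs() > fc_threshold)
        & (stats_table["adj_p"] < p_threshold)
    ].copy()
    sel["direction"] = np.where(sel["coef"] < 0, "down", "up")
    return sel.sort_values("coef")


@dataclass
class HomogeneityReport:
    passed: bool
    prior_df: float
    prior_var: float
    offending: pd.DataFrame  # gene x (pair, adj_p) rows with adj_p < alpha
    n_pairs: int


def control_homogeneity(
    expr: ExpressionMatrix,
    alpha: float = 0.05,
    bh_m: int | None = None,
) -> HomogeneityReport:
    """Pairwise control-vs-control moderated contrasts.

    Fits the group-means model on control arrays only, moderates once, then
    tests every pair of control potencies. Passing (no gene with adjusted
    p < ``alpha`` in any pair) licenses pooling the controls into a single
    reference group.
    """
    ctrl_samples = [s for s in expr.samples if s.agent == "control"]
    potencies = sorted({s.potency for s in ctrl_samples})
    if len(potencies) < 2:
        raise ValueError("need >= 2 control groups")
    x = expr.data[[s.sample_id for s in ctrl_samples]]
    cols_by_pot = {
        p: [s.sample_id for s in ctrl_samples if s.potency == p] for p in potencies
    }
    rss = np.zeros(x.shape[0])
    means = {}
    for p, cols in cols_by_pot.items():
        sub = x[cols].to_numpy()
        mu = sub.mean(axis=1)
        means[p] = mu
        rss += ((sub - mu[:, None]) ** 2).sum(axis=1)
    residual_df = x.shape[1] - len(potencies)
    s2 = rss / residual_df
    d0, s0sq = estimate_prior(s2, np.full_like(s2, residual_df))
    post_var = np.where(s2 > 0, (d0 * s0sq + residual_df * s2) / (d0 + residual_df), s0sq)
    if bh_m is None:
        bh_m = x.shape[0]
    rows = []
    for i, pi in enumerate(potencies):
        for pj in potencies[i + 1 :]:
            scale = np.sqrt(1.0 / len(cols_by_pot[pi]) + 1.0 / len(cols_by_pot[pj]))
            t = (means[pi] - means[pj]) / (np.sqrt(post_var) * scale)
            p = 2.0 * stats.t.sf(np.abs(t), min(d0 + residual_df, PRIOR_DF_CAP))
            adj = bh_adjust(p, m=bh_m)
            hit = adj < alpha
            for g, a in zip(x.index[hit], adj[hit]):
                rows.append((f"{pi}c_vs_{pj}c", g, float(a)))
    offending = pd.DataFrame(rows, columns=["pair", "gene_id", "adj_p"])
    n_pairs = len(potencies) * (len(potencies) - 1) // 2
    return HomogeneityReport(
        passed=offending.empty,
        prior_df=float(d0),
        prior_var=float(s0sq),
        offending=offending,
        n_pairs=n_pairs,
    )
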
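"""Probe-level preprocessing: background floor, quantile normalization,
median-polish summarization, and array QC.

The chain mirrors RMA: (optional) background adjustment, quantile
normalization across arrays at probe level, then a per-gene additive fit
``log2(value) = overall + probe_effect + array_effect`` by Tukey median
polish, reporting ``overall + array_effect`` as the gene-level log2 call.
The full norm+exponential convolution background model is intentionally
replaced by a simple per-array percentile floor (off by default).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, ProbeMatrix


def background_floor(
    probe: ProbeMatrix, percentile: float = 0.0, floor: float = 1.0
) -> ProbeMatrix:
    """Subtract a per-array percentile from every value, clamped at ``floor``.

    ``percentile = 0`` subtracts each array's minimum-or-less, i.e. is the
    identity apart from the clamp; values never drop below ``floor`` so the
    subsequent log2 stays finite.
    """
    if not 0 <= percentile < 100:
        raise ValueError(f"percentile must be in [0, 100), got {percentile}")
    if percentile == 0.0:
        return probe
    cut = np.percentile(probe.values, percentile, axis=0)
    adjusted = np.maximum(probe.values - cut[None, :], floor)
    return ProbeMatrix(probe.gene_ids, probe.probes_per_gene, adjusted, probe.samples)


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Force every column onto the common distribution of column-sorted row means.

    Within-column rank order is preserved; ties receive the mean of the
    target values their tied ranks span (deterministic tie handling).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] == 0 or x.shape[1] == 0:
        raise ValueError("quantile_normalize expects a non-empty 2-D matrix")
    target = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    n = x.shape[0]
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n)
        assigned[order] = target
        # average assigned targets over groups of tied input values
        sorted_vals = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
        if len(boundaries) < n - 1:  # ties exist
            groups = np.concatenate(([0], boundaries, [n]))
            tgt = assigned[order]
            for a, b in zip(groups[:-1], groups[1:]):
                if b - a > 1:
                    tgt[a:b] = tgt[a:b].mean()
            assigned[order] = tgt
        out[:, j] = assigned
    return out


def quantile_normalize_probe(probe: ProbeMatrix) -> ProbeMatrix:
    return ProbeMatrix(
        probe.gene_ids,
        probe.probes_per_gene,
        quantile_normalize(probe.values),
        probe.samples,
    )


def median_polish(
    x: np.ndarray, tol: float = 1e-6, max_iter: int = 10
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Tukey median polish on a stack of tables.

    ``x`` has shape (n_tables, n_rows, n_cols); returns (overall, row_eff,
    col_eff, residuals) with shapes (t,), (t, r), (t, c), (t, r, c).
    Iterates row/column median sweeps until the largest sweep is below
    ``tol`` or ``max_iter`` is reached.
    """
    r = np.array(x, dtype=float)
    t, n_rows, n_cols = r.shape
    overall = np.zeros(t)
    row = np.zeros((t, n_rows))
    col = np.zeros((t, n_cols))
    for _ in range(max_iter):
        rowmed = np.median(r, axis=2)
        r -= rowmed[:, :, None]
        row += rowmed
        colmed_of_row = np.median(row, axis=1)
        row -= colmed_of_row[:, None]
        overall += colmed_of_row

        colmed = np.median(r, axis=1)
        r -= colmed[:, None, :]
        col += colmed
        rowmed_of_col = np.median(col, axis=1)
        col -= rowmed_of_col[:, None]
        overall += rowmed_of_col

        delta = max(np.abs(rowmed).max(initial=0), np.abs(colmed).max(initial=0))
        if delta < tol:
            break
    return overall, row, col, r


def summarize_median_polish(
    probe: ProbeMatrix, tol: float = 1e-6, max_iter: int = 10
) -> ExpressionMatrix:
    """Collapse probes to one log2 call per gene and array (RMA-style).

    Linear-scale inputs are logged exactly once here; the gene/array summary
    is ``overall + array_effect`` of the per-gene median polish.
    """
    vals = probe.as_3d()
    if np.any(vals <= 0):
        raise ValueError("probe values must be positive for log2 summarization")
    overall, _, col, _ = median_polish(np.log2(vals), tol=tol, max_iter=max_iter)
    summary = overall[:, None] + col
    df = pd.DataFrame(
        summary,
        index=pd.Index(probe.gene_ids, name="gene_id"),
        columns=[s.sample_id for s in probe.samples],
    )
    return ExpressionMatrix(df, probe.samples)


@dataclass
class QCReport:
    correlations: pd.DataFrame      # arrays x arrays Pearson r
    mean_correlation: float         # mean of off-diagonal pairs
    per_array_mean: pd.Series
    cv_of_array_means: float
    flagged_arrays: list[str]
    threshold: float

    @property
    def passed(self) -> bool:
        return not self.flagged_arrays


def qc_metrics(expr: ExpressionMatrix, threshold: float = 0.97) -> QCReport:
    """Inter-array Pearson correlations and mean-signal dispersion.

    Arrays whose mean correlation with the other arrays falls below
    ``threshold`` are flagged.
    """
    if len(expr.samples) < 2:
        raise ValueError("QC needs at least 2 arrays")
    corr = expr.data.corr(method="pearson")
    k = corr.shape[0]
    off = corr.to_numpy()[~np.eye(k, dtype=bool)]
    per_array_mean_corr = (corr.sum(axis=0) - 1.0) / (k - 1)
    means = expr.data.mean(axis=0)
    cv = float(means.std(ddof=0) / means.mean()) if means.mean() != 0 else np.inf
    flagged = per_array_mean_corr.index[per_array_mean_corr < threshold].tolist()
    return QCReport(
        correlations=corr,
        mean_correlation=float(off.mean()),
        per_array_mean=means,
        cv_of_array_means=cv,
        flagged_arrays=flagged,
        threshold=threshold,
    )


def preprocess_probe_data(
    probe: ProbeMatrix,
    background_percentile: float = 0.0,
    quantile: bool = True,
) -> ExpressionMatrix:
    """Convenience chain: background floor -> quantile norm -> median polish."""
    step = background_floor(probe, background_percentile)
    if quantile:
        step = quantile_normalize_probe(step)
    return summarize_median_polish(step)
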
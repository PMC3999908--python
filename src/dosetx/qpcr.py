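"""RT-qPCR relative quantification: ddCq fold changes and the replicate
mean +/- SEM aggregation used in the published validation table.

The quantification cycle Cq is inversely proportional to log2 template
abundance, so after normalizing each sample's target Cq by the mean of the
housekeeping genes (dCq) and differencing treated minus control (ddCq),
the relative expression is 2**(-ddCq) and the log2 fold change is -ddCq.

The SEM convention is the population-SD numerator (divisor n), i.e.
``sem = sqrt(sum((x - mean)^2) / n) / sqrt(n)``: this is the only
convention that reproduces the published mean/SEM cells from the printed
replicate values (reverse-engineered; the sample-SD convention does not).
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("sample_id", "gene_id", "tech_rep", "cq")


def _mean_cq(cq: pd.DataFrame, sample: str, gene: str) -> float:
    sub = cq[(cq["sample_id"] == sample) & (cq["gene_id"] == gene)]
    if sub.empty:
        raise KeyError(f"no Cq values for gene {gene!r} in sample {sample!r}")
    return float(sub["cq"].mean())


def delta_cq(
    cq: pd.DataFrame, sample: str, target: str, housekeeping: Sequence[str]
) -> float:
    """Housekeeping-normalized Cq: target mean Cq minus mean over housekeeping genes."""
    if not len(housekeeping):
        raise ValueError("housekeeping gene list must not be empty")
    hk = np.mean([_mean_cq(cq, sample, h) for h in housekeeping])
    return _mean_cq(cq, sample, target) - float(hk)


def delta_delta_cq(
    cq: pd.DataFrame,
    target: str,
    housekeeping: Sequence[str],
    treated: str,
    control: str,
) -> float:
    """log2 fold change of ``target`` in ``treated`` vs ``control`` by ddCq.

    Technical replicates are averaged per sample x gene first; returns
    ``-(dCq_treated - dCq_control)`` = log2(2**-ddCq).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in cq.columns]
    if missing:
        raise ValueError(f"Cq table lacks column(s): {missing}")
    ddcq = delta_cq(cq, treated, target, housekeeping) - delta_cq(
        cq, control, target, housekeeping
    )
    return -ddcq


def aggregate_mean_sem(values: Sequence[float]) -> tuple[float, float]:
    """Replicate mean and SEM with the population-SD numerator.

    NaNs (non-detects) are dropped; an all-missing input returns
    (nan, nan), mirroring the published empty mean cells.
    """
    x = np.asarray(list(values), dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n == 0:
        return float("nan"), float("nan")
    mean = float(x.mean())
    sem = float(np.sqrt(((x - mean) ** 2).sum() / n) / np.sqrt(n))
    return mean, sem


def summarize_replicates(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Add ``mean`` and ``sem`` columns to a gene x replicate log2-FC frame."""
    out = per_replicate.copy()
    agg = out.apply(lambda row: aggregate_mean_sem(row.to_numpy()), axis=1)
    out["mean"] = [a[0] for a in agg]
    out["sem"] = [a[1] for a in agg]
    return out
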
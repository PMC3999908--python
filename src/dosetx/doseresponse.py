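"""Stage-two statistics: directional consistency of a gene set across a
dilution series.

Given the gene set selected at the lowest dilution, each gene's log2 fold
change is recomputed at every potency (against pooled or matched controls),
classified as down / null / up with an inclusive +/-0.05 null band, and the
down-vs-up counts per potency are tested exactly. Three exact-test
constructions are provided because the published 2x2 construction is
ambiguous: a one-sided binomial sign test, Fisher against a balanced split,
and Fisher against a reference (random) gene set's counts. A seeded random
gene set disjoint from the DEGs serves as the negative control, and the
Friedman rank test checks the global null that all condition groups share
one distribution.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ExpressionMatrix

DEFAULT_NULL_BAND = 0.05

LABELS = ("down", "null", "up")


def fold_change_table(
    expr: ExpressionMatrix, convention: str = "pooled"
) -> pd.DataFrame:
    """Gene x potency log2 fold changes (drug mean minus control mean).

    ``pooled`` subtracts the grand mean over all control arrays; ``matched``
    subtracts the same-potency control group mean. The convention is
    recorded in ``DataFrame.attrs["convention"]``.
    """
    if convention not in ("pooled", "matched"):
        raise ValueError(f"unknown control convention {convention!r}")
    potencies = sorted({s.potency for s in expr.samples})
    out = {}
    pooled_cols = expr.sample_ids(agent="control")
    if not pooled_cols:
        raise ValueError("design has no control samples")
    pooled_mean = expr.data[pooled_cols].mean(axis=1)
    for p in potencies:
        drug_cols = expr.sample_ids(agent="drug", potency=p)
        if not drug_cols:
            raise ValueError(f"no drug samples at potency {p}c")
        drug_mean = expr.data[drug_cols].mean(axis=1)
        if convention == "matched":
            ctrl_cols = expr.sample_ids(agent="control", potency=p)
            if not ctrl_cols:
                raise ValueError(f"no control samples at potency {p}c")
            ctrl_mean = expr.data[ctrl_cols].mean(axis=1)
        else:
            ctrl_mean = pooled_mean
        out[p] = drug_mean - ctrl_mean
    fc = pd.DataFrame(out)
    fc.attrs["convention"] = convention
    return fc


def classify_signs(fc: pd.DataFrame, null_band: float = DEFAULT_NULL_BAND) -> pd.DataFrame:
    """Label each fold change: down (< -band), up (> +band), else null.

    The band is inclusive: a fold change of exactly +/-``null_band``
    classifies as null.
    """
    if null_band < 0:
        raise ValueError("null_band must be >= 0")
    vals = fc.to_numpy()
    lab = np.where(vals < -null_band, "down", np.where(vals > null_band, "up", "null"))
    out = pd.DataFrame(lab, index=fc.index, columns=fc.columns)
    out.attrs["null_band"] = null_band
    return out


def count_signs(cls: pd.DataFrame, gene_set: Sequence[str]) -> pd.DataFrame:
    """Down/null/up counts (and integer percentages) per potency for a gene set."""
    unknown = [g for g in gene_set if g not in cls.index]
    if unknown:
        raise KeyError(f"gene id(s) not classified: {unknown[:5]}")
    sub = cls.loc[list(gene_set)]
    rows = []
    n = len(gene_set)
    for p in cls.columns:
        col = sub[p]
        n_down = int((col == "down").sum())
        n_up = int((col == "up").sum())
        n_null = n - n_down - n_up
        rows.append(
            {
                "potency": p,
                "n_down": n_down,
                "n_null": n_null,
                "n_up": n_up,
                "set_size": n,
                "pct_down": round(100 * n_down / n) if n else 0,
                "pct_up": round(100 * n_up / n) if n else 0,
            }
        )
    return pd.DataFrame(rows).set_index("potency")


@dataclass
class ExactTestResult:
    variant: str
    p_value: float
    table: tuple  # counts the test was computed from


def exact_direction_test(
    n_down: int,
    n_up: int,
    variant: str = "binomial_sign",
    reference: tuple[int, int] | None = None,
) -> ExactTestResult:
    """Exact test of down-vs-up imbalance at one potency.

    Variants
    --------
    ``binomial_sign``
        One-sided exact binomial: P(X >= n_down) with X ~ Bin(n_down+n_up, 1/2).
    ``fisher_vs_balanced``
        Two-sided Fisher of (n_down, n_up) against an equal split of the same
        non-null total.
    ``fisher_vs_reference``
        Two-sided Fisher of (n_down, n_up) against the reference set's
        (n_down, n_up).

    Two-sided Fisher p sums tables at most as probable as the observed one
    (the standard convention).
    """
    if n_down < 0 or n_up < 0:
        raise ValueError("counts must be non-negative")
    total = n_down + n_up
    if total == 0:
        raise ValueError("no non-null genes: the direction test is undefined")
    if variant == "binomial_sign":
        p = stats.binomtest(n_down, total, p=0.5, alternative="greater").pvalue
        table: tuple = (n_down, n_up)
    elif variant == "fisher_vs_balanced":
        half = total / 2.0
        ref = (int(np.floor(half)), int(np.ceil(half)))
        _, p = stats.fisher_exact([[n_down, n_up], [ref[0], ref[1]]], alternative="two-sided")
        table = ((n_down, n_up), ref)
    elif variant == "fisher_vs_reference":
        if reference is None:
            raise ValueError("fisher_vs_reference requires a reference count pair")
        _, p = stats.fisher_exact(
            [[n_down, n_up], [int(reference[0]), int(reference[1])]],
            alternative="two-sided",
        )
        table = ((n_down, n_up), tuple(int(v) for v in reference))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return ExactTestResult(variant=variant, p_value=float(p), table=table)


def friedman_test(values: pd.DataFrame | np.ndarray) -> tuple[float, int, float]:
    """Friedman rank test over conditions (columns), genes as blocks (rows).

    Returns (chi-square statistic with tie correction, df = k - 1, upper-tail
    p). Identical columns give statistic 0 and p = 1.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 conditions and >= 2 blocks")
    if np.isnan(x).all(axis=1).any():
        raise ValueError("a block has all-missing values")
    n, k = x.shape
    if np.allclose(x, x[:, [0]]):
        return 0.0, k - 1, 1.0
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    # tie correction: sum over blocks of (t^3 - t) per tie group
    ties = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts ** 3 - counts).sum())
    c = 1.0 - ties / (n * k * (k * k - 1))
    if c <= 0:  # every block fully tied
        return 0.0, k - 1, 1.0
    ssbn = float((ranks.sum(axis=0) ** 2).sum())
    statistic = (12.0 / (n * k * (k + 1)) * ssbn - 3.0 * n * (k + 1)) / c
    p = float(stats.chi2.sf(statistic, k - 1))
    return float(statistic), k - 1, p


def random_gene_set(
    universe: Sequence[str],
    exclude: Sequence[str],
    size: int = 49,
    seed: int = 0,
) -> list[str]:
    """Seeded uniform sample (without replacement) disjoint from ``exclude``."""
    pool = sorted(set(universe) - set(exclude))
    if len(pool) < size:
        raise ValueError(f"universe leaves only {len(pool)} genes, need {size}")
    rng = np.random.default_rng(seed)
    return list(rng.choice(np.asarray(pool, dtype=object), size=size, replace=False))


@dataclass
class ConsistencyReport:
    """Per-potency direction counts and exact tests for DEG and control sets."""

    counts: dict[str, pd.DataFrame]            # set name -> count table
    tests: pd.DataFrame                        # potency x set p-values
    flagged_potencies: list                    # down-set significant, random not
    variant: str
    null_band: float
    random_seed: int | None = None
    friedman: dict[str, tuple[float, int, float]] = field(default_factory=dict)


def consistency_report(
    cls: pd.DataFrame,
    down_set: Sequence[str],
    up_set: Sequence[str],
    random_set: Sequence[str],
    variant: str = "fisher_vs_reference",
    alpha: float = 0.05,
    random_seed: int | None = None,
) -> ConsistencyReport:
    """Run the direction test per potency for the down, up and random sets.

    With ``fisher_vs_reference`` the random set's counts are the reference
    for the DEG sets (and the balanced split for the random set itself).
    A potency is flagged when the down-set test is significant at ``alpha``
    while the random-set test is not.
    """
    sets = {"down": list(down_set), "up": list(up_set), "random": list(random_set)}
    counts = {name: count_signs(cls, genes) for name, genes in sets.items()}
    rows = []
    for p in cls.columns:
        row: dict = {"potency": p}
        ref_counts = counts["random"].loc[p]
        for name in sets:
            c = counts[name].loc[p]
            n_down, n_up = int(c["n_down"]), int(c["n_up"])
            try:
                if variant == "fisher_vs_reference" and name != "random":
                    res = exact_direction_test(
                        n_down,
                        n_up,
                        variant,
                        reference=(int(ref_counts["n_down"]), int(ref_counts["n_up"])),
                    )
                elif variant == "fisher_vs_reference":
                    res = exact_direction_test(n_down, n_up, "fisher_vs_balanced")
                else:
                    res = exact_direction_test(n_down, n_up, variant)
                row[f"p_{name}"] = res.p_value
            except ValueError:
                row[f"p_{name}"] = np.nan
        rows.append(row)
    tests = pd.DataFrame(rows).set_index("potency")
    flagged = [
        p
        for p in tests.index
        if tests.loc[p, "p_down"] < alpha
        and not (tests.loc[p, "p_random"] < alpha)
    ]
    return ConsistencyReport(
        counts=counts,
        tests=tests,
        flagged_potencies=flagged,
        variant=variant,
        null_band=float(cls.attrs.get("null_band", DEFAULT_NULL_BAND)),
        random_seed=random_seed,
    )


def enrichment_fold(
    list_hits: int, list_size: int, background_hits: int, background_size: int
) -> tuple[float, float]:
    """Generic local fold enrichment and exact upper-tail hypergeometric p.

    fold = (k/m) / (K/N); p = P(X >= k) with X ~ Hypergeom(N, K, m).
    """
    k, m, K, N = list_hits, list_size, background_hits, background_size
    if not (0 <= k <= min(m, K)) or m > N or K > N or m <= 0 or N <= 0:
        raise ValueError("invalid enrichment bounds")
    fold = (k / m) / (K / N)
    p = float(stats.hypergeom.sf(k - 1, N, K, m)) if k > 0 else 1.0
    return fold, p
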
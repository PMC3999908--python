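"""Synthetic probe-level microarray data with planted dose-response effects.

The generator emulates the structure the downstream statistics assume: a
whole-transcriptome one-colour array (by default 45,033 target genes x 3
probes each), hybridised for 12 conditions (drug at six centesimal
potencies plus matched succussed-vehicle controls) x 4 biological
replicates, with a planted effect set whose per-potency log2 shifts default
to the published 56-gene dose profile (49 down / 7 up at 2c, attenuating
with potency) and a handful of shift-free housekeeping transcripts.

Signal model, on the log2 scale::

    y[g, p, a] = baseline[g] + probe_offset[g, p] + shift[g, cond(a)]
                 + eps_rep[g, a] + eps_probe[g, p, a]

with gaussian baselines across genes, fixed per-probe additive offsets
(what median polish removes), gene x array replicate noise, and probe-level
measurement noise. Output is linear-scale fluorescence ``2**y``. Control
arrays at every potency share the zero-shift mean: the vehicle is assumed
inert, mirroring the published control-vs-control homogeneity.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    DEFAULT_POTENCIES,
    ProbeMatrix,
    SampleDescriptor,
    make_design,
)
from . import fixtures


def default_effect_table() -> pd.DataFrame:
    """The packaged 56-gene per-potency log2 shift profile (table3 DEG rows)."""
    return fixtures.table3_fold_changes(include_housekeeping=False)


def exponential_effect_table(
    shifts_2c: Mapping[str, float],
    potencies: Sequence[int] = DEFAULT_POTENCIES,
    rate: float = 1.0,
) -> pd.DataFrame:
    """Parametric attenuation profile: shift(d) = shift_2c * exp(-rate * steps).

    ``steps`` counts centesimal steps beyond 2c. Useful for property tests
    where a smooth monotone dose profile is wanted instead of the packaged one.
    """
    pots = list(potencies)
    rows = {
        g: [s * np.exp(-rate * (p - pots[0])) for p in pots]
        for g, s in shifts_2c.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=pots)


DEFAULT_HOUSEKEEPING = ("BC001601", "NM_002046", "BC009081", "NM_001101")


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic array experiment."""

    n_genes: int = 45033
    probes_per_gene: int = 3
    replicates: int = 4
    potencies: tuple[int, ...] = DEFAULT_POTENCIES
    baseline_mean: float = 8.0          # log2 units
    baseline_sd_between_genes: float = 1.5
    replicate_sd: float = 0.10          # gene x array noise, log2 units
    probe_sd: float = 0.05              # per-observation probe noise, log2
    probe_offset_sd: float = 0.30       # fixed per-probe additive offsets, log2
    effect_table: pd.DataFrame | None = None  # gene -> per-potency log2 shift
    housekeeping_ids: tuple[str, ...] = DEFAULT_HOUSEKEEPING
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_sd_between_genes", "replicate_sd", "probe_sd",
                     "probe_offset_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_genes <= 0 or self.replicates <= 0:
            raise ValueError("n_genes and replicates must be positive")
        if self.effect_table is None:
            self.effect_table = default_effect_table()
        missing = [p for p in self.potencies if p not in self.effect_table.columns]
        if missing and len(self.effect_table):
            raise ValueError(f"effect_table lacks potency column(s) {missing}")

    def gene_ids(self) -> np.ndarray:
        """Planted + housekeeping transcripts first, then filler genes."""
        planted = list(self.effect_table.index)
        named = planted + [h for h in self.housekeeping_ids if h not in planted]
        n_filler = self.n_genes - len(named)
        if n_filler < 0:
            raise ValueError(
                f"n_genes={self.n_genes} smaller than the {len(named)} named genes"
            )
        taken = set(named)
        filler: list[str] = []
        i = 0
        while len(filler) < n_filler:
            gid = f"SYN{i:06d}"
            if gid not in taken:
                filler.append(gid)
            i += 1
        return np.asarray(named + filler, dtype=object)


def build_truth_table(config: GeneratorConfig) -> pd.DataFrame:
    """Per-gene planted log2 shifts plus DEG flag and 2c direction.

    Columns: one per potency, then ``is_deg`` (bool) and ``direction``
    (``down``/``up``/``none``, the sign of the 2c shift).
    """
    gene_ids = config.gene_ids()
    pots = list(config.potencies)
    truth = pd.DataFrame(0.0, index=pd.Index(gene_ids, name="gene_id"), columns=pots)
    eff = config.effect_table
    unknown = [g for g in eff.index if g not in truth.index]
    if unknown:
        raise KeyError(f"effect_table references unknown gene id(s): {unknown[:5]}")
    if len(eff):
        truth.loc[eff.index, pots] = eff[pots].to_numpy()
    first = pots[0]
    truth["is_deg"] = truth.index.isin(eff.index) & (truth[first] != 0)
    truth["direction"] = "none"
    truth.loc[truth["is_deg"] & (truth[first] < 0), "direction"] = "down"
    truth.loc[truth["is_deg"] & (truth[first] > 0), "direction"] = "up"
    return truth


def generate_probe_data(
    config: GeneratorConfig,
) -> tuple[ProbeMatrix, list[SampleDescriptor], pd.DataFrame]:
    """Simulate one full experiment; bit-reproducible for a given config."""
    rng = np.random.default_rng(config.seed)
    truth = build_truth_table(config)
    gene_ids = truth.index.to_numpy()
    n_g, n_p = config.n_genes, config.probes_per_gene
    design = make_design(config.potencies, config.replicates)
    n_a = len(design)

    baseline = config.baseline_mean + config.baseline_sd_between_genes * rng.standard_normal(n_g)
    probe_offset = config.probe_offset_sd * rng.standard_normal((n_g, n_p))

    # per-array shift column: zero for controls, planted profile for drug
    shifts = np.zeros((n_g, n_a))
    pots = list(config.potencies)
    for j, s in enumerate(design):
        if s.agent == "drug":
            shifts[:, j] = truth[s.potency].to_numpy()
    del pots

    y = (
        baseline[:, None, None]
        + probe_offset[:, :, None]
        + shifts[:, None, :]
        + config.replicate_sd * rng.standard_normal((n_g, 1, n_a))
        + config.probe_sd * rng.standard_normal((n_g, n_p, n_a))
    )
    values = np.exp2(y).reshape(n_g * n_p, n_a)
    probe = ProbeMatrix(gene_ids, n_p, values, tuple(design))
    return probe, design, truth


def generate_qpcr_cq(
    truth: pd.DataFrame,
    genes: Sequence[str],
    hk_ids: Sequence[str],
    noise_sd: float = 0.0,
    seed: int = 0,
    potency: int = 2,
    base_cq: float = 24.0,
    tech_replicates: int = 3,
) -> pd.DataFrame:
    """Synthetic Cq table whose ddCq analysis recovers the planted shifts.

    Cq is inversely proportional to log2 template abundance, so a drug
    sample expressing a gene ``shift`` log2 units above control yields
    ``Cq = base_cq - shift`` (plus noise). Housekeeping genes stay at
    ``base_cq`` in both samples. Two samples are emitted, ``treated`` and
    ``control``, with ``tech_replicates`` technical replicates per
    sample x gene.
    """
    if not len(hk_ids):
        raise ValueError("at least one housekeeping gene id is required")
    missing = [g for g in list(genes) + list(hk_ids) if g not in truth.index]
    if missing:
        raise KeyError(f"gene(s) not in truth table: {missing[:5]}")
    rng = np.random.default_rng(seed)
    records = []
    for sample, treated in (("treated", True), ("control", False)):
        for g in list(genes) + list(hk_ids):
            shift = float(truth.loc[g, potency]) if (treated and g not in hk_ids) else 0.0
            for rep in range(1, tech_replicates + 1):
                cq = base_cq - shift + noise_sd * rng.standard_normal()
                records.append((sample, g, rep, cq))
    return pd.DataFrame(records, columns=["sample_id", "gene_id", "tech_rep", "cq"])
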
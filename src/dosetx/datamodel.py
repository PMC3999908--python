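"""Core data model and tab-separated I/O.

The pipeline's working variables are expression matrices of log2
fluorescence (genes x arrays), probe-level linear-scale matrices
(gene x probe rows), and the experimental design: a full factorial of
agent (drug vs succussed-vehicle control) x centesimal potency x
biological replicate.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_POTENCIES: tuple[int, ...] = (2, 3, 4, 5, 9, 30)

AGENTS = ("drug", "control")


class DesignError(ValueError):
    """Raised when a sample design contradicts the data it describes."""


@dataclass(frozen=True, order=True)
class SampleDescriptor:
    """One array / culture dish: which agent, at which potency, which replicate."""

    sample_id: str
    agent: str
    potency: int
    replicate: int

    def __post_init__(self) -> None:
        if self.agent not in AGENTS:
            raise DesignError(
                f"agent must be one of {AGENTS}, got {self.agent!r} "
                f"for sample {self.sample_id!r}"
            )
        if self.replicate < 1:
            raise DesignError(
                f"replicate must be >= 1, got {self.replicate} "
                f"for sample {self.sample_id!r}"
            )


def make_design(
    potencies: Sequence[int] = DEFAULT_POTENCIES, replicates: int = 4
) -> list[SampleDescriptor]:
    """Full factorial agent x potency x replicate design (default 12 x 4)."""
    return [
        SampleDescriptor(f"{agent[0].upper()}{p}c_r{r}", agent, int(p), r)
        for agent in AGENTS
        for p in potencies
        for r in range(1, replicates + 1)
    ]


@dataclass
class DesignReport:
    passed: bool
    duplicates: list[str] = field(default_factory=list)
    missing_cells: list[str] = field(default_factory=list)
    unequal_replicates: list[str] = field(default_factory=list)

    def __str__(self) -> str:  # pragma: no cover - convenience only
        if self.passed:
            return "design OK"
        parts = []
        if self.duplicates:
            parts.append(f"duplicate sample ids: {', '.join(self.duplicates)}")
        if self.missing_cells:
            parts.append(f"missing cells: {', '.join(self.missing_cells)}")
        if self.unequal_replicates:
            parts.append(
                f"unequal replicate counts: {', '.join(self.unequal_replicates)}"
            )
        return "; ".join(parts)


def validate_design(
    samples: Sequence[SampleDescriptor],
    potencies: Sequence[int] = DEFAULT_POTENCIES,
    replicates: int = 4,
) -> DesignReport:
    """Check a sample list against the expected full factorial design.

    Passes iff every agent x potency x replicate cell is present exactly
    once and no sample_id repeats.
    """
    report = DesignReport(passed=True)
    seen_ids: set[str] = set()
    for s in samples:
        if s.sample_id in seen_ids:
            report.duplicates.append(s.sample_id)
        seen_ids.add(s.sample_id)
    cells: dict[tuple[str, int, int], int] = {}
    for s in samples:
        key = (s.agent, s.potency, s.replicate)
        cells[key] = cells.get(key, 0) + 1
    for agent in AGENTS:
        for p in potencies:
            for r in range(1, replicates + 1):
                n = cells.get((agent, int(p), r), 0)
                if n == 0:
                    report.missing_cells.append(f"{agent} {p}c replicate {r}")
                elif n > 1:
                    report.unequal_replicates.append(
                        f"{agent} {p}c replicate {r} present {n} times"
                    )
    extra = set(cells) - {
        (a, int(p), r)
        for a in AGENTS
        for p in potencies
        for r in range(1, replicates + 1)
    }
    for key in sorted(extra):
        report.unequal_replicates.append(
            f"unexpected cell {key[0]} {key[1]}c replicate {key[2]}"
        )
    report.passed = not (
        report.duplicates or report.missing_cells or report.unequal_replicates
    )
    return report


@dataclass
class ExpressionMatrix:
    """Genes x samples table of log2 fluorescence values.

    ``data`` is indexed by gene (transcript accession) with one column per
    sample_id, in the order of ``samples``.
    """

    data: pd.DataFrame
    samples: tuple[SampleDescriptor, ...]

    def __post_init__(self) -> None:
        self.samples = tuple(self.samples)
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise DesignError("duplicate sample_id in design")
        if list(self.data.columns) != ids:
            raise DesignError(
                "expression columns do not match design sample ids: "
                f"{list(self.data.columns)} vs {ids}"
            )
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][:5].tolist()
            raise DesignError(f"duplicate gene ids, e.g. {dup}")
        if not np.all(np.isfinite(self.data.to_numpy())):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    def sample_ids(
        self, agent: str | None = None, potency: int | None = None
    ) -> list[str]:
        """Sample ids, optionally restricted to an agent and/or potency."""
        out = []
        for s in self.samples:
            if agent is not None and s.agent != agent:
                continue
            if potency is not None and s.potency != potency:
                continue
            out.append(s.sample_id)
        return out


@dataclass
class ProbeMatrix:
    """Probe-level linear-scale fluorescence, ``probes_per_gene`` rows per gene.

    ``values`` has shape (n_genes * probes_per_gene, n_samples), gene-major
    (all probes of gene 0 first). Values are non-negative raw fluorescence.
    """

    gene_ids: np.ndarray
    probes_per_gene: int
    values: np.ndarray
    samples: tuple[SampleDescriptor, ...]

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        self.samples = tuple(self.samples)
        n_rows = len(self.gene_ids) * self.probes_per_gene
        if self.values.shape != (n_rows, len(self.samples)):
            raise ValueError(
                f"probe matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {self.probes_per_gene} probes "
                f"x {len(self.samples)} samples"
            )
        if np.any(self.values < 0):
            raise ValueError("probe fluorescence must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def as_3d(self) -> np.ndarray:
        """View as (n_genes, probes_per_gene, n_samples)."""
        return self.values.reshape(self.n_genes, self.probes_per_gene, -1)


# ---------------------------------------------------------------------------
# Tab-separated I/O


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> Path:
    """Write a matrix as TSV: gene_id column then one column per sample, 6 decimals."""
    path = Path(path)
    matrix.data.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6f")
    return path


def read_expression_tsv(
    path: str | Path, design: Sequence[SampleDescriptor]
) -> ExpressionMatrix:
    """Read a TSV written by :func:`write_expression_tsv` against a design.

    The file header must contain every design sample_id; columns are
    reordered to design order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col="gene_id", dtype={"gene_id": str})
    wanted = [s.sample_id for s in design]
    missing = [c for c in wanted if c not in df.columns]
    if missing:
        raise DesignError(
            f"file {path} header lacks design sample(s): {', '.join(missing)}"
        )
    df = df[wanted]
    bad = df.columns[[not pd.api.types.is_numeric_dtype(t) for t in df.dtypes]]
    if len(bad):
        col = bad[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
        raise ValueError(f"non-numeric cell at gene {row!r}, sample {col!r}")
    df.index = df.index.astype(str)
    return ExpressionMatrix(df.astype(float), tuple(design))


def write_design_tsv(samples: Sequence[SampleDescriptor], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame([dataclasses.asdict(s) for s in samples]).to_csv(
        path, sep="\t", index=False
    )
    return path


def read_design_tsv(path: str | Path) -> list[SampleDescriptor]:
    df = pd.read_csv(path, sep="\t")
    needed = {"sample_id", "agent", "potency", "replicate"}
    if not needed <= set(df.columns):
        raise DesignError(f"design table must have columns {sorted(needed)}")
    return [
        SampleDescriptor(str(r.sample_id), str(r.agent), int(r.potency), int(r.replicate))
        for r in df.itertuples()
    ]


def write_probe_tsv(probe: ProbeMatrix, path: str | Path) -> Path:
    """Probe TSV: columns gene_id, probe (1-based), then one column per sample."""
    path = Path(path)
    ids = np.repeat(probe.gene_ids, probe.probes_per_gene)
    probes = np.tile(np.arange(1, probe.probes_per_gene + 1), probe.n_genes)
    df = pd.DataFrame(probe.values, columns=[s.sample_id for s in probe.samples])
    df.insert(0, "probe", probes)
    df.insert(0, "gene_id", ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def read_probe_tsv(path: str | Path, design: Sequence[SampleDescriptor]) -> ProbeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    wanted = [s.sample_id for s in design]
    missing = [c for c in wanted if c not in df.columns]
    if missing:
        raise DesignError(f"probe file lacks design sample(s): {', '.join(missing)}")
    gene_ids = df["gene_id"].to_numpy()
    # gene-major order expected; derive probes_per_gene from the first gene
    first = gene_ids[0]
    ppg = int(np.argmax(gene_ids != first)) if len(gene_ids) > 1 else 1
    if ppg == 0:
        ppg = len(gene_ids)
    uniq = gene_ids[::ppg]
    return ProbeMatrix(uniq, ppg, df[wanted].to_numpy(float), tuple(design))
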
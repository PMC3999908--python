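"""End-to-end orchestration: simulate (or load) -> preprocess -> stage-one
differential expression -> stage-two directional consistency -> clustering,
with TSV artifacts and a machine-readable JSON run report.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, diffexpr, doseresponse, preprocess, simulate
from .datamodel import (
    read_design_tsv,
    read_probe_tsv,
    write_design_tsv,
    write_expression_tsv,
)

log = logging.getLogger("dosetx")

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """One reproducible pipeline run."""

    out_dir: str | Path | None = None
    generator: simulate.GeneratorConfig = field(default_factory=simulate.GeneratorConfig)
    probe_tsv: str | Path | None = None    # load instead of simulating
    design_tsv: str | Path | None = None
    fc_threshold: float = 0.5
    p_threshold: float = 0.05
    null_band: float = 0.05
    deg_potency: int = 2
    deg_convention: str = "pooled"         # stage-one contrast reference
    dose_convention: str = "matched"       # stage-two fold-change reference
    bh_m: int | None = None                # None -> number of genes tested
    k_clusters: int = 5
    restarts: int = 20
    random_set_size: int = 49
    random_set_seed: int = 0
    background_percentile: float = 0.0
    write_outputs: bool = True

    def validate(self) -> None:
        if self.fc_threshold <= 0 or self.p_threshold <= 0 or self.null_band < 0:
            raise ValueError("thresholds must be positive (null_band >= 0)")
        if self.write_outputs and self.out_dir is None:
            raise ValueError("missing required config field: out_dir")


def _stage(name: str):
    log.info("stage=%s", name)
    return time.perf_counter()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; deterministic given the config seeds.

    Returns the run report (also written as ``report.json`` next to the
    stage TSVs when outputs are enabled).
    """
    config.validate()
    out = Path(config.out_dir) if config.out_dir else None
    if out is not None and config.write_outputs:
        out.mkdir(parents=True, exist_ok=True)

    t0 = _stage("input")
    if config.probe_tsv is not None:
        design = read_design_tsv(config.design_tsv)
        probe = read_probe_tsv(config.probe_tsv, design)
        truth = None
    else:
        probe, design, truth = simulate.generate_probe_data(config.generator)
    log.info("input done in %.1fs (%d genes, %d arrays)",
             time.perf_counter() - t0, probe.n_genes, len(design))

    t0 = _stage("preprocess")
    expr = preprocess.preprocess_probe_data(
        probe, background_percentile=config.background_percentile
    )
    qc = preprocess.qc_metrics(expr)
    log.info("preprocess done in %.1fs (mean r=%.4f)",
             time.perf_counter() - t0, qc.mean_correlation)

    t0 = _stage("control_homogeneity")
    bh_m = config.bh_m or expr.n_genes
    homog = diffexpr.control_homogeneity(expr, alpha=config.p_threshold, bh_m=bh_m)

    t0 = _stage("differential_expression")
    fits = diffexpr.fit_contrast(expr, config.deg_potency, config.deg_convention)
    mod = diffexpr.empirical_bayes_moderate(fits, bh_m=bh_m)
    degs = diffexpr.select_degs(mod.table, config.fc_threshold, config.p_threshold)
    down_set = degs.index[degs["direction"] == "down"].tolist()
    up_set = degs.index[degs["direction"] == "up"].tolist()
    log.info("DE done in %.1fs (%d DEGs: %d down / %d up)",
             time.perf_counter() - t0, len(degs), len(down_set), len(up_set))

    t0 = _stage("dose_response")
    fc_pooled = doseresponse.fold_change_table(expr, "pooled")
    fc_dose = (
        fc_pooled
        if config.dose_convention == "pooled"
        else doseresponse.fold_change_table(expr, "matched")
    )
    cls = doseresponse.classify_signs(fc_dose, config.null_band)
    random_set = doseresponse.random_gene_set(
        expr.gene_ids, degs.index, size=config.random_set_size,
        seed=config.random_set_seed,
    )
    report_sets = doseresponse.consistency_report(
        cls,
        down_set,
        up_set,
        random_set,
        alpha=config.p_threshold,
        random_seed=config.random_set_seed,
    ) if down_set or up_set else None
    # Friedman over the 12 condition-group mean expression values per gene
    group_means = {}
    for s in expr.samples:
        group_means.setdefault((s.agent, s.potency), []).append(s.sample_id)
    gm = pd.DataFrame(
        {f"{a}_{p}c": expr.data[cols].mean(axis=1) for (a, p), cols in group_means.items()}
    )
    friedman = {}
    for name, genes in (("down", down_set), ("up", up_set)):
        if len(genes) >= 2:
            friedman[name] = doseresponse.friedman_test(gm.loc[genes])
    if report_sets is not None:
        report_sets.friedman = friedman
    log.info("dose-response done in %.1fs", time.perf_counter() - t0)

    t0 = _stage("clustering")
    cluster = None
    if len(degs) >= config.k_clusters:
        cluster = clustering.kmeans_profiles(
            fc_pooled.loc[degs.index],
            config.k_clusters,
            seed=config.random_set_seed,
            restarts=config.restarts,
        )
    log.info("clustering done in %.1fs", time.perf_counter() - t0)

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seeds": {
            "generator": getattr(config.generator, "seed", None),
            "random_set": config.random_set_seed,
        },
        "n_genes": expr.n_genes,
        "qc": {
            "mean_correlation": qc.mean_correlation,
            "flagged_arrays": qc.flagged_arrays,
            "cv_of_array_means": qc.cv_of_array_means,
        },
        "control_homogeneity": {
            "passed": homog.passed,
            "n_offending": int(len(homog.offending)),
        },
        "degs": {
            "n": int(len(degs)),
            "n_down": len(down_set),
            "n_up": len(up_set),
            "fc_threshold": config.fc_threshold,
            "p_threshold": config.p_threshold,
            "prior_df": mod.prior_df,
            "prior_var": mod.prior_var,
        },
        "dose_response": None,
        "clustering": None,
    }
    if truth is not None:
        planted = truth.index[truth["is_deg"]]
        report["truth"] = {
            "n_planted": int(len(planted)),
            "recovered": int(degs.index.isin(planted).sum()),
            "false_positives": int((~degs.index.isin(planted)).sum()),
        }
    if report_sets is not None:
        report["dose_response"] = {
            "convention": config.dose_convention,
            "null_band": config.null_band,
            "counts": {
                name: tbl.reset_index().to_dict(orient="records")
                for name, tbl in report_sets.counts.items()
            },
            "tests": report_sets.tests.reset_index().to_dict(orient="records"),
            "flagged_potencies": [int(p) for p in report_sets.flagged_potencies],
            "friedman": {
                name: {"statistic": s, "df": d, "p": p}
                for name, (s, d, p) in friedman.items()
            },
        }
    if cluster is not None:
        sizes = cluster.assignments.value_counts().sort_index()
        report["clustering"] = {
            "k": cluster.k,
            "sizes": [int(v) for v in sizes],
            "inertia": cluster.inertia,
        }

    if out is not None and config.write_outputs:
        write_expression_tsv(expr, out / "expression.tsv")
        write_design_tsv(design, out / "design.tsv")
        mod.table.to_csv(out / "stats.tsv", sep="\t", index_label="gene_id",
                         float_format="%.6g")
        degs.to_csv(out / "degs.tsv", sep="\t", index_label="gene_id",
                    float_format="%.6g")
        fc_dose.to_csv(out / "fold_changes.tsv", sep="\t", index_label="gene_id",
                       float_format="%.6f")
        cls.to_csv(out / "sign_matrix.tsv", sep="\t", index_label="gene_id")
        if report_sets is not None:
            pd.concat(report_sets.counts, names=["gene_set"]).to_csv(
                out / "direction_counts.tsv", sep="\t"
            )
        if cluster is not None:
            cluster.assignments.to_csv(out / "clusters.tsv", sep="\t",
                                       index_label="gene_id")
            cluster.centroids.to_csv(out / "centroids.tsv", sep="\t",
                                     index_label="cluster", float_format="%.6f")
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
        report["out_dir"] = str(out)
    return report
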
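"""End-to-end orchestration: simulate/ingest -> preprocess -> call -> enrich.

A :class:`RunConfig` holds every stage parameter with the pipeline defaults
(expression filter fold 2; APR cuts 0.95/0.95 with fold cut 2; GSEA
significance at FDR q < 0.05 or FWER < 0.1; 5 replicates per condition), a
run writes all stage outputs plus a machine-readable JSON report, and the
resolved configuration is saved next to the outputs for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .arrayio import (GeneSetCollection, read_gmt, read_matrix, read_scans,
                      write_matrix, write_treeview)
from .enrichment import gsea_significance, rank_by_score, rank_position_test
from .preprocess import ExpressionMatrix, build_expression_matrix
from .ripstats import (call_targets_from_matrix, cluster_targets,
                       qq_against_normal, squared_correlation)
from .simulate import SimulationParams, generate_experiment, write_experiment

log = logging.getLogger("ripchip")


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run."""

    out_dir: str = "ripchip_run"
    manifest: str | None = None       # existing scans; None -> simulate
    gmt: str | None = None            # gene sets; None -> simulated sets
    validation_matrix: str | None = None  # pre-normalized matrix (validation mode)
    loess_span: float = 0.4
    filter_fold: float = 2.0
    ip_cut: float = 0.95
    mock_cut: float = 0.95
    fold_cut: float = 2.0
    n_perm: int = 1000
    gsea_weight: float = 1.0
    fdr_cut: float = 0.05
    fwer_cut: float = 0.1
    seed: int = 7
    simulation: SimulationParams = field(default_factory=SimulationParams)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", {})
        if isinstance(sim.get("set_size_range"), list):
            sim["set_size_range"] = tuple(sim["set_size_range"])
        cfg = cls(**raw)
        cfg.simulation = SimulationParams(**sim) if sim else cfg.simulation
        return cfg


@dataclass
class RunReport:
    probes_in: int
    probes_expressed: int
    targets_called: int
    target_fraction_pct: float
    r2_ip_vs_total: float
    r2_ip_vs_mock: float
    significant_sets: list[str]
    seed: int
    version: str = __version__
    planted_targets: int | None = None
    sensitivity: float | None = None
    false_discovery_proportion: float | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def summarize_target_fraction(targets: int, expressed: int) -> str:
    """Targets as a percentage of the expressed universe, one decimal."""
    if expressed == 0:
        raise ValueError("expressed count is zero")
    return f"{100.0 * targets / expressed:.1f}%"


def run_pipeline(config: RunConfig) -> RunReport:
    """Run every stage and write outputs + report under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)

    truth = None
    if config.validation_matrix is not None:
        matrix = _ingest_validation_matrix(config.validation_matrix)
        log.info("validation mode: %d probes x %d samples (pass-through)",
                 len(matrix.probe_ids), len(matrix.sample_meta))
        collection = read_gmt(config.gmt) if config.gmt else None
    elif config.manifest is not None:
        scans = read_scans(config.manifest)
        log.info("read %d scans from %s", len(scans), config.manifest)
        matrix = build_expression_matrix(scans, span=config.loess_span,
                                         filter_fold=config.filter_fold)
        collection = read_gmt(config.gmt) if config.gmt else None
    else:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        scans, truth = generate_experiment(sim)
        write_experiment(scans, truth, out / "simulated")
        log.info("simulated %d arrays of %d probes", len(scans), sim.n_probes)
        matrix = build_expression_matrix(scans, span=config.loess_span,
                                         filter_fold=config.filter_fold)
        if config.gmt:
            collection = read_gmt(config.gmt)
        else:
            collection = GeneSetCollection(sets={
                name: ("simulated", list(m))
                for name, m in truth.gene_set_membership.items()})

    write_matrix(matrix.probe_ids, matrix.sample_names, matrix.values,
                 out / "matrix.tsv")
    n_probes = len(matrix.probe_ids)
    n_expressed = int(matrix.expressed_mask.sum())
    log.info("preprocess: %d probes in, %d expressed", n_probes, n_expressed)

    call, diff = call_targets_from_matrix(
        matrix, ip_cut=config.ip_cut, mock_cut=config.mock_cut,
        fold_cut=config.fold_cut)
    targets = call.to_frame()
    targets["t_score"] = diff.t_score
    targets["p_value"] = diff.p_value
    targets["bh_q"] = diff.bh_q
    targets["log_fold_change"] = diff.log_fold_change
    targets.to_csv(out / "targets.tsv", sep="\t", index=False)
    log.info("called %d targets of %d expressed", call.n_targets, n_expressed)

    # diagnostics: QQ of t-scores, r^2 of per-probe means between conditions
    expr = matrix.expressed()
    theo, emp = qq_against_normal(diff.t_score)
    np.savetxt(out / "qq_t_scores.tsv",
               np.column_stack([theo, emp]), delimiter="\t",
               header="theoretical\tempirical", comments="")
    ip_mean = expr.columns_for("IP").mean(axis=1)
    r2_total = squared_correlation(ip_mean, expr.columns_for("total").mean(axis=1))
    r2_mock = squared_correlation(ip_mean, expr.columns_for("mock").mean(axis=1))

    # cluster + TreeView export of the target submatrix
    if call.n_targets >= 2:
        tmask = np.isin(expr.probe_ids, call.probe_ids[call.is_target])
        sub = expr.restrict(tmask)
        row_o, col_o, row_t, col_t = cluster_targets(sub.values)
        write_treeview(sub.probe_ids, sub.sample_names, sub.values,
                       row_o, col_o, out / "targets_clustered",
                       row_tree=row_t, col_tree=col_t)

    significant: list[str] = []
    if collection is not None and len(collection) > 0:
        ranked = rank_by_score(diff.probe_ids, diff.t_score)
        results = gsea_significance(ranked, collection, n_perm=config.n_perm,
                                    p=config.gsea_weight, seed=config.seed)
        rows = [dataclasses.asdict(r) for r in results]
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        significant = [r.set_name for r in results
                       if r.fdr_q < config.fdr_cut or r.fwer_p < config.fwer_cut]
        log.info("GSEA: %d/%d sets significant", len(significant), len(results))

    report = RunReport(
        probes_in=n_probes,
        probes_expressed=n_expressed,
        targets_called=call.n_targets,
        target_fraction_pct=round(100.0 * call.n_targets / max(n_expressed, 1), 1),
        r2_ip_vs_total=round(r2_total, 4),
        r2_ip_vs_mock=round(r2_mock, 4),
        significant_sets=significant,
        seed=config.seed,
    )
    if truth is not None:
        planted = set(truth.planted_ids.tolist())
        called = set(call.probe_ids[call.is_target].tolist())
        report.planted_targets = len(planted)
        report.sensitivity = round(len(planted & called) / max(len(planted), 1), 4)
        report.false_discovery_proportion = round(
            len(called - planted) / max(len(called), 1), 4)
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    return report


def _ingest_validation_matrix(path: str | Path) -> ExpressionMatrix:
    """Adapter for externally normalized matrices (e.g. GEO supplements).

    Columns must be named ``<role>_<replicate>`` with roles IP/mock/total.
    Values are taken as already-normalized log2 ratios; every probe is
    treated as expressed (the external filter already ran).
    """
    df = read_matrix(path)
    meta = []
    for col in df.columns:
        role, _, rep = str(col).rpartition("_")
        meta.append((role, int(rep)))
    return ExpressionMatrix(
        probe_ids=df.index.to_numpy(dtype=object),
        sample_meta=meta,
        values=df.to_numpy(dtype=float),
        expressed_mask=np.ones(len(df), dtype=bool),
    )


def rank_test_report(matrix: ExpressionMatrix, set_members,
                     rank_key: str = "t_score") -> dict:
    """Rank-position test of a set, ranking either by t-score or by IP APR."""
    from .ripstats import average_percentile_rank, call_targets_from_matrix

    expr = matrix.expressed()
    if rank_key == "apr":
        scores = average_percentile_rank(expr.columns_for("IP"))
        ranked = rank_by_score(expr.probe_ids, scores)
    else:
        _, diff = call_targets_from_matrix(matrix)
        ranked = rank_by_score(diff.probe_ids, getattr(diff, rank_key))
    stat, p = rank_position_test(ranked, set_members)
    return {"rank_key": rank_key, "statistic": stat, "p_value": p,
            "test": "one-sided Wilcoxon rank-sum (members vs non-members)",
            "n_members_in_list": int(len(ranked.positions_of(set_members)))}
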
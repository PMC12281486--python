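"""End-to-end orchestration with auditable run reports.

``run_targets`` executes the full competition-PAL target deconvolution:
median normalization, log2, paired probe-vs-vehicle statistics, Gaussian fit
and reciprocal-curve enrichment filter, paired probe-vs-competition
statistics on the enriched subset, and the two-stage specificity call.

``run_metabolomics`` executes pooled-QC CV filtering, normalization,
per-comparison statistics, significance filters, Venn overlaps, and
hierarchical clustering of the final significant set.

Every threshold, fit parameter and stage count lands in a JSON-serializable
report, so any individual call can be audited without rerunning.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffstats, metabo_analysis, preprocess, target_filter
from .io_tables import (
    AbundanceMatrix,
    MetaboliteTable,
    SampleDesign,
    ValidationError,
    read_abundance_table,
    read_metabolite_table,
)
from .synthetic_data import COND_COMPETITION, COND_PROBE, COND_VEHICLE

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All thresholds and switches, defaulting to the published settings:

    curvature c = 0.8, fold-change cutoff at mu + 1 sigma, FDR 5% (two-stage
    step-up for the proteomics stages), stage-2 competition log2 fold change
    > 1, pooled-QC CV ceiling 25%, process/instrument QA ceilings 20%/10%.
    """

    # proteomics target calling
    condition_vehicle: str = COND_VEHICLE
    condition_probe: str = COND_PROBE
    condition_competition: str = COND_COMPETITION
    curvature_c: float = target_filter.DEFAULT_CURVATURE
    sigma_multiplier: float = target_filter.DEFAULT_SIGMA_MULTIPLIER
    q_max: float = target_filter.DEFAULT_Q_MAX
    min_log2fc_competition: float = target_filter.DEFAULT_MIN_X_COMPETITION
    n_bins: int | None = None
    stage1_q_max: float | None = None
    competition_fdr_scope: str = "enriched"
    proteomics_fdr_method: str = "bky"
    proteomics_paired: bool = True
    normalize: bool = True
    # metabolomics
    cv_max: float = preprocess.DEFAULT_QC_CV_MAX
    process_cv_max: float = preprocess.DEFAULT_PROCESS_CV_MAX
    instrument_cv_max: float = preprocess.DEFAULT_INSTRUMENT_CV_MAX
    metabo_fdr_method: str = "bh"
    metabo_paired: bool = False
    metabo_p_max: float = 0.05
    metabo_q_max: float = 0.05
    metabo_min_abs_log2fc: float = 2.0
    metabo_levels: tuple[str, ...] = ("L1", "L2")
    # misc
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, overrides: dict | None = None) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if overrides:
            data.update(overrides)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["metabo_levels"] = list(d["metabo_levels"])
        return d


def run_targets(
    cfg: RunConfig,
    matrix: AbundanceMatrix | None = None,
    design: SampleDesign | None = None,
    abundance_path: str | Path | None = None,
    design_path: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full PAL target deconvolution; returns (calls, report).

    Accepts in-memory objects or file paths.  The report records the
    configuration, the Gaussian fit (mu, sigma, convergence), the curve
    parameters, and feature counts at every stage.
    """
    if design is None:
        if design_path is None:
            raise ValidationError("run_targets needs a design or design_path")
        design = SampleDesign.read(design_path)
    if matrix is None:
        if abundance_path is None:
            raise ValidationError("run_targets needs a matrix or abundance_path")
        matrix = read_abundance_table(abundance_path, design)

    report: dict = {"stage": "targets", "config": cfg.to_dict(), "counts": {}}
    report["counts"]["features_input"] = len(matrix.feature_ids)

    norm = preprocess.global_median_normalize(matrix) if cfg.normalize else matrix
    logm = preprocess.log2_transform(norm)

    pv = diffstats.compare_conditions(
        logm, design, cfg.condition_probe, cfg.condition_vehicle,
        paired=cfg.proteomics_paired, fdr_method=cfg.proteomics_fdr_method,
        alpha=cfg.alpha,
    )
    pc = diffstats.compare_conditions(
        logm, design, cfg.condition_probe, cfg.condition_competition,
        paired=cfg.proteomics_paired, fdr_method=cfg.proteomics_fdr_method,
        alpha=cfg.alpha,
    )
    report["counts"]["features_tested_probe_vehicle"] = len(pv)
    report["counts"]["features_tested_probe_competition"] = len(pc)

    calls, fit = target_filter.classify_targets(
        pv, pc,
        c=cfg.curvature_c,
        sigma_multiplier=cfg.sigma_multiplier,
        q_max=cfg.q_max,
        min_x_comp=cfg.min_log2fc_competition,
        n_bins=cfg.n_bins,
        stage1_q_max=cfg.stage1_q_max,
        competition_fdr_scope=cfg.competition_fdr_scope,
        fdr_method=cfg.proteomics_fdr_method,
    )
    counts = calls["call"].value_counts().to_dict()
    report["gaussian_fit"] = {
        "amplitude": fit.amplitude,
        "mu": fit.mu,
        "sigma": fit.sigma,
        "rss": fit.rss,
        "converged": fit.converged,
        "n_bins": fit.n_bins,
    }
    report["curve"] = {
        "c": cfg.curvature_c,
        "x0": fit.mu + cfg.sigma_multiplier * fit.sigma,
    }
    n_enriched = int(
        counts.get(target_filter.CALL_SPECIFIC, 0)
        + counts.get(target_filter.CALL_NONSPECIFIC, 0)
    )
    report["counts"]["stage1_enriched"] = n_enriched
    report["counts"]["specific"] = int(counts.get(target_filter.CALL_SPECIFIC, 0))
    report["counts"]["nonspecific"] = int(
        counts.get(target_filter.CALL_NONSPECIFIC, 0)
    )
    report["counts"]["not_enriched"] = int(
        counts.get(target_filter.CALL_NOT_ENRICHED, 0)
    )
    return calls, report


def run_metabolomics(
    cfg: RunConfig,
    comparisons: list[tuple[str, str]],
    table: MetaboliteTable | None = None,
    design: SampleDesign | None = None,
    table_path: str | Path | None = None,
    design_path: str | Path | None = None,
) -> dict:
    """QC filter -> stats -> filters -> overlaps -> clustering.

    ``comparisons`` lists (group_a, group_b) pairs; log2 fold changes are
    group_a over group_b.  Returns a result dict with per-comparison tables,
    significant sets at each filter tier, pairwise overlap counts, the
    cluster tree of the final significant set, and the audit report.
    """
    if design is None:
        if design_path is None:
            raise ValidationError("run_metabolomics needs a design or design_path")
        design = SampleDesign.read(design_path)
    if table is None:
        if table_path is None:
            raise ValidationError("run_metabolomics needs a table or table_path")
        table = read_metabolite_table(table_path, design)

    report: dict = {"stage": "metabolomics", "config": cfg.to_dict(), "counts": {}}
    report["counts"]["features_input"] = len(table.feature_ids)

    filtered, qc_report = preprocess.qc_filter_metabolites(
        table, design, cv_max=cfg.cv_max
    )
    report["counts"]["qc_removed"] = qc_report.n_removed
    report["counts"]["features_after_qc"] = len(filtered.feature_ids)

    norm = (
        preprocess.global_median_normalize(filtered.matrix)
        if cfg.normalize
        else filtered.matrix
    )
    logm = preprocess.log2_transform(norm)

    results: dict[str, pd.DataFrame] = {}
    sets_p: dict[str, set] = {}
    sets_q: dict[str, set] = {}
    sets_q_fc: dict[str, set] = {}
    for a, b in comparisons:
        key = f"{a}_vs_{b}"
        res = diffstats.compare_conditions(
            logm, design, a, b,
            paired=cfg.metabo_paired, fdr_method=cfg.metabo_fdr_method,
            alpha=cfg.alpha,
        )
        results[key] = res
        sets_p[key] = metabo_analysis.significant_metabolites(
            res, filtered, metabo_analysis.SignificanceFilter(p_max=cfg.metabo_p_max)
        )
        sets_q[key] = metabo_analysis.significant_metabolites(
            res, filtered, metabo_analysis.SignificanceFilter(q_max=cfg.metabo_q_max)
        )
        sets_q_fc[key] = metabo_analysis.significant_metabolites(
            res,
            filtered,
            metabo_analysis.SignificanceFilter(
                q_max=cfg.metabo_q_max,
                min_abs_log2fc=cfg.metabo_min_abs_log2fc,
            ),
        )
        report["counts"][key] = {
            "tested": len(res),
            "p_filter": len(sets_p[key]),
            "q_filter": len(sets_q[key]),
            "q_fc_filter": len(sets_q_fc[key]),
        }

    overlaps = {}
    keys = list(results)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            for tier, sets in (
                ("p", sets_p), ("q", sets_q), ("q_fc", sets_q_fc)
            ):
                n_a, n_b, n_both = metabo_analysis.overlap_counts(
                    sets[keys[i]], sets[keys[j]]
                )
                overlaps[f"{keys[i]}__{keys[j]}__{tier}"] = {
                    "n_a": n_a, "n_b": n_b, "n_both": n_both,
                }
    report["overlaps"] = overlaps

    # cluster the union of q-significant, well-annotated metabolites over
    # biological samples (display stage of the analysis)
    union: set = set()
    for s in sets_q.values():
        union |= s
    levels = filtered.annotations["annotation_level"]
    annotated = set(levels.index[levels.isin(cfg.metabo_levels)])
    to_cluster = sorted(union & annotated)
    cluster = None
    bio_cols = [
        s for s in design.table.loc[
            design.table["role"] == "biological", "sample_id"
        ]
        if s in logm.sample_ids
    ]
    if len(to_cluster) >= 2:
        sub = AbundanceMatrix(
            logm.data.loc[to_cluster, bio_cols], scale="log2"
        )
        complete = sub.data.dropna(axis=0)
        varying = complete.index[complete.std(axis=1, ddof=1) > 0]
        if len(varying) >= 2:
            z = metabo_analysis.zscore_rows(
                AbundanceMatrix(complete.loc[varying], scale="log2")
            )
            cluster = metabo_analysis.pearson_average_linkage(z, axis="features")
    report["counts"]["clustered"] = 0 if cluster is None else len(cluster.labels)

    return {
        "results": results,
        "sets_p": sets_p,
        "sets_q": sets_q,
        "sets_q_fc": sets_q_fc,
        "cluster": cluster,
        "qc_report": qc_report,
        "report": report,
    }


def summarize_calls(calls: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Confusion summary of target calls against a synthetic truth table.

    Returns sensitivity for true specific binders, the rate at which
    nonspecific binders are miscalled specific, and the count of background
    features called specific (false discoveries).
    """
    merged = calls.merge(truth, on="feature_id", how="left")
    spec_true = merged["class"] == "specific"
    nonspec_true = merged["class"] == "nonspecific"
    bg = merged["class"] == "background"
    called_spec = merged["call"] == target_filter.CALL_SPECIFIC
    out = {
        "n_specific_true": int(spec_true.sum()),
        "n_nonspecific_true": int(nonspec_true.sum()),
        "sensitivity": float(
            (spec_true & called_spec).sum() / max(1, spec_true.sum())
        ),
        "nonspecific_as_specific_rate": float(
            (nonspec_true & called_spec).sum() / max(1, nonspec_true.sum())
        ),
        "background_called_specific": int((bg & called_spec).sum()),
    }
    return out
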
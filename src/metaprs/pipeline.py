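"""End-to-end orchestration: synthetic cohort -> QC -> PCs -> per-trait PRS
series -> optimal-threshold selection -> Cox screen -> elastic-net metaPRS
-> evaluation tables.

This is thin plumbing over the analysis modules; it exists so the CLI, the
numbered analysis scripts and the determinism checks all run the identical
code path.  All outputs are plain TSV and are byte-reproducible under a
fixed (config, seed).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import (
    baseline_table,
    compare_models,
    confusion_at_cutoff,
    group_hazard_ratios,
    stratify_quartiles,
    youden_cutoff,
)
from .io_formats import write_model
from .metaprs_pipeline import (
    MetaPrsModel,
    OptimalPrsSet,
    apply_metaprs,
    attach_pcs,
    build_metaprs,
    screen_prs,
    select_optimal_prs,
)
from .prs_engine import ClumpParams, build_prs_series, harmonize_alleles, threshold_grid
from .quality_control import QcThresholds, apply_qc
from .survival_core import km_curve
from .synthetic_cohort import SimConfig, simulate_cohort

__all__ = ["PipelineParams", "PipelineResult", "run_pipeline", "write_outputs"]


@dataclass(frozen=True)
class PipelineParams:
    qc: QcThresholds = QcThresholds()
    clump: ClumpParams = ClumpParams()
    p_min: float = 5e-8
    p_max: float = 0.5
    n_steps: int = 500
    screen_p_cut: float = 0.1
    alpha: float = 0.5
    folds: int = 5
    n_lambda: int = 100
    horizon: float | None = None
    n_pcs: int = 10


@dataclass
class PipelineResult:
    panel: object
    frame: object
    truth: object
    qc_report: object
    optimal: OptimalPrsSet
    survivors: list[str]
    metaprs: MetaPrsModel | None
    metaprs_scores: np.ndarray | None
    groups: object | None
    group_fit: object | None
    auc_table: pd.DataFrame | None
    confusion: object | None
    baseline: pd.DataFrame | None
    per_trait: pd.DataFrame = field(default=None)


def run_pipeline(
    config: SimConfig, params: PipelineParams = PipelineParams()
) -> PipelineResult:
    panel, stats_list, frame, truth = simulate_cohort(config)
    panel, qc_report = apply_qc(panel, params.qc)
    frame = frame.align_to(panel.sample_ids)
    frame = attach_pcs(frame, panel, k=params.n_pcs)

    grid = threshold_grid(params.p_min, params.p_max, params.n_steps)
    series = {}
    for stats in stats_list:
        aligned, _ = harmonize_alleles(stats, panel)
        series[stats.trait_name] = build_prs_series(
            aligned, panel, params.clump, grid
        )
    optimal = select_optimal_prs(series, frame)
    survivors = screen_prs(optimal, frame, params.screen_p_cut)

    rows = []
    for trait, entry in optimal.entries.items():
        fit = entry.cox
        rows.append(
            (trait, entry.model.p_threshold, entry.model.n_variants,
             entry.nagelkerke_r2, fit.hr[0], fit.ci[0][0], fit.ci[1][0],
             fit.p[0], trait in survivors)
        )
    per_trait = pd.DataFrame(
        rows,
        columns=["trait", "p_threshold", "n_variants", "nagelkerke_r2",
                 "hr_per_sd", "ci_low", "ci_high", "cox_p", "screened_in"],
    )

    result = PipelineResult(
        panel=panel, frame=frame, truth=truth, qc_report=qc_report,
        optimal=optimal, survivors=survivors, metaprs=None,
        metaprs_scores=None, groups=None, group_fit=None, auc_table=None,
        confusion=None, baseline=None, per_trait=per_trait,
    )
    if len(survivors) < 2:
        return result

    meta = build_metaprs(
        optimal, survivors, frame, panel, alpha=params.alpha,
        folds=params.folds, seed=config.seed, horizon=params.horizon,
        n_lambda=params.n_lambda,
    )
    scores = apply_metaprs(meta, panel)
    groups = stratify_quartiles(scores)
    group_fit = group_hazard_ratios(frame, groups)

    horizon = params.horizon or float(np.median(frame.time))
    model_specs = {
        "age": frame.data["age"].to_numpy(float),
        "sex": frame.data["sex"].to_numpy(float),
        "smoking": frame.data["smoking"].to_numpy(float),
        "metaPRS": scores,
        "clinical": ["age", "sex", "smoking"],
        "combined": None,
    }
    aug = frame.with_columns({"metaPRS": scores})
    model_specs["combined"] = ["age", "sex", "smoking", "metaPRS"]
    auc_table = compare_models(aug, model_specs, horizon)

    cutoff = youden_cutoff(scores, frame.event)
    confusion = confusion_at_cutoff(scores, frame.event, cutoff)
    baseline = baseline_table(
        frame,
        continuous_vars=["age"],
        categorical_vars=["sex", "smoking", "PPI", "ACEI", "BB", "CCB"],
        test_plan={"age": "t_test_pooled"},
    )

    result.metaprs = meta
    result.metaprs_scores = scores
    result.groups = groups
    result.group_fit = group_fit
    result.auc_table = auc_table
    result.confusion = confusion
    result.baseline = baseline
    return result


def _fmt(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_outputs(result: PipelineResult, out_dir: str) -> list[str]:
    """Write every pipeline table as TSV; returns the file list."""
    os.makedirs(out_dir, exist_ok=True)
    written = []

    def emit(df: pd.DataFrame, name: str) -> None:
        path = os.path.join(out_dir, name)
        _fmt(df, path)
        written.append(path)

    emit(result.qc_report.to_frame(), "qc_report.tsv")
    emit(result.per_trait, "per_trait_prs.tsv")
    if result.metaprs is not None:
        write_model(result.metaprs, os.path.join(out_dir, "metaprs_model.tsv"))
        written.append(os.path.join(out_dir, "metaprs_model.tsv"))
        emit(
            pd.DataFrame(
                {"sample_id": result.panel.sample_ids,
                 "metaprs": result.metaprs_scores,
                 "risk_group": result.groups.labels}
            ),
            "risk_groups.tsv",
        )
        emit(result.group_fit.summary().reset_index(names="term"),
             "group_hazard_ratios.tsv")
        emit(result.auc_table, "auc_table.tsv")
        c = result.confusion
        emit(
            pd.DataFrame(
                [{"tn": c.tn, "fn": c.fn, "fp": c.fp, "tp": c.tp,
                  "cutoff": c.cutoff,
                  "sensitivity_pct": c.sensitivity_pct,
                  "specificity_pct": c.specificity_pct}]
            ),
            "confusion.tsv",
        )
        emit(result.baseline, "baseline_table.tsv")
        km = km_curve(result.frame.time, result.frame.event)
        emit(
            pd.DataFrame(
                {"time": km.times, "survival": km.survival,
                 "cumulative_incidence": km.cumulative_incidence,
                 "at_risk": km.at_risk, "n_events": km.n_events}
            ),
            "km_overall.tsv",
        )
    return written
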
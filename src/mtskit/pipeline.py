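"""End-to-end orchestration: prune, refine, screen, threshold, evaluate.

Stage order: drop incomplete rows in both groups; prune correlated
variables on the healthy group and apply the same selection to the
abnormal group; refine the healthy reference space by XmR outlier
screening; run the orthogonal-array screening experiment (healthy
survivors vs abnormal) and keep the positive-gain variables; refit the
space on the selected variables; set the operating threshold at the
Youden optimum of the training ROC; optionally cross-validate the whole
procedure.  Deterministic given inputs and config.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_config import FeatureTable, Group, RunConfig
from .mahalanobis import (
    MahalanobisSpace,
    RefinementResult,
    compute_md,
    fit_space,
    refine_space,
)
from .preprocess import CorrelationPruneReport, drop_incomplete_rows, pearson_prune
from .taguchi import SNTable, generate_oa, run_oa_experiment, select_variables
from .threshold import ROCCurve, classify, kfold_evaluate, roc_curve

logger = logging.getLogger("mtskit")

__all__ = ["TrainedModel", "PipelineResult", "fit_diagnostic", "run_full_pipeline"]


@dataclass
class TrainedModel:
    """Everything needed to score and classify new subjects."""

    selected_variables: list[str]
    space: MahalanobisSpace
    threshold: float
    scaled: bool
    roc: ROCCurve
    prune_report: CorrelationPruneReport
    refinement: RefinementResult
    sn_table: SNTable
    selection_fallback: bool = False

    def score(self, table: FeatureTable) -> np.ndarray:
        return compute_md(self.space, table, scaled=self.scaled).values

    def classify(self, table: FeatureTable) -> np.ndarray:
        return classify(self.score(table), self.threshold)


@dataclass
class PipelineResult:
    """Full audit of one training run, serializable via ``write_report``."""

    n_normal_in: int
    n_abnormal_in: int
    n_missing_removed_normal: int
    n_missing_removed_abnormal: int
    prune_report: CorrelationPruneReport
    refinement: RefinementResult
    sn_table: SNTable
    selected_variables: list[str]
    selection_fallback: bool
    final_space_variables: list[str]
    threshold: float
    roc_auc: float
    se_at_youden: float
    sp_at_youden: float
    cv: dict | None = None

    def to_dict(self) -> dict:
        return {
            "counts": {
                "n_normal_in": self.n_normal_in,
                "n_abnormal_in": self.n_abnormal_in,
                "n_missing_removed_normal": self.n_missing_removed_normal,
                "n_missing_removed_abnormal": self.n_missing_removed_abnormal,
            },
            "prune": self.prune_report.to_dict(),
            "refinement": self.refinement.to_dict(),
            "sn": self.sn_table.to_dict(),
            "selected_variables": list(self.selected_variables),
            "selection_fallback": self.selection_fallback,
            "final_space_variables": list(self.final_space_variables),
            "threshold": self.threshold,
            "roc": {
                "auc": self.roc_auc,
                "se_at_youden": self.se_at_youden,
                "sp_at_youden": self.sp_at_youden,
            },
            "cv": self.cv,
        }


def fit_diagnostic(
    normal: FeatureTable,
    abnormal: FeatureTable,
    config: RunConfig | None = None,
) -> TrainedModel:
    """Train the full diagnostic on one (normal, abnormal) split."""
    config = config or RunConfig()
    normal, n_rm_n = _complete(normal)
    abnormal, n_rm_a = _complete(abnormal)
    logger.info("missing-row removal: %d normal, %d abnormal", n_rm_n, n_rm_a)

    pruned_normal, prune_report = pearson_prune(
        normal, config.correlation_threshold, config.reserved_variables
    )
    variables = pruned_normal.variable_names
    pruned_abnormal = abnormal.select(variables)
    logger.info("pruning: %d -> %d variables", normal.n_variables, len(variables))

    _, refinement = refine_space(
        pruned_normal,
        variables,
        max_passes=config.refinement_max_passes,
        condition_bound=config.condition_bound,
        scaled=config.scaled,
    )
    survivors = _without_rows(pruned_normal, refinement.removed_indices)
    logger.info(
        "refinement: removed %d of %d healthy subjects (T=%.4f)",
        refinement.n_removed, pruned_normal.n_subjects, refinement.threshold_T,
    )

    oa = generate_oa(len(variables))
    sn_table = run_oa_experiment(
        survivors, pruned_abnormal, oa, variables,
        scaled=config.scaled, condition_bound=config.condition_bound,
    )
    selected = select_variables(sn_table)
    fallback = False
    if not selected:
        warnings.warn(
            "empty variable selection; falling back to all pruned variables",
            stacklevel=2,
        )
        selected = list(variables)
        fallback = True
    logger.info("selection: %d of %d variables", len(selected), len(variables))

    final_space = fit_space(survivors, selected, config.condition_bound)
    md_normal = compute_md(final_space, survivors, scaled=config.scaled)
    md_abnormal = compute_md(final_space, pruned_abnormal, scaled=config.scaled)
    roc = roc_curve(md_normal, md_abnormal)
    if roc.auc < 0.6:
        warnings.warn(
            f"little separation between groups (training AUC {roc.auc:.3f})",
            stacklevel=2,
        )
    logger.info(
        "threshold %.4f (AUC %.4f, Se %.3f, Sp %.3f)",
        roc.youden_threshold, roc.auc, roc.se_at_youden, roc.sp_at_youden,
    )

    return TrainedModel(
        selected_variables=selected,
        space=final_space,
        threshold=roc.youden_threshold,
        scaled=config.scaled,
        roc=roc,
        prune_report=prune_report,
        refinement=refinement,
        sn_table=sn_table,
        selection_fallback=fallback,
    )


def run_full_pipeline(
    normal: FeatureTable,
    abnormal: FeatureTable,
    config: RunConfig | None = None,
    cross_validate: bool = False,
) -> tuple[TrainedModel, PipelineResult]:
    """Train on the full data and assemble the audit report.

    With ``cross_validate``, additionally runs the seeded group-stratified
    k-fold evaluation of the entire training procedure.
    """
    config = config or RunConfig()
    n_in, a_in = normal.n_subjects, abnormal.n_subjects
    complete_n, rm_n = _complete(normal)
    complete_a, rm_a = _complete(abnormal)
    model = fit_diagnostic(complete_n, complete_a, config)
    cv = None
    if cross_validate:
        cv = kfold_evaluate(complete_n, complete_a, config)
    result = PipelineResult(
        n_normal_in=n_in,
        n_abnormal_in=a_in,
        n_missing_removed_normal=rm_n,
        n_missing_removed_abnormal=rm_a,
        prune_report=model.prune_report,
        refinement=model.refinement,
        sn_table=model.sn_table,
        selected_variables=model.selected_variables,
        selection_fallback=model.selection_fallback,
        final_space_variables=model.space.variable_names,
        threshold=model.threshold,
        roc_auc=model.roc.auc,
        se_at_youden=model.roc.se_at_youden,
        sp_at_youden=model.roc.sp_at_youden,
        cv=cv,
    )
    return model, result


def _complete(table: FeatureTable) -> tuple[FeatureTable, int]:
    if table.has_missing():
        return drop_incomplete_rows(table)
    return table, 0


def _without_rows(table: FeatureTable, positions: list[int]) -> FeatureTable:
    if not positions:
        return table
    keep = np.setdiff1d(np.arange(table.n_subjects), np.asarray(positions))
    return FeatureTable(table.data.iloc[keep].copy(), table.group)
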
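"""ROC analysis of Mahalanobis distances and threshold-based classification.

The diagnostic rule is one-dimensional: a subject is called abnormal when
its MD strictly exceeds a threshold.  The operating threshold is picked at
the ROC point maximizing the Youden index J = sensitivity + specificity - 1,
with ties broken toward the smallest threshold (favoring sensitivity).
AUC is computed by the trapezoidal rule and cross-checked internally
against the Mann-Whitney rank statistic (ties half-weighted); disagreement
beyond round-off raises, since the two must coincide for a step ROC curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .exceptions import ContractError, NumericError
from .io_config import FeatureTable, Group, RunConfig
from .mahalanobis import MDSeries

__all__ = [
    "ROCCurve",
    "EvalMetrics",
    "roc_curve",
    "classify",
    "evaluate",
    "kfold_evaluate",
]


@dataclass
class ROCCurve:
    """ROC over MD scores: operating points, AUC, and the Youden optimum.

    ``thresholds`` is descending; ``tpr``/``fpr`` are the sensitivity and
    false-positive rate of the rule "abnormal iff MD > threshold" at each
    threshold, hence non-decreasing along the array.  ``degenerate`` is
    set when all pooled scores are identical, in which case the Youden
    threshold is undefined (NaN) and AUC is 0.5.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    youden_threshold: float
    se_at_youden: float
    sp_at_youden: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "youden_threshold": self.youden_threshold,
            "se_at_youden": self.se_at_youden,
            "sp_at_youden": self.sp_at_youden,
            "degenerate": self.degenerate,
            "thresholds": self.thresholds.tolist(),
            "tpr": self.tpr.tolist(),
            "fpr": self.fpr.tolist(),
        }


@dataclass
class EvalMetrics:
    """Confusion counts with sensitivity (TPR) and specificity (TNR)."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def n_abnormal(self) -> int:
        return self.tp + self.fn

    @property
    def n_normal(self) -> int:
        return self.tn + self.fp

    @property
    def sensitivity(self) -> float:
        return self.tp / self.n_abnormal

    @property
    def specificity(self) -> float:
        return self.tn / self.n_normal

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
            "n_normal": self.n_normal, "n_abnormal": self.n_abnormal,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
        }


def _scores(series: MDSeries | np.ndarray) -> np.ndarray:
    values = series.values if isinstance(series, MDSeries) else np.asarray(series, dtype=float)
    return np.asarray(values, dtype=float).ravel()


def _auc_rank(normal: np.ndarray, abnormal: np.ndarray) -> float:
    """Mann-Whitney AUC: P(abnormal > normal) + 0.5 P(tie), via ranks."""
    pooled = np.concatenate([abnormal, normal])
    ranks = rankdata(pooled)
    n1, n0 = abnormal.size, normal.size
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_curve(md_normal: MDSeries | np.ndarray, md_abnormal: MDSeries | np.ndarray) -> ROCCurve:
    """ROC curve of the rule "abnormal iff MD > t" over candidate thresholds.

    Candidate thresholds are the midpoints between consecutive sorted
    unique pooled scores plus one sentinel below the minimum and one above
    the maximum, so both trivial operating points appear.
    """
    normal = _scores(md_normal)
    abnormal = _scores(md_abnormal)
    if normal.size == 0 or abnormal.size == 0:
        raise ContractError("both score series must be non-empty")

    uniq = np.unique(np.concatenate([normal, abnormal]))
    if uniq.size == 1:
        warnings.warn("all scores identical; ROC is degenerate", stacklevel=2)
        t = np.array([uniq[0] + 1.0, uniq[0] - 1.0])
        return ROCCurve(
            thresholds=t,
            tpr=np.array([0.0, 1.0]),
            fpr=np.array([0.0, 1.0]),
            auc=0.5,
            youden_threshold=float("nan"),
            se_at_youden=float("nan"),
            sp_at_youden=float("nan"),
            degenerate=True,
        )

    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate([[uniq[-1] + 1.0], mids[::-1], [uniq[0] - 1.0]])
    tpr = (abnormal[None, :] > thresholds[:, None]).mean(axis=1)
    fpr = (normal[None, :] > thresholds[:, None]).mean(axis=1)

    auc = float(np.trapezoid(tpr, fpr))
    auc_rank = _auc_rank(normal, abnormal)
    if abs(auc - auc_rank) > 1e-9:
        raise NumericError(
            f"trapezoidal AUC {auc} disagrees with rank AUC {auc_rank}"
        )

    j = tpr - fpr
    jmax = j.max()
    # Ties at the maximum J: smallest threshold = last index (descending order).
    best = np.nonzero(j == jmax)[0][-1]
    return ROCCurve(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        youden_threshold=float(thresholds[best]),
        se_at_youden=float(tpr[best]),
        sp_at_youden=float(1.0 - fpr[best]),
    )


def classify(md: MDSeries | np.ndarray, threshold: float) -> np.ndarray:
    """Label each score: abnormal iff MD strictly exceeds ``threshold``."""
    if not np.isfinite(threshold):
        raise ContractError("threshold must be finite")
    scores = _scores(md)
    return np.where(scores > threshold, Group.ABNORMAL.value, Group.NORMAL.value)


def evaluate(predictions: np.ndarray, truth: np.ndarray) -> EvalMetrics:
    """Confusion counts of predicted vs true normal/abnormal labels."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise ContractError("predictions and truth differ in length")
    abn, nor = Group.ABNORMAL.value, Group.NORMAL.value
    if not ((truth == abn).any() and (truth == nor).any()):
        raise ContractError("truth must contain both classes")
    tp = int(((predictions == abn) & (truth == abn)).sum())
    fn = int(((predictions == nor) & (truth == abn)).sum())
    tn = int(((predictions == nor) & (truth == nor)).sum())
    fp = int(((predictions == abn) & (truth == nor)).sum())
    return EvalMetrics(tp=tp, fn=fn, tn=tn, fp=fp)


def _fold_indices(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, folds)]


def kfold_evaluate(
    normal: FeatureTable,
    abnormal: FeatureTable,
    config: RunConfig,
) -> dict:
    """Group-stratified k-fold evaluation of the full diagnostic pipeline.

    Each group is independently partitioned into ``config.cv_folds``
    near-equal folds by the seeded RNG.  Per fold, the entire training
    procedure (prune, refine, OA selection, threshold) runs on the other
    folds only, and the held-out subjects are classified at the trained
    threshold.  Folds whose training fails (too few subjects to fit a
    space) are skipped with a warning.

    Returns per-fold metrics, their means, and the pooled confusion.
    """
    from .pipeline import fit_diagnostic  # local import to avoid a cycle

    folds = config.cv_folds
    if normal.n_subjects <= folds or abnormal.n_subjects <= folds:
        raise ContractError("each group must contain more subjects than folds")
    rng = np.random.default_rng(config.rng_seed)
    normal_folds = _fold_indices(normal.n_subjects, folds, rng)
    abnormal_folds = _fold_indices(abnormal.n_subjects, folds, rng)

    per_fold: list[dict] = []
    pooled = EvalMetrics(0, 0, 0, 0)
    for f in range(folds):
        n_test, a_test = normal_folds[f], abnormal_folds[f]
        n_train = np.setdiff1d(np.arange(normal.n_subjects), n_test)
        a_train = np.setdiff1d(np.arange(abnormal.n_subjects), a_test)
        train_n = FeatureTable(normal.data.iloc[n_train].copy(), normal.group)
        train_a = FeatureTable(abnormal.data.iloc[a_train].copy(), abnormal.group)
        test_n = FeatureTable(normal.data.iloc[n_test].copy(), normal.group)
        test_a = FeatureTable(abnormal.data.iloc[a_test].copy(), abnormal.group)
        try:
            model = fit_diagnostic(train_n, train_a, config)
        except Exception as exc:  # fold too small / degenerate
            warnings.warn(f"fold {f}: training failed ({exc}); skipped", stacklevel=2)
            per_fold.append({"fold": f, "skipped": True, "reason": str(exc)})
            continue
        test_n_c, _ = _complete(test_n)
        test_a_c, _ = _complete(test_a)
        preds = np.concatenate([
            model.classify(test_a_c),
            model.classify(test_n_c),
        ])
        truth = np.concatenate([
            np.full(test_a_c.n_subjects, Group.ABNORMAL.value),
            np.full(test_n_c.n_subjects, Group.NORMAL.value),
        ])
        metrics = evaluate(preds, truth)
        pooled = EvalMetrics(
            pooled.tp + metrics.tp, pooled.fn + metrics.fn,
            pooled.tn + metrics.tn, pooled.fp + metrics.fp,
        )
        per_fold.append({
            "fold": f,
            "skipped": False,
            "metrics": metrics.to_dict(),
            "threshold": model.threshold,
            "selected_variables": list(model.selected_variables),
        })
    done = [p for p in per_fold if not p["skipped"]]
    return {
        "folds": per_fold,
        "mean_sensitivity": float(np.mean([p["metrics"]["sensitivity"] for p in done])) if done else float("nan"),
        "mean_specificity": float(np.mean([p["metrics"]["specificity"] for p in done])) if done else float("nan"),
        "pooled": pooled.to_dict() if done else None,
    }


def _complete(table: FeatureTable) -> tuple[FeatureTable, int]:
    from .preprocess import drop_incomplete_rows

    if table.has_missing():
        return drop_incomplete_rows(table)
    return table, 0
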
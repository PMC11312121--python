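"""Liver-level aggregation of patch votes, and evaluation metrics.

A liver is called non-valid when at least a configurable fraction
(default 20 %) of its patches are classified non-valid. The continuous
fraction of non-valid patches doubles as the liver-level score for ROC
analysis. The positive class throughout is ``non_valid`` (steatosis
above threshold).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn import metrics as _skm
from sklearn.inspection import permutation_importance

VALID, NON_VALID = 0, 1


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class AggregationConfig:
    """Fraction-of-patches decision rule; the boundary is inclusive."""

    fraction_threshold: float = 0.20

    def __post_init__(self) -> None:
        if not 0 < self.fraction_threshold <= 1:
            raise EvaluationError("fraction_threshold must be in (0, 1]")


@dataclass
class LiverPrediction:
    case_id: str
    n_patches: int
    n_non_valid: int
    fraction: float
    decision: int  # VALID or NON_VALID
    patch_scores: Optional[np.ndarray] = None


@dataclass
class Metrics:
    accuracy: float
    precision: Optional[float]  # None when no positive predictions
    recall: float
    tp: int
    fp: int
    fn: int
    tn: int


def aggregate(
    patch_labels: Sequence[int],
    cfg: AggregationConfig = AggregationConfig(),
    case_id: str = "",
    patch_scores: Optional[np.ndarray] = None,
) -> LiverPrediction:
    """Fraction-of-non-valid-patches vote: non-valid iff fraction >= threshold."""
    labels = np.asarray(patch_labels, dtype=int)
    if labels.size == 0:
        raise EvaluationError("cannot aggregate zero patches")
    n_nv = int((labels == NON_VALID).sum())
    fraction = n_nv / labels.size
    decision = NON_VALID if fraction >= cfg.fraction_threshold else VALID
    return LiverPrediction(
        case_id=case_id,
        n_patches=int(labels.size),
        n_non_valid=n_nv,
        fraction=float(fraction),
        decision=decision,
        patch_scores=patch_scores,
    )


def metrics(decisions: Sequence[int], truths: Sequence[int]) -> Metrics:
    """Accuracy, precision and recall with ``non_valid`` as positive class."""
    d = np.asarray(decisions, dtype=int)
    t = np.asarray(truths, dtype=int)
    if d.size == 0 or d.size != t.size:
        raise EvaluationError("decisions and truths must be equal-length, non-empty")
    tp = int(((d == NON_VALID) & (t == NON_VALID)).sum())
    fp = int(((d == NON_VALID) & (t == VALID)).sum())
    fn = int(((d == VALID) & (t == NON_VALID)).sum())
    tn = int(((d == VALID) & (t == VALID)).sum())
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    return Metrics(
        accuracy=(tp + tn) / d.size,
        precision=precision,
        recall=recall,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
    )


def roc_auc(
    scores: Sequence[float], truths: Sequence[int]
) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) and trapezoidal AUC of the liver scores.

    The trapezoidal area equals the pairwise probability
    ``P(score_pos > score_neg) + 0.5 * P(tie)``.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truths, dtype=int)
    if len(np.unique(t)) < 2:
        raise EvaluationError("ROC needs both classes present")
    fpr, tpr, _ = _skm.roc_curve(t, s, pos_label=NON_VALID, drop_intermediate=False)
    auc = float(_skm.auc(fpr, tpr))
    return np.column_stack([fpr, tpr]), auc


def bootstrap_ci(
    metric_fn: Callable[[np.ndarray, np.ndarray], Optional[float]],
    decisions: Sequence[int],
    truths: Sequence[int],
    B: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Case-level percentile bootstrap CI for a metric.

    Resamples are drawn over cases; resamples where the metric is
    undefined (``None``/NaN) are dropped, and more than 50 % undefined is
    an error.
    """
    d = np.asarray(decisions)
    t = np.asarray(truths)
    if B < 1:
        raise EvaluationError("B must be >= 1")
    rng = np.random.default_rng(seed)
    n = d.size
    vals = []
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        v = metric_fn(d[idx], t[idx])
        if v is not None and np.isfinite(v):
            vals.append(v)
    if len(vals) < B / 2:
        raise EvaluationError("metric undefined in more than half of the resamples")
    alpha = (1 - level) / 2
    lo, hi = np.quantile(vals, [alpha, 1 - alpha])
    return float(lo), float(hi)


def mcnemar(
    model_correct: Sequence[bool], surgeon_correct: Sequence[bool]
) -> float:
    """Exact two-sided McNemar test on paired correctness flags.

    Only discordant pairs inform the test: with ``b`` cases the model
    alone got right and ``c`` the comparator alone got right,
    ``p = min(1, 2 * P(X <= min(b, c)))`` for ``X ~ Binomial(b+c, 1/2)``.
    """
    m = np.asarray(model_correct, dtype=bool)
    s = np.asarray(surgeon_correct, dtype=bool)
    if m.size != s.size:
        raise EvaluationError("paired flags must have equal length")
    b = int((m & ~s).sum())
    c = int((~m & s).sum())
    n = b + c
    if n == 0:
        return 1.0
    p = 2 * stats.binom.cdf(min(b, c), n, 0.5)
    return float(min(1.0, p))


def importance_report(
    model,
    X_val: np.ndarray,
    y_val: np.ndarray,
    feature_names: Sequence[str],
    seed: int = 0,
    n_repeats: int = 10,
) -> dict[str, list[tuple[str, float]]]:
    """Feature rankings by impurity decrease and by permutation.

    ``model`` is a fitted scikit-learn estimator. The impurity ranking
    requires a forest (``feature_importances_``); the permutation ranking
    (mean AUC drop when one column is shuffled, averaged over
    ``n_repeats`` shuffles) works for any scoring model.
    """
    report: dict[str, list[tuple[str, float]]] = {}
    names = list(feature_names)
    if hasattr(model, "feature_importances_"):
        imp = np.asarray(model.feature_importances_)
        order = np.argsort(imp)[::-1]
        report["impurity"] = [(names[i], float(imp[i])) for i in order]
    perm = permutation_importance(
        model, X_val, y_val, n_repeats=n_repeats, random_state=seed,
        scoring="roc_auc",
    )
    order = np.argsort(perm.importances_mean)[::-1]
    report["permutation"] = [
        (names[i], float(perm.importances_mean[i])) for i in order
    ]
    return report


def require_impurity(model) -> None:
    if not hasattr(model, "feature_importances_"):
        raise EvaluationError("impurity ranking requires a forest model")
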
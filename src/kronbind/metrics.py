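"""Scoring metrics for quantitative pKd predictions and activity classes.

The six challenge-style regression metrics are RMSE, Pearson, Spearman,
concordance index (CI), F1 at a pKd > 7 binarization, and an averaged
ROC-AUC over ten binarization thresholds spanning the measured pKd
interval [6, 8].  Classification analyses (single-dose assay vs model
predictions) add confusion-matrix summaries (PPV, FDR, sensitivity,
specificity) and ROC/PR curves.

Note on balanced accuracy: the convention used here for challenge-style
reports is the arithmetic mean of precision and recall; the conventional
mean of sensitivity and specificity is exposed separately as
``balanced_accuracy_conventional`` to avoid silent divergence.

Note on PPV/FDR: under the standard definitions FDR = 1 - PPV whenever
any positive is predicted; published pairings that violate this identity
(e.g. PPV 0.66 with FDR 0.44) cannot arise from a single confusion
matrix and are not reproduced here — this module always reports the
self-consistent pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats
from sklearn.metrics import (
    auc as _auc,
    f1_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

from .io import InteractionTable, PredictionSet

__all__ = [
    "ScoreReport",
    "ClassificationSpec",
    "ConfusionSummary",
    "CurveSet",
    "score_report",
    "concordance_index",
    "average_auc",
    "classification_summary",
    "curves",
    "F1_CUTOFF",
    "AVG_AUC_THRESHOLDS",
]

#: binarization cutoff for the F1 component of the score report
F1_CUTOFF = 7.0

#: ten evenly spaced binarization thresholds spanning pKd in [6, 8]
AVG_AUC_THRESHOLDS = np.linspace(6.0, 8.0, 10)


@dataclass(frozen=True)
class ScoreReport:
    """The six challenge metrics for one prediction set."""

    rmse: float
    pearson: float
    spearman: float
    ci: float
    f1: float
    avg_auc: float

    def to_dict(self) -> dict[str, float]:
        return {
            "rmse": self.rmse,
            "pearson": self.pearson,
            "spearman": self.spearman,
            "ci": self.ci,
            "f1": self.f1,
            "avg_auc": self.avg_auc,
        }


@dataclass(frozen=True)
class ClassificationSpec:
    """Cutoffs for activity classification.

    ``truth_cutoff``: measured pKd above which a pair is truly active
    (6 or 7 in practice).  ``pred_cutoff``: predicted-pKd cutoff for the
    by-prediction mode.  ``inhibition_cutoff``: single-dose %inhibition
    cutoff for the by-inhibition mode (80% is the two-step screening
    convention).  All comparisons are strict (> cutoff); ties at the
    cutoff are negative.
    """

    truth_cutoff: float = 6.0
    pred_cutoff: float = 6.0
    inhibition_cutoff: float = 80.0

    def __post_init__(self) -> None:
        for name in ("truth_cutoff", "pred_cutoff", "inhibition_cutoff"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class ConfusionSummary:
    """Confusion-matrix counts and derived rates.

    ``ppv`` is ``nan`` (and ``ppv_defined`` False) when nothing is
    predicted positive; otherwise ``fdr = 1 - ppv`` by construction.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    ppv: float
    fdr: float
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    balanced_accuracy_conventional: float

    @property
    def ppv_defined(self) -> bool:
        return not math.isnan(self.ppv)

    def to_dict(self) -> dict[str, float]:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "ppv": self.ppv, "fdr": self.fdr,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy,
            "balanced_accuracy_conventional": self.balanced_accuracy_conventional,
        }


@dataclass(frozen=True)
class CurveSet:
    """ROC and PR curves with their areas and the positive prevalence."""

    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    roc_auc: float
    pr_recall: np.ndarray
    pr_precision: np.ndarray
    pr_auc: float
    prevalence: float


def _aligned(pred: PredictionSet, measured: InteractionTable):
    pairs = measured.pairs()
    missing = [p for p in pairs if p not in pred.entries]
    if missing:
        raise KeyError(f"prediction set missing measured pairs, e.g. {missing[:3]}")
    y_pred = pred.values_for(pairs)
    y_true = measured.frame["pkd"].to_numpy(dtype=float)
    return y_pred, y_true


def score_report(pred: PredictionSet, measured: InteractionTable) -> ScoreReport:
    """Compute the six challenge metrics for one prediction set.

    Requires >= 2 pairs; Pearson/Spearman raise if either vector has
    zero variance (correlation undefined).  Spearman uses average ranks
    for ties; F1 binarizes both vectors at pKd > 7.
    """
    y_pred, y_true = _aligned(pred, measured)
    n = len(y_true)
    if n < 2:
        raise ValueError(f"scoring needs >= 2 pairs, got {n}")
    if np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        raise ValueError("zero-variance vector: correlation undefined")
    rmse = float(np.sqrt(np.mean((y_pred - y_true) ** 2)))
    pearson = float(stats.pearsonr(y_pred, y_true).statistic)
    spearman = float(stats.spearmanr(y_pred, y_true).statistic)
    ci = concordance_index(pred, measured)
    f1 = float(
        f1_score(y_true > F1_CUTOFF, y_pred > F1_CUTOFF, zero_division=0.0)
    )
    avg = average_auc(pred, measured)
    return ScoreReport(rmse, pearson, spearman, ci, f1, avg)


def concordance_index(pred: PredictionSet, measured: InteractionTable) -> float:
    """Probability that two pairs with different measured pKd are ranked
    in the correct order by the predictions.

    Over all pair-of-pairs with distinct measured values: concordant
    counts 1, a tied prediction 0.5, discordant 0; CI is the mean.
    """
    y_pred, y_true = _aligned(pred, measured)
    return _ci_from_arrays(y_pred, y_true)


def _ci_from_arrays(y_pred: np.ndarray, y_true: np.ndarray) -> float:
    dt = y_true[:, None] - y_true[None, :]
    dp = y_pred[:, None] - y_pred[None, :]
    comparable = dt > 0  # each unordered pair counted once, oriented
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise ValueError("all measured values equal: concordance undefined")
    concordant = (dp > 0) & comparable
    tied = (dp == 0) & comparable
    return float((concordant.sum() + 0.5 * tied.sum()) / n_comp)


def average_auc(pred: PredictionSet, measured: InteractionTable) -> float:
    """ROC-AUC of the predictions as a ranker, averaged over the ten
    binarization thresholds spanning measured pKd in [6, 8].

    Thresholds at which only one class is present are skipped; the mean
    is over the remaining thresholds.  Raises if every threshold is
    degenerate.  Invariant under strictly monotone transforms of the
    predictions (rank-based).
    """
    y_pred, y_true = _aligned(pred, measured)
    aucs = []
    for thr in AVG_AUC_THRESHOLDS:
        labels = y_true > thr
        if labels.all() or not labels.any():
            continue
        aucs.append(roc_auc_score(labels, y_pred))
    if not aucs:
        raise ValueError(
            "every binarization threshold has a single class: avg AUC undefined"
        )
    return float(np.mean(aucs))


def classification_summary(
    positive_scores: Mapping[tuple[str, str], float],
    measured: InteractionTable,
    spec: ClassificationSpec = ClassificationSpec(),
    mode: str = "by_prediction",
) -> ConfusionSummary:
    """Confusion summary of an activity classifier against measured pKd.

    Truth: measured pKd > ``spec.truth_cutoff``.  Predicted positive:
    score > ``spec.pred_cutoff`` (``mode='by_prediction'``, scores are
    predicted pKd) or score > ``spec.inhibition_cutoff``
    (``mode='by_inhibition'``, scores are single-dose %inhibition).
    When nothing is predicted positive, PPV/FDR are flagged undefined
    (nan) rather than raising.
    """
    if mode not in ("by_prediction", "by_inhibition"):
        raise ValueError(f"unknown mode {mode!r}")
    pairs = measured.pairs()
    missing = [p for p in pairs if p not in positive_scores]
    if missing:
        raise KeyError(f"scores missing for measured pairs, e.g. {missing[:3]}")
    scores = np.array([positive_scores[p] for p in pairs], dtype=float)
    y_true = measured.frame["pkd"].to_numpy(dtype=float) > spec.truth_cutoff
    cutoff = spec.pred_cutoff if mode == "by_prediction" else spec.inhibition_cutoff
    y_pos = scores > cutoff
    tp = int(np.sum(y_true & y_pos))
    fp = int(np.sum(~y_true & y_pos))
    tn = int(np.sum(~y_true & ~y_pos))
    fn = int(np.sum(y_true & ~y_pos))
    ppv = tp / (tp + fp) if (tp + fp) > 0 else math.nan
    fdr = 1.0 - ppv if (tp + fp) > 0 else math.nan
    sens = tp / (tp + fn) if (tp + fn) > 0 else math.nan
    spec_ = tn / (tn + fp) if (tn + fp) > 0 else math.nan
    bal = (ppv + sens) / 2.0
    bal_conv = (sens + spec_) / 2.0
    return ConfusionSummary(tp, fp, tn, fn, ppv, fdr, sens, spec_, bal, bal_conv)


def curves(
    positive_scores: Mapping[tuple[str, str], float],
    measured: InteractionTable,
    truth_cutoff: float = 6.0,
) -> CurveSet:
    """ROC and PR curves ranking pairs by a positive score.

    Truth is measured pKd > ``truth_cutoff``; both classes must be
    present.  The PR baseline (random-ranker precision) equals the
    positive-class prevalence, reported alongside the curves.
    """
    pairs = measured.pairs()
    scores = np.array([positive_scores[p] for p in pairs], dtype=float)
    y_true = measured.frame["pkd"].to_numpy(dtype=float) > truth_cutoff
    if y_true.all() or not y_true.any():
        raise ValueError("both activity classes must be present for curves")
    fpr, tpr, _ = roc_curve(y_true, scores)
    roc_a = float(roc_auc_score(y_true, scores))
    precision, recall, _ = precision_recall_curve(y_true, scores)
    pr_a = float(_auc(recall, precision))
    return CurveSet(
        roc_fpr=fpr,
        roc_tpr=tpr,
        roc_auc=roc_a,
        pr_recall=recall,
        pr_precision=precision,
        pr_auc=pr_a,
        prevalence=float(y_true.mean()),
    )
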
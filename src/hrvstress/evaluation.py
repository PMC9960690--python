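"""Classification metrics, leave-one-subject-out and cross-dataset evaluation.

Metrics follow the stress-positive convention: TP are stress windows
classified as stress, FP non-stress windows classified as stress.  The
reported ROC AUC is the hard-label form ``(1 + TPR - FPR) / 2`` — which is
algebraically the balanced accuracy ``(TPR + TNR) / 2`` — with the rank-based
score AUC additionally logged as a diagnostic.  Aggregate LOSO metrics pool
confusion counts across folds rather than averaging per-fold metrics, so
folds whose test subject has a single class still contribute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from hrvstress.data_io import PipelineConfig, SchemaError, ValidationError
from hrvstress.modeling import (
    FitState,
    ModelSpec,
    encode_labels,
    feature_columns,
    fit_pipeline,
    predict_pipeline,
)

logger = logging.getLogger("hrvstress")


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with stress as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def swapped(self) -> "ConfusionCounts":
        """Counts with the positive/negative roles exchanged."""
        return ConfusionCounts(tp=self.tn, fp=self.fn, fn=self.fp, tn=self.tp)

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )


@dataclass
class MetricReport:
    """All reported scores for one evaluation (stress = positive class)."""

    counts: ConfusionCounts
    precision_stress: float
    recall_stress: float
    f1_stress: float
    precision_non_stress: float
    recall_non_stress: float
    f1_non_stress: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    specificity: float
    tpr: float
    fpr: float
    auc: float                       # hard-label (1 + TPR - FPR)/2
    score_auc: float = float("nan")  # rank-based AUC of continuous scores
    per_fold: pd.DataFrame | None = None

    def as_dict(self) -> dict:
        return {
            "f1": self.macro_f1,
            "specificity": self.specificity,
            "roc_auc": self.auc,
            "f1_stress": self.f1_stress,
            "f1_non_stress": self.f1_non_stress,
            "macro_recall": self.macro_recall,
            "macro_precision": self.macro_precision,
            "score_auc": self.score_auc,
        }


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("0/0 in %s: reporting 0", what)
        return 0.0
    return num / den


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Count TP/FP/FN/TN under the stress-positive convention.

    Accepts ``stress``/``non_stress`` strings or 1/0 codes; unequal lengths or
    labels outside the binary vocabulary raise.
    """
    t = encode_labels(y_true)
    p = encode_labels(y_pred)
    if t.shape != p.shape:
        raise ValidationError("y_true and y_pred must have equal length")
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        fp=int(np.sum((t == 0) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
        tn=int(np.sum((t == 0) & (p == 0))),
    )


def metric_report(counts: ConfusionCounts, score_auc: float = float("nan"),
                  per_fold: pd.DataFrame | None = None) -> MetricReport:
    """Derive every reported score from confusion counts.

    Per-class F1 is the harmonic mean of precision and recall; the non-stress
    class uses the label-swapped counts.  Macro scores are unweighted means
    over the two classes.  Any 0/0 denominator yields 0 with a warning.
    """
    def prf(c: ConfusionCounts, cls: str) -> tuple[float, float, float]:
        precision = _safe_div(c.tp, c.tp + c.fp, f"precision[{cls}]")
        recall = _safe_div(c.tp, c.tp + c.fn, f"recall[{cls}]")
        f1 = _safe_div(2 * precision * recall, precision + recall, f"f1[{cls}]")
        return precision, recall, f1

    p_s, r_s, f_s = prf(counts, "stress")
    p_n, r_n, f_n = prf(counts.swapped(), "non_stress")
    tpr = r_s
    fpr = _safe_div(counts.fp, counts.fp + counts.tn, "FPR")
    specificity = _safe_div(counts.tn, counts.tn + counts.fp, "specificity")
    return MetricReport(
        counts=counts,
        precision_stress=p_s, recall_stress=r_s, f1_stress=f_s,
        precision_non_stress=p_n, recall_non_stress=r_n, f1_non_stress=f_n,
        macro_precision=(p_s + p_n) / 2,
        macro_recall=(r_s + r_n) / 2,
        macro_f1=(f_s + f_n) / 2,
        specificity=specificity,
        tpr=tpr,
        fpr=fpr,
        auc=(1 + tpr - fpr) / 2,
        score_auc=score_auc,
        per_fold=per_fold,
    )


def loso_evaluate(
    dataset: pd.DataFrame,
    spec: ModelSpec,
    config: PipelineConfig | None = None,
) -> MetricReport:
    """Leave-one-subject-out evaluation of the full pipeline.

    One fold per subject: the pipeline (outlier filter, SMOTE, scaling, fit)
    is fitted on all other subjects' rows only, then scores the held-out
    subject.  Fold confusion counts are pooled into one report; per-fold
    breakdowns are kept for diagnostics.  Subjects with no labelled windows
    are skipped with a warning.
    """
    config = config or PipelineConfig()
    subjects = sorted(dataset["subject_id"].unique())
    if len(subjects) < 2:
        raise ValidationError("LOSO needs at least 2 subjects")
    pooled = ConfusionCounts(0, 0, 0, 0)
    fold_rows, all_scores, all_true = [], [], []
    for subject in subjects:
        test = dataset[dataset["subject_id"] == subject]
        train = dataset[dataset["subject_id"] != subject]
        if test.empty:
            logger.warning("subject %s has no labelled windows; skipped", subject)
            continue
        state = fit_pipeline(train, spec, config)
        y_pred, score = predict_pipeline(state, test)
        y_true = encode_labels(test["label"])
        c = confusion_counts(y_true, y_pred)
        pooled = pooled + c
        all_scores.append(score)
        all_true.append(y_true)
        fold = metric_report(c)
        fold_rows.append(
            (subject, c.tp, c.fp, c.fn, c.tn, fold.macro_f1, fold.auc)
        )
    per_fold = pd.DataFrame(
        fold_rows, columns=["subject_id", "tp", "fp", "fn", "tn", "macro_f1", "auc"]
    )
    y_true_all = np.concatenate(all_true)
    score_all = np.concatenate(all_scores)
    score_auc = (
        float(roc_auc_score(y_true_all, score_all))
        if np.unique(y_true_all).size == 2 else float("nan")
    )
    return metric_report(pooled, score_auc=score_auc, per_fold=per_fold)


def cross_dataset_evaluate(
    train_ds: pd.DataFrame,
    test_ds: pd.DataFrame,
    spec: ModelSpec,
    config: PipelineConfig | None = None,
) -> MetricReport:
    """Train on one dataset, evaluate on another (generalizability protocol).

    The pipeline is fitted once on the full training table with the same
    leakage-safe stage order as a LOSO fold, then applied to every row of the
    test table.  Requires matching feature registries and (by convention)
    disjoint subject identifier spaces.
    """
    config = config or PipelineConfig()
    if test_ds.empty:
        raise ValidationError("empty test table")
    if feature_columns(train_ds) != feature_columns(test_ds):
        raise SchemaError("train and test tables have different feature registries")
    overlap = set(train_ds["subject_id"]) & set(test_ds["subject_id"])
    if overlap:
        logger.warning("train/test subject id overlap: %s", sorted(overlap)[:5])
    state = fit_pipeline(train_ds, spec, config)
    y_pred, score = predict_pipeline(state, test_ds)
    y_true = encode_labels(test_ds["label"])
    c = confusion_counts(y_true, y_pred)
    score_auc = (
        float(roc_auc_score(y_true, score))
        if np.unique(y_true).size == 2 else float("nan")
    )
    return metric_report(c, score_auc=score_auc)
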
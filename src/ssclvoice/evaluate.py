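"""Diagnostic metrics, ROC analysis and the cross-validation harness.

Implements the eight confusion-matrix metrics used in the dysphonia study
(accuracy, recall/sensitivity, specificity, precision, F-score, Matthews
correlation coefficient, Cohen's Kappa and AUC).  Cohen's Kappa uses the
standard chance-agreement term pe = [(TP+FP)(TP+FN) + (TN+FN)(TN+FP)] / n^2.
Cross-validation is stratified at record level by default; a subject-level
grouped split is available because the three replicate records per subject
leak speaker identity across record-level folds.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .classify import LabeledSet, Prediction, knn_baseline, svm_baseline, classify_prototypes
from .datamodel import ConfigError, FeatureTable, RunConfig
from .features import EmptySelectionError, build_and_select, FeaturePipeline
from .sscl import fit_sscl

METRIC_NAMES = ("accuracy", "recall", "specificity", "precision",
                "f_score", "mcc", "kappa")


class StratificationError(ValueError):
    """A fold would contain records of a single class."""


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for v in (self.tp, self.tn, self.fp, self.fn):
            if v < 0:
                raise ValueError("confusion counts must be non-negative")
        if self.n < 1:
            raise ValueError("confusion matrix is empty")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(
    true_labels: np.ndarray, predicted_labels: np.ndarray, positive_class: int = 1
) -> ConfusionCounts:
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    pos_t = t == positive_class
    pos_p = p == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


@dataclass
class MetricsReport:
    accuracy: float | None
    recall: float | None
    specificity: float | None
    precision: float | None
    f_score: float | None
    mcc: float | None
    kappa: float | None
    auc: float | None = None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in METRIC_NAMES + ("auc",)}


def _ratio(num: float, den: float, name: str) -> float | None:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as absent")
        return None
    return num / den


def metrics(c: ConfusionCounts) -> MetricsReport:
    """All confusion-matrix metrics; zero-denominator ratios become None."""
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    n = c.n
    accuracy = (tp + tn) / n
    recall = _ratio(tp, tp + fn, "recall")
    specificity = _ratio(tn, tn + fp, "specificity")
    precision = _ratio(tp, tp + fp, "precision")
    if precision is None or recall is None or (precision + recall) == 0:
        warnings.warn("f_score undefined; reported as absent")
        f_score = None
    else:
        f_score = 2 * precision * recall / (precision + recall)
    mcc_den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        warnings.warn("mcc undefined (degenerate marginal); reported as absent")
        mcc = None
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / n**2
    if pe == 1.0:
        warnings.warn("kappa undefined (chance agreement = 1); reported as absent")
        kappa = None
    else:
        kappa = (po - pe) / (1 - pe)
    return MetricsReport(accuracy=accuracy, recall=recall, specificity=specificity,
                         precision=precision, f_score=f_score, mcc=mcc, kappa=kappa)


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def roc(scores: np.ndarray, true_labels: np.ndarray, positive_class: int = 1) -> ROCCurve:
    """ROC curve by threshold sweep over unique scores, trapezoidal AUC."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(true_labels) == positive_class
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if y.all() or not y.any():
        raise ValueError("ROC requires both classes in the truth labels")
    fpr, tpr, thr = _sk_roc_curve(y.astype(int), scores)
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr,
                    auc=float(_trapezoid_auc(fpr, tpr)))


@dataclass
class CVReport:
    method: str
    config: RunConfig
    fold_metrics: list[MetricsReport]
    fold_confusions: list[ConfusionCounts]
    mean: dict[str, float | None]
    sd: dict[str, float | None]
    pooled_roc: ROCCurve | None
    pooled_true: np.ndarray
    pooled_pred: np.ndarray
    pooled_scores: np.ndarray
    pooled_record_ids: np.ndarray

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "method": self.method,
            "n_folds": len(self.fold_metrics),
            "mean": self.mean,
            "sd": self.sd,
            "per_fold": [m.as_dict() for m in self.fold_metrics],
            "pooled_auc": None if self.pooled_roc is None else self.pooled_roc.auc,
            "config": {k: v for k, v in vars(self.config).items()},
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for name in METRIC_NAMES:
            rows.append({"metric": name, "mean": self.mean[name], "sd": self.sd[name]})
        rows.append({
            "metric": "auc",
            "mean": None if self.pooled_roc is None else self.pooled_roc.auc,
            "sd": None,
        })
        return pd.DataFrame(rows)


def _aggregate(fold_metrics: list[MetricsReport]) -> tuple[dict, dict]:
    mean: dict[str, float | None] = {}
    sd: dict[str, float | None] = {}
    for name in METRIC_NAMES:
        vals = [getattr(m, name) for m in fold_metrics if getattr(m, name) is not None]
        if not vals:
            mean[name] = sd[name] = None
        else:
            mean[name] = float(np.mean(vals))
            sd[name] = float(np.std(vals, ddof=1)) if len(vals) > 1 else None
    return mean, sd


def _fold_indices(table: FeatureTable, config: RunConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified folds at record or subject level, seeded and deterministic."""
    y = table.label
    if np.any(y < 0):
        raise ValueError("cross-validation requires a fully labeled table")
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                          random_state=config.rng_seed % (2**31))
    if config.split_level == "record":
        splits = list(skf.split(np.zeros(len(y)), y))
    else:
        subjects = pd.unique(table.subject_id)
        subj_label = np.array(
            [y[table.subject_id == s][0] for s in subjects]
        )
        splits = []
        for tr_s, te_s in skf.split(np.zeros(len(subjects)), subj_label):
            tr_mask = np.isin(table.subject_id, subjects[tr_s])
            splits.append((np.flatnonzero(tr_mask), np.flatnonzero(~tr_mask)))
    for tr, te in splits:
        for part, what in ((tr, "training"), (te, "test")):
            if len(np.unique(y[part])) < 2:
                raise StratificationError(f"a {what} fold contains a single class")
    return splits


def _fit_fold_pipeline(train_table: FeatureTable, config: RunConfig) -> FeaturePipeline:
    try:
        _, _, pipeline = build_and_select(train_table, config)
    except EmptySelectionError:
        # Routine on null data at alpha = 0.05: keep the fold runnable by
        # falling back to the full candidate feature set.
        warnings.warn("fold selection empty; falling back to all candidate features")
        relaxed = config.replace(alpha=1.0 - 1e-12)
        _, _, pipeline = build_and_select(train_table, relaxed)
    return pipeline


def _predict_fold(
    method: str,
    train_x: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
    config: RunConfig,
) -> Prediction:
    training = LabeledSet(patterns=train_x, labels=train_y)
    if method == "sscl":
        # transductive: cluster labeled + unlabeled records together,
        # label centroids using training labels only
        stacked = np.vstack([train_x, test_x])
        model = fit_sscl(stacked, config)
        pred = classify_prototypes(model, training, config.r_neighbors)
        sl = slice(len(train_x), len(stacked))
        return Prediction(record_labels=pred.record_labels[sl],
                          scores=pred.scores[sl],
                          centroid_labels=pred.centroid_labels,
                          prototype_of=pred.prototype_of[sl])
    if method == "knn":
        return knn_baseline(training, test_x, k=config.knn_k)
    if method == "svm":
        return svm_baseline(training, test_x, sigma=config.svm_sigma,
                            rng_seed=config.rng_seed % (2**31))
    raise ConfigError(f"unknown method {method!r} (expected sscl/knn/svm)")


def cross_validate(table: FeatureTable, config: RunConfig, method: str) -> CVReport:
    """Stratified k-fold evaluation of one classifier.

    Per fold the feature pipeline (PCA models and MWW selection) is fitted on
    the training records only and applied frozen to the held-out records
    (unless ``config.fit_features_on_all`` requests the whole-dataset fit).
    The pooled ROC concatenates held-out scores across folds.
    """
    splits = _fold_indices(table, config)
    whole_pipeline = _fit_fold_pipeline(table, config) if config.fit_features_on_all else None

    fold_metrics, fold_conf = [], []
    pooled_true, pooled_pred, pooled_scores, pooled_ids = [], [], [], []
    for tr, te in splits:
        train_table = table.subset(tr)
        test_table = table.subset(te)
        pipeline = whole_pipeline or _fit_fold_pipeline(train_table, config)
        train_x = pipeline.transform(train_table).values
        test_x = pipeline.transform(test_table).values
        pred = _predict_fold(method, train_x, table.label[tr], test_x, config)
        c = confusion(table.label[te], pred.record_labels)
        fold_conf.append(c)
        fold_metrics.append(metrics(c))
        pooled_true.append(table.label[te])
        pooled_pred.append(pred.record_labels)
        pooled_scores.append(pred.scores)
        pooled_ids.append(te)

    mean, sd = _aggregate(fold_metrics)
    y_all = np.concatenate(pooled_true)
    s_all = np.concatenate(pooled_scores)
    pooled_roc = roc(s_all, y_all) if len(np.unique(s_all)) > 1 else None
    return CVReport(method=method, config=config, fold_metrics=fold_metrics,
                    fold_confusions=fold_conf, mean=mean, sd=sd,
                    pooled_roc=pooled_roc, pooled_true=y_all,
                    pooled_pred=np.concatenate(pooled_pred),
                    pooled_scores=s_all,
                    pooled_record_ids=np.concatenate(pooled_ids))


def gender_misclassification_summary(
    predicted_labels: np.ndarray, table: FeatureTable
) -> pd.DataFrame:
    """Misclassified records as percentages of all misclassifications,
    stratified by true class and gender; the Total row sums to 100%."""
    pred = np.asarray(predicted_labels)
    wrong = pred != table.label
    total = int(wrong.sum())
    genders = [g for g in ("male", "female", "unknown") if g in set(table.gender)]
    rows = {}
    for cls, cls_name in ((0, "HC"), (1, "PD")):
        rows[cls_name] = {
            g: (100.0 * np.sum(wrong & (table.label == cls) & (table.gender == g)) / total
                if total else 0.0)
            for g in genders
        }
    rows["Total"] = {g: rows["HC"][g] + rows["PD"][g] for g in genders}
    frame = pd.DataFrame(rows).T
    frame.attrs["total_misclassified"] = total
    return frame
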
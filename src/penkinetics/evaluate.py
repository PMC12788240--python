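"""Fold-wise and pooled evaluation: metrics, ROC curves, confusion matrix,
baseline comparison, and impurity-based feature importance.

The positive class is the impaired (AD) group throughout.  Fold test
predictions are pooled into a single confusion matrix (element-wise sum over
folds), so each real subject contributes exactly one pooled prediction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.metrics import roc_curve

from penkinetics.features import FeatureTensor, summarize, summary_feature_names
from penkinetics.models.baselines import BaselineSpec, fit_baseline, predict_scores
from penkinetics.models.hybrid import (
    HybridArchitectureSpec,
    TrainConfig,
    build_hybrid,
    train_hybrid,
)
from penkinetics.models.splits import mixed_supervision_split

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "auc")


@dataclass
class ConfusionCounts:
    """Binary confusion counts with the impaired class as positive."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        for name in ("tp", "fn", "tn", "fp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fn + other.fn,
                               self.tn + other.tn, self.fp + other.fp)

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        )


def metrics_from_confusion(c: ConfusionCounts) -> Dict[str, float]:
    """Closed-form classification metrics from confusion counts.

    Returns accuracy, precision, recall (sensitivity), specificity and F1.
    Requires at least one positive and one negative; an empty predicted-
    positive set yields precision 0 with a warning.
    """
    if c.total == 0:
        raise ValueError("confusion counts are all zero")
    pos = c.tp + c.fn
    neg = c.tn + c.fp
    if pos == 0 or neg == 0:
        raise ValueError("recall/specificity need at least one sample of each class")
    if c.tp + c.fp == 0:
        warnings.warn("no predicted positives; precision reported as 0", RuntimeWarning)
        precision = 0.0
    else:
        precision = c.tp / (c.tp + c.fp)
    recall = c.tp / pos
    specificity = c.tn / neg
    accuracy = (c.tp + c.tn) / c.total
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "specificity": specificity,
        "f1": f1,
    }


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> Tuple[float, np.ndarray, np.ndarray]:
    """ROC curve and area under it.

    Returns ``(auc, fpr, tpr)`` where the staircase points come from the
    standard threshold sweep.  The trapezoidal area equals the Mann-Whitney
    U statistic normalized by n_pos * n_neg, with ties contributing 1/2.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("roc_auc requires both classes present")
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(np.trapezoid(tpr, fpr)), fpr, tpr


def mean_roc(curves: Sequence[Tuple[np.ndarray, np.ndarray]], n_grid: int = 101):
    """Vertically average fold ROC curves on a common FPR grid.

    Returns ``(grid, mean_tpr, std_tpr)``; each fold's TPR is interpolated
    onto the grid before averaging.
    """
    grid = np.linspace(0, 1, n_grid)
    tprs = np.stack([np.interp(grid, fpr, tpr) for fpr, tpr in curves])
    tprs[:, 0] = 0.0
    return grid, tprs.mean(axis=0), tprs.std(axis=0)


@dataclass
class EvalReport:
    """Cross-validated evaluation results for one model."""

    model_name: str
    fold_metrics: List[Dict[str, float]]
    pooled_confusion: ConfusionCounts
    roc_curves: List[Tuple[list, list]]
    feature_importances: Optional[List[Tuple[str, float]]] = None
    chosen_hyperparameters: Optional[List[dict]] = None

    @property
    def metric_means(self) -> Dict[str, float]:
        return {m: float(np.mean([f[m] for f in self.fold_metrics])) for m in self.fold_metrics[0]}

    @property
    def metric_stds(self) -> Dict[str, float]:
        return {m: float(np.std([f[m] for f in self.fold_metrics])) for m in self.fold_metrics[0]}

    @property
    def pooled_metrics(self) -> Dict[str, float]:
        return metrics_from_confusion(self.pooled_confusion)

    def to_json(self) -> str:
        payload = {
            "model_name": self.model_name,
            "fold_metrics": self.fold_metrics,
            "pooled_confusion": asdict(self.pooled_confusion),
            "roc_curves": [[list(map(float, f)), list(map(float, t))] for f, t in self.roc_curves],
            "feature_importances": self.feature_importances,
            "chosen_hyperparameters": self.chosen_hyperparameters,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EvalReport":
        d = json.loads(text)
        return cls(
            model_name=d["model_name"],
            fold_metrics=d["fold_metrics"],
            pooled_confusion=ConfusionCounts(**d["pooled_confusion"]),
            roc_curves=[(list(f), list(t)) for f, t in d["roc_curves"]],
            feature_importances=(None if d.get("feature_importances") is None
                                 else [tuple(x) for x in d["feature_importances"]]),
            chosen_hyperparameters=d.get("chosen_hyperparameters"),
        )


def _labels_to_binary(items: Sequence[FeatureTensor]) -> np.ndarray:
    return np.array([1 if it.label == "AD" else 0 for it in items], dtype=float)


def cross_validate(
    real: Sequence[FeatureTensor],
    synthetic: Sequence[FeatureTensor],
    model: Union[str, BaselineSpec] = "hybrid",
    *,
    n_folds: int = 5,
    seed: int = 0,
    train_config: Optional[TrainConfig] = None,
    threshold: float = 0.5,
    baselines_use_synthetic: bool = False,
) -> EvalReport:
    """K-fold mixed-supervision evaluation of the hybrid net or a baseline.

    Per fold, the training partition is all synthetic tensors plus the real
    training subjects; the test partition holds real subjects only.  The
    hybrid network trains on full feature tensors; a baseline family (pass a
    family name or ``BaselineSpec``) trains on 90-dimensional summary
    vectors and, following the comparison protocol, on the real training
    data only unless ``baselines_use_synthetic`` is set.  Hard labels use
    ``threshold`` on the positive-class score; test predictions across folds
    are pooled into one confusion matrix.  For the random-forest baseline
    the report carries impurity-based feature importances from the last
    fold's fitted model.
    """
    if isinstance(model, str) and model != "hybrid":
        model = BaselineSpec(model)
    is_hybrid = isinstance(model, str)

    fold_metrics: List[Dict[str, float]] = []
    curves: List[Tuple[np.ndarray, np.ndarray]] = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    importances = None
    chosen = []

    for fold in range(n_folds):
        fold_seed = (seed * 1009 + fold) % (2**31)
        synth_train = list(synthetic) if (is_hybrid or baselines_use_synthetic) else []
        train, test = mixed_supervision_split(real, synth_train, fold, n_folds, seed)
        y_train = _labels_to_binary(train)
        y_test = _labels_to_binary(test)
        if is_hybrid:
            X_train = np.stack([t.values for t in train]).astype(np.float32)
            X_test = np.stack([t.values for t in test]).astype(np.float32)
            spec = HybridArchitectureSpec(seq_len=X_train.shape[1], n_channels=X_train.shape[2])
            cfg = train_config or TrainConfig()
            net = build_hybrid(spec, seed=fold_seed)
            fold_cfg = TrainConfig(**{**cfg.__dict__, "seed": fold_seed})
            net, _ = train_hybrid(net, X_train, y_train, fold_cfg)
            scores = net.predict_proba(X_test)
        else:
            X_train = np.stack([summarize(t) for t in train])
            X_test = np.stack([summarize(t) for t in test])
            fitted = fit_baseline(model, X_train, y_train, seed=fold_seed)
            chosen.append(fitted.best_params_)
            scores = predict_scores(fitted, X_test)
            if model.family == "RF":
                importances = feature_importance(fitted, summary_feature_names())
            # map decision-function scores through a sigmoid-free threshold at 0
            if not hasattr(fitted.best_estimator_, "predict_proba"):
                threshold_fold = 0.0
            else:
                threshold_fold = threshold
        thr = threshold if is_hybrid else threshold_fold
        preds = (scores >= thr).astype(int)
        counts = ConfusionCounts.from_predictions(y_test, preds)
        pooled = pooled + counts
        m = metrics_from_confusion(counts)
        auc, fpr, tpr = roc_auc(scores, y_test)
        m = {k: m[k] for k in ("accuracy", "precision", "recall", "f1")}
        m["auc"] = auc
        fold_metrics.append(m)
        curves.append((fpr, tpr))

    name = "hybrid" if is_hybrid else model.family
    return EvalReport(
        model_name=name,
        fold_metrics=fold_metrics,
        pooled_confusion=pooled,
        roc_curves=[(list(map(float, f)), list(map(float, t))) for f, t in curves],
        feature_importances=importances,
        chosen_hyperparameters=chosen or None,
    )


def feature_importance(fitted, feature_names: Sequence[str]) -> List[Tuple[str, float]]:
    """Impurity-decrease importances of a fitted random forest, descending.

    Accepts a fitted ``GridSearchCV`` or pipeline whose final step is the
    forest.  Importances sum to 1.
    """
    est = getattr(fitted, "best_estimator_", fitted)
    if hasattr(est, "named_steps"):
        est = est.named_steps["clf"]
    if not hasattr(est, "feature_importances_"):
        raise ValueError("feature_importance requires a fitted tree ensemble")
    imp = est.feature_importances_
    if len(imp) != len(feature_names):
        raise ValueError("feature-name count does not match the fitted model")
    order = np.argsort(-imp)
    return [(feature_names[i], float(imp[i])) for i in order]
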
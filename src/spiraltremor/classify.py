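"""Training, evaluation metrics, and single-image prediction.

The positive class is ``parkinson``.  Headline metrics follow the usual
binary conventions: accuracy (TP+TN)/total, positive-class precision
TP/(TP+FP), recall TP/(TP+FN), and F1 = 2TP/(2TP+FP+FN); per-class metrics
and support-weighted averages (weights = true class counts) are reported
alongside, all as percentages rounded to two decimals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import nan

import joblib
import numpy as np

from .dataset import FeatureTable
from .estimators import (NEGATIVE_LABEL, POSITIVE_LABEL,
                         SpiralFeatureExtractor, TremorSpiralClassifier)
from .preprocess import load_gray

__all__ = ["ConfusionMatrix", "MetricBundle", "EvalReport", "TrainedModel",
           "metrics_from_confusion", "train_grid_search", "evaluate",
           "predict_image", "save_model", "load_model"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; positive class = parkinson."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred,
                         positive=POSITIVE_LABEL) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos_t, pos_p = y_true == positive, y_pred == positive
        return cls(tp=int(np.sum(pos_t & pos_p)),
                   tn=int(np.sum(~pos_t & ~pos_p)),
                   fp=int(np.sum(~pos_t & pos_p)),
                   fn=int(np.sum(pos_t & ~pos_p)))


def _pct(x: float) -> float:
    return round(100.0 * x, 2) if np.isfinite(x) else float("nan")


def _ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("undefined %s (zero denominator); reporting NaN", what)
        return nan
    return num / den


@dataclass(frozen=True)
class MetricBundle:
    """All evaluation metrics derived from one confusion matrix.

    Percentages rounded to 2 decimals; undefined ratios are NaN.
    """

    accuracy: float
    precision_positive: float
    recall_positive: float
    f1_positive: float
    precision_weighted: float
    recall_weighted: float
    f1_weighted: float
    per_class: dict
    cm: ConfusionMatrix


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricBundle:
    """Accuracy, precision, recall, F1 (positive-class, per-class, weighted)."""
    acc = _ratio(cm.tp + cm.tn, cm.total, "accuracy")

    prec_pos = _ratio(cm.tp, cm.tp + cm.fp, "positive precision")
    rec_pos = _ratio(cm.tp, cm.tp + cm.fn, "positive recall")
    f1_pos = _ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn, "positive F1")

    # negative (healthy) class: swap the roles of the counts
    prec_neg = _ratio(cm.tn, cm.tn + cm.fn, "negative precision")
    rec_neg = _ratio(cm.tn, cm.tn + cm.fp, "negative recall")
    denom = 2 * cm.tn + cm.fn + cm.fp
    f1_neg = _ratio(2 * cm.tn, denom, "negative F1")

    support_pos = cm.tp + cm.fn
    support_neg = cm.tn + cm.fp

    def weighted(pos, neg):
        return (support_pos * pos + support_neg * neg) / cm.total

    per_class = {
        POSITIVE_LABEL: {"precision": _pct(prec_pos), "recall": _pct(rec_pos),
                         "f1": _pct(f1_pos), "support": support_pos},
        NEGATIVE_LABEL: {"precision": _pct(prec_neg), "recall": _pct(rec_neg),
                         "f1": _pct(f1_neg), "support": support_neg},
    }
    return MetricBundle(
        accuracy=_pct(acc),
        precision_positive=_pct(prec_pos),
        recall_positive=_pct(rec_pos),
        f1_positive=_pct(f1_pos),
        precision_weighted=_pct(weighted(prec_pos, prec_neg)),
        recall_weighted=_pct(weighted(rec_pos, rec_neg)),
        f1_weighted=_pct(weighted(f1_pos, f1_neg)),
        per_class=per_class,
        cm=cm,
    )


@dataclass
class TrainedModel:
    """A fitted classifier plus the metadata needed to apply it."""

    classifier: TremorSpiralClassifier
    feature_set: str
    algorithm: str
    seed: int | None = None
    extractor_params: dict = field(default_factory=dict)

    @property
    def chosen_hyperparameters(self) -> dict:
        return self.classifier.best_params_


@dataclass
class EvalReport:
    """Evaluation of one trained model on one held-out table."""

    algorithm: str
    feature_set: str
    chosen_hyperparameters: dict
    metrics: MetricBundle

    @property
    def accuracy(self) -> float:
        return self.metrics.accuracy

    def as_dict(self) -> dict:
        m = self.metrics
        return {
            "algorithm": self.algorithm,
            "feature_set": self.feature_set,
            "chosen_hyperparameters": self.chosen_hyperparameters,
            "accuracy": m.accuracy,
            "precision_weighted": m.precision_weighted,
            "recall_weighted": m.recall_weighted,
            "f1_positive": m.f1_positive,
            "f1_weighted": m.f1_weighted,
            "per_class": m.per_class,
            "confusion_matrix": {"TP": m.cm.tp, "TN": m.cm.tn,
                                 "FP": m.cm.fp, "FN": m.cm.fn},
        }


def train_grid_search(table: FeatureTable, algorithm: str = "RF",
                      grids: dict | None = None,
                      seed: int | None = None,
                      extractor_params: dict | None = None) -> TrainedModel:
    """Grid search with 5-fold stratified CV and fold-wise normalization."""
    if len(table) < 10:
        raise ValueError("need at least 10 training rows")
    clf = TremorSpiralClassifier(algorithm=algorithm, param_grid=grids,
                                 random_state=seed)
    clf.fit(table.X, table.y)
    return TrainedModel(classifier=clf, feature_set=table.feature_set,
                        algorithm=algorithm, seed=seed,
                        extractor_params=dict(extractor_params or {}))


def evaluate(model: TrainedModel, table: FeatureTable) -> EvalReport:
    """Apply the stored scaler + classifier to a held-out table."""
    if table.feature_set != model.feature_set:
        raise ValueError(
            f"feature-set mismatch: model {model.feature_set!r} vs "
            f"table {table.feature_set!r}")
    if len(table) == 0:
        raise ValueError("empty evaluation table")
    y_pred = model.classifier.predict(table.X)
    cm = ConfusionMatrix.from_predictions(table.y, y_pred)
    return EvalReport(algorithm=model.algorithm,
                      feature_set=model.feature_set,
                      chosen_hyperparameters=model.chosen_hyperparameters,
                      metrics=metrics_from_confusion(cm))


def predict_image(model: TrainedModel, image_or_path) -> str:
    """Classify one drawing; returns 'healthy', 'parkinson' or 'unusable'.

    An image whose required features cannot be computed (self-intersecting
    spiral, blank page, ...) is reported as 'unusable' rather than guessed.
    """
    if isinstance(image_or_path, (str, bytes)) or hasattr(image_or_path,
                                                          "__fspath__"):
        image = load_gray(image_or_path)
    else:
        image = np.asarray(image_or_path)
    extractor = SpiralFeatureExtractor(feature_set=model.feature_set,
                                       **model.extractor_params).fit()
    x = extractor.transform([image])
    if np.isnan(x).any() or np.isinf(x).any():
        return "unusable"
    return str(model.classifier.predict(x)[0])


def save_model(model: TrainedModel, path) -> None:
    """Persist a trained model (self-describing joblib archive)."""
    joblib.dump({"format": "spiraltremor-model", "version": 1,
                 "model": model}, path)


def load_model(path) -> TrainedModel:
    payload = joblib.load(path)
    if not (isinstance(payload, dict)
            and payload.get("format") == "spiraltremor-model"):
        raise ValueError(f"{path} is not a spiraltremor model archive")
    return payload["model"]
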
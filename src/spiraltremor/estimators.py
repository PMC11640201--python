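"""scikit-learn estimators wrapping the spiral pipeline.

:class:`SpiralFeatureExtractor` is a stateless transformer turning raster
drawings into the tremor/pencil feature matrix; :class:`TremorSpiralClassifier`
is a grid-searched binary classifier with leakage-safe fold-wise
standardization.  Both follow the sklearn estimator contract (get/set_params,
fitted attributes with trailing underscores) and compose with sklearn
pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .pipeline import FEATURE_SETS, PipelineConfig, extract_record

__all__ = ["SpiralFeatureExtractor", "TremorSpiralClassifier",
           "ALGORITHMS", "default_grid"]

POSITIVE_LABEL = "parkinson"
NEGATIVE_LABEL = "healthy"


class SpiralFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transform spiral drawings into tremor and pencil features.

    Parameters mirror :class:`~spiraltremor.pipeline.PipelineConfig`; the
    transformer holds no fitted state (``fit`` only validates parameters),
    matching sklearn's convention for deterministic feature extractors.

    ``X`` is a list/array of 2-D grayscale images; ``transform`` returns a
    float matrix with one row per image and NaN where extraction failed.
    """

    def __init__(self, feature_set: str = "FP", blur_kernel: int = 5,
                 block_size: int = 11, offset_c: float = 2.0,
                 smoothing_scale: float = 10.0, draw_duration: float = 10.0,
                 include_holes: bool = True):
        self.feature_set = feature_set
        self.blur_kernel = blur_kernel
        self.block_size = block_size
        self.offset_c = offset_c
        self.smoothing_scale = smoothing_scale
        self.draw_duration = draw_duration
        self.include_holes = include_holes

    def _config(self) -> PipelineConfig:
        return PipelineConfig(blur_kernel=self.blur_kernel,
                              block_size=self.block_size,
                              offset_c=self.offset_c,
                              smoothing_scale=self.smoothing_scale,
                              draw_duration=self.draw_duration,
                              include_holes=self.include_holes)

    def fit(self, X=None, y=None):
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {self.feature_set!r}")
        self.feature_names_out_ = list(FEATURE_SETS[self.feature_set])
        self.n_features_out_ = len(self.feature_names_out_)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "feature_names_out_")
        config = self._config()
        rows = []
        for image in X:
            record = extract_record(np.asarray(image), self.feature_set,
                                    config)
            rows.append([record[k] for k in self.feature_names_out_])
        return np.asarray(rows, dtype=float)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "feature_names_out_")
        return np.asarray(self.feature_names_out_, dtype=object)


def _base_estimator(algorithm: str, random_state):
    import lightgbm
    import xgboost

    if algorithm == "DT":
        return DecisionTreeClassifier(random_state=random_state)
    if algorithm == "RF":
        return RandomForestClassifier(random_state=random_state)
    if algorithm == "SVM":
        return SVC(random_state=random_state)
    if algorithm == "XGBoost":
        return xgboost.XGBClassifier(random_state=random_state,
                                     eval_metric="logloss", n_jobs=1)
    if algorithm == "AdaBoost-DT":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            random_state=random_state)
    if algorithm == "LightGBM":
        # small-cohort default: the stock min_child_samples=20 collapses
        # trees to a constant on datasets of this size
        return lightgbm.LGBMClassifier(random_state=random_state,
                                       min_child_samples=5,
                                       verbose=-1, n_jobs=1)
    raise ValueError(f"unknown algorithm {algorithm!r}")


#: Default hyperparameter grids per algorithm family.
DEFAULT_GRIDS = {
    "DT": {"max_depth": [3, 5, 10, None]},
    "RF": {"n_estimators": [100, 300, 500], "max_depth": [None, 5, 10]},
    "SVM": {"kernel": ["rbf", "linear"], "C": [0.1, 1.0, 10.0]},
    "XGBoost": {"n_estimators": [100, 300], "learning_rate": [0.05, 0.1],
                "max_depth": [3, 6]},
    "AdaBoost-DT": {"n_estimators": [50, 200], "learning_rate": [0.5, 1.0]},
    "LightGBM": {"n_estimators": [200, 500], "max_depth": [4, 6]},
}

ALGORITHMS = tuple(DEFAULT_GRIDS)


def default_grid(algorithm: str) -> dict:
    return {k: list(v) for k, v in DEFAULT_GRIDS[algorithm].items()}


class TremorSpiralClassifier(ClassifierMixin, BaseEstimator):
    """Grid-searched binary classifier over tremor/pencil features.

    Fitting runs a grid search with stratified ``cv``-fold cross-validation
    where each fold standardizes features using statistics of that fold's
    training portion only (scaler and classifier live in one sklearn
    Pipeline, so no information flows from a validation fold into its
    scaler).  The best mean-CV-accuracy grid point (ties: first in declared
    order) is refit on all training rows.

    Attributes
    ----------
    classes_ : array of class labels.
    best_params_ : chosen hyperparameters (without pipeline prefixes).
    best_score_ : mean CV accuracy of the chosen grid point.
    pipeline_ : fitted Pipeline(StandardScaler, classifier).
    """

    def __init__(self, algorithm: str = "RF", param_grid: dict | None = None,
                 cv: int = 5, random_state: int | None = None):
        self.algorithm = algorithm
        self.param_grid = param_grid
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        if np.isnan(X).any():
            raise ValueError("X contains NaN; clean the table first")
        self.classes_, counts = np.unique(y, return_counts=True)
        if len(self.classes_) < 2:
            raise ValueError("training data contains a single class")
        if counts.min() < self.cv:
            raise ValueError(
                f"smallest class has {counts.min()} rows; cannot stratify "
                f"{self.cv} folds")
        y_enc = np.searchsorted(self.classes_, y)
        grid = self.param_grid if self.param_grid is not None \
            else default_grid(self.algorithm)
        pipe = Pipeline([
            ("scale", StandardScaler()),
            ("clf", _base_estimator(self.algorithm, self.random_state)),
        ])
        search = GridSearchCV(
            pipe,
            {f"clf__{k}": v for k, v in grid.items()},
            scoring="accuracy",
            cv=StratifiedKFold(n_splits=self.cv, shuffle=True,
                               random_state=self.random_state),
            refit=True,
            n_jobs=None,
        )
        search.fit(X, y_enc)
        self.best_params_ = {k.removeprefix("clf__"): v
                             for k, v in search.best_params_.items()}
        self.best_score_ = float(search.best_score_)
        self.cv_results_ = search.cv_results_
        self.pipeline_ = search.best_estimator_
        self.scaler_ = self.pipeline_.named_steps["scale"]
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "pipeline_")
        X = np.asarray(X, dtype=float)
        return self.classes_[self.pipeline_.predict(X).astype(int)]

    def predict_proba(self, X):
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict_proba(np.asarray(X, dtype=float))
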
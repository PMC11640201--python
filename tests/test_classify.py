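"""Classifier construction, fold-wise normalization, and metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from spiraltremor import (ConfusionMatrix, FeatureTable,
                          TremorSpiralClassifier, evaluate, load_model,
                          metrics_from_confusion, predict_image, save_model,
                          train_grid_search)


def blob_table(n=40, sep=20.0, seed=0, feature_set="P"):
    rng = np.random.default_rng(seed)
    half = n // 2
    x = np.vstack([rng.normal(0, 1, (half, 2)),
                   rng.normal(sep, 1, (n - half, 2))])
    df = pd.DataFrame({
        "id": [f"r{i}" for i in range(n)],
        "label": ["healthy"] * half + ["parkinson"] * (n - half),
        "thickness": x[:, 0], "pressure": x[:, 1]})
    return FeatureTable(df, feature_set=feature_set)


def test_separable_blobs_reach_perfect_accuracy():
    table = blob_table()
    model = train_grid_search(table, algorithm="RF", seed=0)
    assert model.classifier.best_score_ == pytest.approx(1.0)
    report = evaluate(model, blob_table(seed=1))
    assert report.accuracy == 100.0
    assert report.metrics.cm.fp == 0 and report.metrics.cm.fn == 0


def test_grid_search_deterministic_under_seed():
    table = blob_table(sep=2.0)
    a = train_grid_search(table, algorithm="RF", seed=7)
    b = train_grid_search(table, algorithm="RF", seed=7)
    assert a.chosen_hyperparameters == b.chosen_hyperparameters
    assert a.classifier.best_score_ == b.classifier.best_score_


@pytest.mark.parametrize("algorithm",
                         ["DT", "SVM", "XGBoost", "AdaBoost-DT", "LightGBM"])
def test_all_algorithm_families_train(algorithm):
    table = blob_table(n=30)
    model = train_grid_search(table, algorithm=algorithm, seed=1)
    assert evaluate(model, blob_table(n=20, seed=2)).accuracy >= 90.0


def test_too_small_or_single_class_tables_raise():
    with pytest.raises(ValueError):
        train_grid_search(blob_table(n=4), algorithm="DT", seed=0)
    single = blob_table(n=20)
    single.df["label"] = "healthy"
    table = FeatureTable(single.df, "P")
    with pytest.raises(ValueError, match="single class"):
        train_grid_search(table, algorithm="DT", seed=0)


def test_feature_set_mismatch_rejected():
    model = train_grid_search(blob_table(), algorithm="DT", seed=0)
    fp_df = blob_table().df.copy()
    for col in ("peak_magnitude", "peak_frequency", "snr", "variance",
                "bandwidth"):
        fp_df[col] = 0.0
    with pytest.raises(ValueError, match="mismatch"):
        evaluate(model, FeatureTable(fp_df, "FP"))


def test_cv_normalization_is_fold_wise():
    """The grid search's CV accuracy matches a manual leakage-free
    replication: each fold's scaler fit on that fold's training rows only.

    Uses a scale-sensitive learner (SVM) and data with extreme outliers so
    that a scaler leaking validation rows would produce a different score.
    """
    from sklearn.svm import SVC

    table = blob_table(n=40, sep=3.0, seed=3)
    X, y = table.X.copy(), table.y
    X[:4] *= 500.0  # outliers that would distort a leaky scaler
    seed = 11
    clf = TremorSpiralClassifier(algorithm="SVM",
                                 param_grid={"kernel": ["rbf"], "C": [1.0]},
                                 random_state=seed)
    clf.fit(X, y)

    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    scores = []
    for train_idx, val_idx in cv.split(X, y):
        scaler = StandardScaler().fit(X[train_idx])
        svc = SVC(kernel="rbf", C=1.0, random_state=seed)
        svc.fit(scaler.transform(X[train_idx]), y[train_idx])
        scores.append(np.mean(
            svc.predict(scaler.transform(X[val_idx])) == y[val_idx]))
    assert clf.best_score_ == pytest.approx(np.mean(scores), abs=1e-12)


def test_final_scaler_is_fit_on_all_training_rows():
    table = blob_table(n=40, sep=3.0, seed=3)
    model = train_grid_search(table, algorithm="DT", seed=5)
    expected = StandardScaler().fit(table.X)
    assert np.allclose(model.classifier.scaler_.mean_, expected.mean_)
    assert np.allclose(model.classifier.scaler_.scale_, expected.scale_)


def test_classifier_is_sklearn_compatible():
    from sklearn.base import clone

    clf = TremorSpiralClassifier(algorithm="DT", random_state=3)
    cloned = clone(clf)
    assert cloned.get_params()["algorithm"] == "DT"
    table = blob_table(n=30)
    clf.fit(table.X, table.y)
    assert set(clf.classes_) == {"healthy", "parkinson"}
    assert clf.score(table.X, table.y) == 1.0


# ----------------------------------------------------------- metrics -----

def test_printed_confusion_matrix_metrics():
    m = metrics_from_confusion(ConfusionMatrix(tp=10, tn=10, fp=1, fn=0))
    assert m.accuracy == 95.24
    assert m.precision_weighted == 95.67
    assert m.recall_weighted == 95.24
    assert m.f1_positive == 95.24
    assert m.per_class["healthy"]["recall"] == 90.91


def test_perfect_and_degenerate_confusions():
    perfect = metrics_from_confusion(ConfusionMatrix(tp=5, tn=5, fp=0, fn=0))
    assert perfect.accuracy == perfect.f1_positive == 100.0
    all_pos = metrics_from_confusion(ConfusionMatrix(tp=5, tn=0, fp=5, fn=0))
    assert all_pos.accuracy == 50.0
    assert all_pos.per_class["healthy"]["recall"] == 0.0
    assert np.isnan(all_pos.per_class["healthy"]["precision"])
    with pytest.raises(ValueError):
        ConfusionMatrix(tp=0, tn=0, fp=0, fn=0)


def test_metrics_agree_with_sklearn_recount():
    """Brute-force recount from (label, prediction) pairs on random data."""
    rng = np.random.default_rng(99)
    labels = np.array(["healthy", "parkinson"])
    for _ in range(200):
        n = int(rng.integers(4, 60))
        y_true = labels[rng.integers(0, 2, n)]
        y_pred = labels[rng.integers(0, 2, n)]
        if len(set(y_true)) < 2 or len(set(y_pred)) < 2:
            continue
        cm = ConfusionMatrix.from_predictions(y_true, y_pred)
        m = metrics_from_confusion(cm)
        # metrics are percentages rounded to 2 decimals (round-half-even),
        # so agreement holds to half a rounding quantum
        assert m.accuracy == pytest.approx(
            100.0 * np.mean(y_true == y_pred), abs=0.0051)
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, average="weighted", zero_division=0.0)
        assert m.precision_weighted == pytest.approx(100 * p, abs=0.0051)
        assert m.recall_weighted == pytest.approx(100 * r, abs=0.0051)
        assert m.f1_weighted == pytest.approx(100 * f, abs=0.0051)


@given(tp=st.integers(0, 60), tn=st.integers(0, 60),
       fp=st.integers(0, 60), fn=st.integers(0, 60))
@settings(deadline=None, derandomize=True)
def test_recall_weighted_equals_accuracy_for_complete_predictions(
        tp, tn, fp, fn):
    """Support-weighted recall is accuracy whenever both classes occur."""
    assume(tp + fn > 0 and tn + fp > 0)
    m = metrics_from_confusion(ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn))
    assert m.recall_weighted == m.accuracy
    assert 0.0 <= m.accuracy <= 100.0


# ------------------------------------------------------ predict_image ----

def test_predict_image_paths(tmp_path, small_cohort):
    from spiraltremor.dataset import build_feature_table

    table = build_feature_table(small_cohort.images, small_cohort.labels,
                                "P")
    model = train_grid_search(table, algorithm="DT", seed=0)
    healthy_idx = small_cohort.labels.index("healthy")
    assert predict_image(model, small_cohort.images[healthy_idx]) in (
        "healthy", "parkinson")
    blank = np.full((64, 64), 255, np.uint8)
    assert predict_image(model, blank) == "unusable"


def test_model_round_trip(tmp_path):
    table = blob_table(n=30)
    model = train_grid_search(table, algorithm="DT", seed=0)
    path = tmp_path / "model.joblib"
    save_model(model, path)
    back = load_model(path)
    assert back.algorithm == "DT"
    assert back.chosen_hyperparameters == model.chosen_hyperparameters
    assert evaluate(back, blob_table(n=20, seed=4)).accuracy == \
        evaluate(model, blob_table(n=20, seed=4)).accuracy
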
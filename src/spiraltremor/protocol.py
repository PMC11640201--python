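"""The full study protocol: augment, extract, clean, grid-search, evaluate.

This is the end-to-end recipe for a cohort of labeled spiral drawings that
is already divided into a training and a testing split: the training split
is rotation-augmented (the test split is left untouched to avoid evaluating
on rotated copies of training drawings), features are extracted for the
requested feature sets (F / P / FP), NaN rows are dropped, each classifier
family is tuned by grid search with 5-fold stratified CV and fold-wise
standardization, and the tuned model is evaluated on the held-out split.

``run_protocol_from_dirs`` applies the same recipe to drawings on disk in
the layout ``<root>/{train,test}/{healthy,parkinson}/*.png``, so a
separately obtained real dataset can be processed with one call (or via the
``spiraltremor protocol`` CLI).
"""

from __future__ import annotations

from pathlib import Path

from .classify import EvalReport, evaluate, train_grid_search
from .dataset import augment_rotations, build_feature_table, clean_table
from .pipeline import PipelineConfig

__all__ = ["run_protocol", "run_protocol_from_dirs"]

LABELS = ("healthy", "parkinson")


def _augmented(images, labels, ids):
    out_images, out_labels, out_ids = [], [], []
    for image, label, id_ in zip(images, labels, ids):
        for angle, rotated in zip(range(-45, 166, 15),
                                  augment_rotations(image)):
            out_images.append(rotated)
            out_labels.append(label)
            out_ids.append(f"{id_}_rot{angle:+04d}")
    return out_images, out_labels, out_ids


def run_protocol(train_images, train_labels, test_images, test_labels,
                 feature_sets=("F", "P", "FP"), algorithms=("RF",),
                 seed: int | None = 0, augment: bool = True,
                 config: PipelineConfig = PipelineConfig(),
                 grids: dict | None = None) -> dict:
    """Run the whole pipeline; returns {(algorithm, feature_set): EvalReport}.

    ``grids`` optionally maps algorithm name -> hyperparameter grid.
    """
    train_ids = [f"train{i:04d}" for i in range(len(train_images))]
    test_ids = [f"test{i:04d}" for i in range(len(test_images))]
    if augment:
        train_images, train_labels, train_ids = _augmented(
            train_images, train_labels, train_ids)

    reports: dict = {}
    for fs in feature_sets:
        train_tab = clean_table(build_feature_table(
            train_images, train_labels, fs, ids=train_ids, config=config,
            split="train"))
        test_tab = clean_table(build_feature_table(
            test_images, test_labels, fs, ids=test_ids, config=config,
            split="test"))
        for algorithm in algorithms:
            grid = (grids or {}).get(algorithm)
            model = train_grid_search(train_tab, algorithm=algorithm,
                                      grids=grid, seed=seed)
            reports[(algorithm, fs)] = evaluate(model, test_tab)
    return reports


def _load_split(split_dir: Path):
    from .preprocess import load_gray

    images, labels = [], []
    for label in LABELS:
        label_dir = split_dir / label
        if not label_dir.is_dir():
            raise FileNotFoundError(f"missing directory {label_dir}")
        for path in sorted(label_dir.iterdir()):
            if path.suffix.lower() in (".png", ".jpg", ".jpeg"):
                images.append(load_gray(path))
                labels.append(label)
    if not images:
        raise FileNotFoundError(f"no images under {split_dir}")
    return images, labels


def run_protocol_from_dirs(root, feature_sets=("F", "P", "FP"),
                           algorithms=("RF",), seed: int | None = 0,
                           augment: bool = True) -> dict:
    """Run the study protocol on a ``{train,test}/{healthy,parkinson}``
    directory tree of PNG/JPEG drawings."""
    root = Path(root)
    train_images, train_labels = _load_split(root / "train")
    test_images, test_labels = _load_split(root / "test")
    return run_protocol(train_images, train_labels, test_images, test_labels,
                        feature_sets=feature_sets, algorithms=algorithms,
                        seed=seed, augment=augment)
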
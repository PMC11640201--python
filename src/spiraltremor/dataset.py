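"""Rotation augmentation, feature tables, CSV serialization, NaN cleaning.

Rotation is the one augmentation appropriate for spiral drawings: scaling
would destroy the micrographia signal, shifting is meaningless once the
spiral center is detected, and blur/brightness changes would corrupt the
pencil features.  Each image is rotated from -45 deg to 165 deg in 15 deg
steps (15 images including the untouched original at 0 deg).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import rotate as _nd_rotate

from .exceptions import EmptyTableError
from .pipeline import FEATURE_SETS, PipelineConfig, extract_record

__all__ = ["ROTATION_ANGLES", "FeatureTable", "augment_rotations",
           "build_feature_table", "clean_table", "write_csv", "read_csv"]

logger = logging.getLogger(__name__)

ROTATION_ANGLES = tuple(range(-45, 166, 15))  # 15 angles incl. 0
WHITE = 255


def augment_rotations(image: np.ndarray,
                      angles=ROTATION_ANGLES) -> list:
    """Rotations of a grayscale drawing about the image center.

    Output images keep the input dimensions; corners exposed by the
    rotation are filled white (paper).  The 0 deg element is the unaltered
    input.  Resampling is bilinear.
    """
    image = np.asarray(image)
    out = []
    for angle in angles:
        if angle == 0:
            out.append(image.copy())
            continue
        rot = _nd_rotate(image.astype(float), angle, reshape=False,
                         order=1, mode="constant", cval=WHITE)
        out.append(np.clip(np.rint(rot), 0, 255).astype(image.dtype))
    return out


@dataclass
class FeatureTable:
    """Feature rows for one cohort split.

    ``df`` columns: ``id``, ``label`` and the feature columns of
    ``feature_set`` (F: the 5 frequency features; P: the 2 pencil features;
    FP: all 7).
    """

    df: pd.DataFrame
    feature_set: str = "FP"
    split: str | None = None

    def __post_init__(self):
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {self.feature_set!r}")
        expected = ["id", "label"] + FEATURE_SETS[self.feature_set]
        missing = [c for c in expected if c not in self.df.columns]
        if missing:
            raise ValueError(f"table is missing columns {missing}")
        if self.df["id"].duplicated().any():
            raise ValueError("duplicate row ids")
        self.df = self.df[expected].reset_index(drop=True)

    @property
    def feature_columns(self) -> list:
        return FEATURE_SETS[self.feature_set]

    @property
    def X(self) -> np.ndarray:
        return self.df[self.feature_columns].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.df["label"].to_numpy()

    def __len__(self) -> int:
        return len(self.df)


def build_feature_table(images, labels, feature_set: str = "FP",
                        ids=None, config: PipelineConfig = PipelineConfig(),
                        split: str | None = None) -> FeatureTable:
    """Run the extraction pipelines over a cohort of grayscale images.

    One row per image; images the pipeline cannot process get NaN feature
    values (removed later by :func:`clean_table`).
    """
    images = list(images)
    labels = list(labels)
    if not images:
        raise ValueError("no images given")
    if len(images) != len(labels):
        raise ValueError("images and labels differ in length")
    if ids is None:
        ids = [f"img{i:04d}" for i in range(len(images))]
    rows = []
    for id_, image, label in zip(ids, images, labels):
        row = {"id": id_, "label": label}
        row.update(extract_record(image, feature_set, config))
        rows.append(row)
    return FeatureTable(pd.DataFrame(rows), feature_set=feature_set,
                        split=split)


def clean_table(table: FeatureTable) -> FeatureTable:
    """Drop rows with NaN in any key feature column (order preserved)."""
    keep = ~table.df[table.feature_columns].isna().any(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("clean_table: dropped %d of %d rows with NaN features",
                    dropped, len(table))
    df = table.df[keep].reset_index(drop=True)
    if df.empty:
        raise EmptyTableError("empty table after cleaning")
    return FeatureTable(df, feature_set=table.feature_set, split=table.split)


def write_csv(table: FeatureTable, path) -> None:
    """Serialize as comma-separated UTF-8 with a header row; NaN as 'NaN'.

    Floats are written with shortest round-trip repr; together with the
    round-trip parser in :func:`read_csv` a write/read cycle reproduces the
    table bit-exactly.
    """
    table.df.to_csv(path, index=False, na_rep="NaN")


def read_csv(path, feature_set: str | None = None,
             split: str | None = None) -> FeatureTable:
    """Read a feature CSV written by :func:`write_csv`.

    The feature set is inferred from the columns when not given.
    """
    df = pd.read_csv(path, dtype={"id": str, "label": str},
                     float_precision="round_trip")
    if feature_set is None:
        cols = set(df.columns)
        for fs in ("FP", "F", "P"):
            if set(FEATURE_SETS[fs]) <= cols:
                feature_set = fs
                break
        else:
            raise ValueError("could not infer feature set from columns")
    return FeatureTable(df, feature_set=feature_set, split=split)
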
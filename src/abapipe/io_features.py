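"""Subject feature tables and training-partition standardization.

The whole pipeline operates on tidy per-subject tables: a few metadata
columns (subject id, gender, chronological age in years, diagnostic group
AD/CN, source cohort tag) followed by named numeric morphometric features —
typically FreeSurfer-style ROI volumes and cortical thicknesses.  Feature
standardization (z-scoring) is a *model*: it is fitted on a training
partition only and then applied unchanged to both training and test
partitions, which is what keeps downstream cross-validation leakage-free.

Chronological age is deliberately never standardized: it is the regression
target and a classifier input, and keeping it in years means MAE values are
in years too.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

METADATA_COLUMNS = ("subject_id", "gender", "age", "group", "cohort")
GENDERS = ("M", "F")
GROUPS = ("AD", "CN")


class FeatureTableError(ValueError):
    """A feature table violated its schema or one of its invariants."""


@dataclass(frozen=True)
class FeatureTable:
    """Per-subject metadata plus a named numeric feature matrix.

    ``meta`` holds exactly the columns in :data:`METADATA_COLUMNS`;
    ``features`` holds one numeric column per feature, row-aligned with
    ``meta``.  Both frames are re-indexed to a clean RangeIndex and
    validated on construction.
    """

    meta: pd.DataFrame
    features: pd.DataFrame

    def __post_init__(self) -> None:
        meta = self.meta.reset_index(drop=True)
        features = self.features.reset_index(drop=True)
        _validate(meta, features)
        object.__setattr__(self, "meta", meta)
        object.__setattr__(self, "features", features)

    # -- basic accessors -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.meta)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.meta["subject_id"].to_numpy()

    @property
    def ages(self) -> np.ndarray:
        return self.meta["age"].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        """Diagnosis coded 1 for AD, 0 for CN."""
        return (self.meta["group"].to_numpy() == "AD").astype(int)

    # -- row/column subsetting -------------------------------------------
    def take(self, positions: Sequence[int]) -> "FeatureTable":
        positions = np.asarray(positions, dtype=int)
        return FeatureTable(self.meta.iloc[positions], self.features.iloc[positions])

    def where(self, mask) -> "FeatureTable":
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_subjects,):
            raise FeatureTableError("boolean mask length does not match table")
        return self.take(np.flatnonzero(mask))

    def select_features(self, names: Sequence[str]) -> "FeatureTable":
        missing = [n for n in names if n not in self.features.columns]
        if missing:
            raise FeatureTableError(f"unknown feature columns: {missing}")
        return FeatureTable(self.meta, self.features[list(names)])

    def with_features(self, features: pd.DataFrame) -> "FeatureTable":
        return FeatureTable(self.meta, features)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [self.meta.reset_index(drop=True), self.features.reset_index(drop=True)],
            axis=1,
        )


def _validate(meta: pd.DataFrame, features: pd.DataFrame) -> None:
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise FeatureTableError(f"missing required metadata column(s): {missing}")
    if len(meta) != len(features):
        raise FeatureTableError("metadata and feature frames have different lengths")
    ids = meta["subject_id"].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise FeatureTableError(f"duplicate subject_id: {dupes}")
    if len(meta):
        bad_gender = set(meta["gender"].unique()) - set(GENDERS)
        if bad_gender:
            raise FeatureTableError(f"unknown gender code(s): {sorted(bad_gender)}")
        bad_group = set(meta["group"].unique()) - set(GROUPS)
        if bad_group:
            raise FeatureTableError(f"unknown group label(s): {sorted(bad_group)}")
        age = meta["age"].to_numpy(dtype=float)
        if not np.all(np.isfinite(age)) or np.any(age <= 0):
            raise FeatureTableError("age must be positive and finite for all subjects")
    if len(set(features.columns)) != features.shape[1]:
        raise FeatureTableError("duplicate feature column names")
    overlap = set(features.columns) & set(METADATA_COLUMNS)
    if overlap:
        raise FeatureTableError(f"feature names clash with metadata: {sorted(overlap)}")
    if features.shape[1]:
        values = features.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            nonnum = [
                c for c in features.columns
                if not np.issubdtype(features[c].dtype, np.number)
            ]
            raise FeatureTableError(f"non-numeric feature column(s): {nonnum}")
        if len(features) and not np.all(np.isfinite(values)):
            bad = [
                c for c in features.columns
                if not np.all(np.isfinite(features[c].to_numpy(dtype=float)))
            ]
            raise FeatureTableError(
                f"missing or non-finite feature values in column(s): {bad}"
            )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _separator_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def load_feature_table(
    path, schema: Mapping[str, str] | None = None
) -> FeatureTable:
    """Read a CSV/TSV feature table.

    ``schema`` maps canonical metadata names (``subject_id`` ...) to the
    column names actually used in the file; every column not named in the
    schema is treated as a feature.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_separator_for(path))
    if frame.empty:
        raise FeatureTableError(f"empty table: {path}")
    schema = dict(schema or {})
    rename = {}
    for canonical in METADATA_COLUMNS:
        actual = schema.get(canonical, canonical)
        if actual not in frame.columns:
            raise FeatureTableError(
                f"missing required column {actual!r} (for {canonical!r}) in {path}"
            )
        rename[actual] = canonical
    frame = frame.rename(columns=rename)
    feature_cols = [c for c in frame.columns if c not in METADATA_COLUMNS]
    features = frame[feature_cols]
    for col in feature_cols:
        try:
            features[col].astype(float)
        except (TypeError, ValueError) as exc:
            raise FeatureTableError(
                f"non-numeric feature cell in column {col!r}"
            ) from exc
    return FeatureTable(frame[list(METADATA_COLUMNS)], features.astype(float))


def write_feature_table(table: FeatureTable, path) -> None:
    path = Path(path)
    table.to_frame().to_csv(path, sep=_separator_for(path), index=False)


def split_by_gender(table: FeatureTable) -> tuple[FeatureTable, FeatureTable]:
    """Partition into (male, female) tables; union of rows equals input."""
    gender = table.meta["gender"].to_numpy()
    return table.where(gender == "M"), table.where(gender == "F")


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardizationModel:
    """Per-feature mean and (n-1)-denominator standard deviation.

    Fitted on a training partition; :func:`apply_standardizer` maps each
    feature x to (x - mean) / sd.  Metadata (including age) is untouched.
    """

    mean: pd.Series
    sd: pd.Series

    @property
    def feature_names(self) -> list[str]:
        return list(self.mean.index)

    def to_json(self) -> str:
        payload = {
            name: {"mean": float(self.mean[name]), "sd": float(self.sd[name])}
            for name in self.feature_names
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "StandardizationModel":
        payload = json.loads(text)
        names = list(payload)
        mean = pd.Series({n: payload[n]["mean"] for n in names}, dtype=float)
        sd = pd.Series({n: payload[n]["sd"] for n in names}, dtype=float)
        return cls(mean=mean[names], sd=sd[names])


def fit_standardizer(train: FeatureTable) -> StandardizationModel:
    if train.n_subjects < 2:
        raise FeatureTableError("need at least 2 training subjects to standardize")
    mean = train.features.mean(axis=0)
    sd = train.features.std(axis=0, ddof=1)
    # relative floor catches numerically-constant columns (sd ~ 1e-16 |mean|)
    floor = 1e-12 * np.maximum(1.0, mean.abs())
    degenerate = sd.index[(sd <= floor) | ~np.isfinite(sd)].tolist()
    if degenerate:
        raise FeatureTableError(f"zero-variance feature(s): {degenerate}")
    return StandardizationModel(mean=mean, sd=sd)


def apply_standardizer(
    model: StandardizationModel, table: FeatureTable
) -> FeatureTable:
    if table.feature_names != model.feature_names:
        raise FeatureTableError(
            "feature names do not match the standardization model"
        )
    z = (table.features - model.mean) / model.sd
    return table.with_features(z)
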
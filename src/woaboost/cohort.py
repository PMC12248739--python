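"""Reading, validating, one-hot encoding, and splitting the cohort table.

The cohort is a purely categorical table: 16 clinical features (demographics,
histopathology, TNM staging, treatment response) plus a binary recurrence
label.  Validation is strict — unknown category levels and missing cells are
errors, never silently recoded — because in this dataset every cell is
expected to be a known string and a mismatch signals corrupted input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import StratifiedKFold, train_test_split


class SchemaError(ValueError):
    """The table's column layout does not match the schema."""


class DataValidationError(ValueError):
    """A cell is missing or holds a level the schema does not know."""


@dataclass(frozen=True)
class CohortSchema:
    """Ordered feature → level-list mapping plus the target definition."""

    features: dict[str, list[str]]
    target: str
    target_levels: tuple[str, str]  # (negative, positive)
    version: int = 1

    def __post_init__(self) -> None:
        if len(set(self.features)) != len(self.features):
            raise SchemaError("feature names must be unique")
        for name, levels in self.features.items():
            if not levels:
                raise SchemaError(f"feature {name!r} has an empty level list")
            if len(set(levels)) != len(levels):
                raise SchemaError(f"feature {name!r} has duplicate levels")

    @property
    def feature_names(self) -> list[str]:
        return list(self.features)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def n_onehot_columns(self) -> int:
        return sum(len(v) for v in self.features.values())

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "CohortSchema":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls._from_mapping(raw)

    @classmethod
    def _from_mapping(cls, raw: dict) -> "CohortSchema":
        features = {str(k): [str(v) for v in vals] for k, vals in raw["features"].items()}
        tgt = raw["target"]
        levels = [str(v) for v in tgt["levels"]]
        if len(levels) != 2:
            raise SchemaError("target must have exactly two levels")
        return cls(
            features=features,
            target=str(tgt["name"]),
            target_levels=(levels[0], levels[1]),
            version=int(raw.get("version", 1)),
        )


def default_schema() -> CohortSchema:
    """The packaged DTC recurrence schema (16 features, target 'Recurred')."""
    ref = resources.files("woaboost").joinpath("schema/dtc_schema.yaml")
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return CohortSchema._from_mapping(raw)


@dataclass
class CategoricalCohort:
    """Validated categorical feature table with 0/1 label vector."""

    frame: pd.DataFrame        # feature columns only, schema order
    target: np.ndarray         # int {0,1}, 1 = recurrence
    schema: CohortSchema

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def n_positive(self) -> int:
        return int(self.target.sum())

    def subset(self, idx: np.ndarray) -> "CategoricalCohort":
        return CategoricalCohort(
            frame=self.frame.iloc[idx].reset_index(drop=True),
            target=self.target[np.asarray(idx)],
            schema=self.schema,
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        out = self.frame.copy()
        neg, pos = self.schema.target_levels
        out[self.schema.target] = np.where(self.target == 1, pos, neg)
        out.to_csv(path, index=False)


@dataclass
class EncodedMatrix:
    """Full one-hot indicator matrix with its (feature, level) column map."""

    matrix: np.ndarray                       # (n, n_onehot) float 0/1
    columns: list[tuple[str, str]]           # (source feature, level)

    @property
    def column_names(self) -> list[str]:
        return [f"{f}={lvl}" for f, lvl in self.columns]

    def feature_column_indices(self, feature: str) -> list[int]:
        idx = [i for i, (f, _) in enumerate(self.columns) if f == feature]
        if not idx:
            raise KeyError(f"no columns for feature {feature!r}")
        return idx

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.column_names)


def validate_cohort(frame: pd.DataFrame, schema: CohortSchema) -> None:
    missing = [c for c in schema.feature_names + [schema.target] if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    for col in schema.feature_names + [schema.target]:
        series = frame[col]
        na = series.isna() | (series.astype(str).str.strip() == "")
        if na.any():
            row = int(np.flatnonzero(na.to_numpy())[0])
            raise DataValidationError(f"missing value at row {row}, column {col!r}")
    for col in schema.feature_names:
        allowed = set(schema.features[col])
        seen = set(frame[col].astype(str).str.strip())
        unknown = sorted(seen - allowed)
        if unknown:
            raise DataValidationError(
                f"unknown levels in column {col!r}: {unknown}; allowed: {sorted(allowed)}"
            )
    allowed_t = set(schema.target_levels)
    seen_t = set(frame[schema.target].astype(str).str.strip())
    unknown_t = sorted(seen_t - allowed_t)
    if unknown_t:
        raise DataValidationError(
            f"unknown target levels: {unknown_t}; allowed: {sorted(allowed_t)}"
        )


def cohort_from_frame(frame: pd.DataFrame, schema: CohortSchema) -> CategoricalCohort:
    """Validate a raw table (strings trimmed, exact level matching) into a cohort."""
    frame = frame.copy()
    for col in frame.columns:
        frame[col] = frame[col].astype(str).str.strip()
    validate_cohort(frame, schema)
    target = (frame[schema.target] == schema.target_levels[1]).to_numpy(dtype=int)
    return CategoricalCohort(
        frame=frame[schema.feature_names].reset_index(drop=True),
        target=target,
        schema=schema,
    )


def read_cohort_csv(
    path: Union[str, Path], schema: Optional[CohortSchema] = None
) -> CategoricalCohort:
    """Load and validate a cohort CSV (UTF-8, header row, schema column set)."""
    if schema is None:
        schema = default_schema()
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    return cohort_from_frame(frame, schema)


def one_hot_encode(
    cohort: CategoricalCohort, schema: Optional[CohortSchema] = None
) -> EncodedMatrix:
    """Full (non-dropped) indicator encoding in schema feature × level order.

    Tree ensembles are unaffected by the resulting collinearity, and keeping
    every level makes the encoding invertible: per feature the indicator block
    sums to exactly 1 on every row.
    """
    if schema is None:
        schema = cohort.schema
    columns: list[tuple[str, str]] = []
    blocks: list[np.ndarray] = []
    for feat, levels in schema.features.items():
        vals = cohort.frame[feat].to_numpy()
        for lvl in levels:
            columns.append((feat, lvl))
            blocks.append((vals == lvl).astype(float))
    return EncodedMatrix(matrix=np.column_stack(blocks), columns=columns)


def decode_one_hot(enc: EncodedMatrix, schema: CohortSchema) -> pd.DataFrame:
    """Invert :func:`one_hot_encode` (round trip used as a codec check)."""
    n = enc.matrix.shape[0]
    out: dict[str, list[str]] = {}
    for feat, levels in schema.features.items():
        idx = enc.feature_column_indices(feat)
        block = enc.matrix[:, idx]
        if not np.all(block.sum(axis=1) == 1):
            raise DataValidationError(f"indicator block for {feat!r} is not one-hot")
        lvl_of = [enc.columns[i][1] for i in idx]
        out[feat] = [lvl_of[j] for j in np.argmax(block, axis=1)]
    return pd.DataFrame(out, index=range(n))


def stratified_split(
    cohort: CategoricalCohort, test_fraction: float = 0.25, seed: int = 0
) -> tuple[CategoricalCohort, CategoricalCohort]:
    """Disjoint, exhaustive, label-stratified train/test partition."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly in (0, 1)")
    counts = np.bincount(cohort.target, minlength=2)
    if (counts < 2).any():
        raise ValueError("both classes need at least 2 members to split")
    idx = np.arange(cohort.n)
    train_idx, test_idx = train_test_split(
        idx,
        test_size=test_fraction,
        random_state=seed,
        stratify=cohort.target,
    )
    return cohort.subset(np.sort(train_idx)), cohort.subset(np.sort(test_idx))


def stratified_kfold(
    y: Union[CategoricalCohort, np.ndarray, Sequence[int]],
    k: int = 5,
    seed: int = 0,
) -> list[np.ndarray]:
    """Return k disjoint, exhaustive, class-balanced test-index sets."""
    if isinstance(y, CategoricalCohort):
        y = y.target
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be at least 2")
    counts = np.bincount(y, minlength=2)
    if (counts[counts > 0] < k).any():
        raise ValueError(f"every class needs at least k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros_like(y), y)]
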
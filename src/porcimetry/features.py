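"""Tabular feature pipeline: cleaning, encoding, imputation, row
normalization, correlation and variance-threshold feature selection.

Cleaning derives ``Age`` in whole days from the determination and birth
dates, one-hot encodes gender and breed, and imputes missing heights with
the median of the observed heights.  Normalization divides each feature row
by the Euclidean norm of the full 11-value row *including the weight*; the
weight label itself is kept on the raw kilogram scale for training.  (This
row convention — the default of sklearn's ``normalize`` applied to the full
table — is the one that reproduces the published worked example to four
decimals; note it makes each feature row depend on its own label, a leakage
the original protocol carries.  ``include_weight_in_norm=False`` gives the
leakage-free variant.)

The sklearn-style transformers (`PigRecordCleaner`, `RowL2Normalizer`,
`VarianceFeatureSelector`) wrap the module functions so the table pipeline
composes with sklearn tooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_selection import VarianceThreshold

from .errors import (
    ImputationError,
    InvalidParameterError,
    InvalidRecordError,
    NormalizationError,
    UndefinedCorrelationError,
)

__all__ = [
    "FEATURE_COLUMNS",
    "LABEL_COLUMN",
    "FeatureSelection",
    "clean_records",
    "row_norms",
    "normalize_rows",
    "correlation_matrix",
    "variance_filter",
    "feature_set",
    "example_records",
    "PigRecordCleaner",
    "RowL2Normalizer",
    "VarianceFeatureSelector",
]

FEATURE_COLUMNS = [
    "Chest", "Abdomen", "Waist", "Length", "Height",
    "Female", "Male", "S21", "S23", "Age",
]
LABEL_COLUMN = "Weight"

_MODEL_FEATURES = {
    1: list(FEATURE_COLUMNS),
    2: ["Height", "Chest", "Abdomen", "Waist"],
    3: ["Abdomen", "Age"],
    4: ["Length", "Age", "Chest", "Abdomen", "Waist"],
}


def _canon(name: str) -> str:
    return str(name).strip().lower().replace(" ", "_")


def clean_records(records: pd.DataFrame, height_median: float | None = None) -> pd.DataFrame:
    """Clean raw herd records into the 10-feature + weight table.

    ``Age`` is the whole-day difference between determination and birth
    dates; gender and breed become one-hot pairs; missing heights are
    imputed with the median observed height (of this table, unless a
    ``height_median`` learned elsewhere is supplied).
    """
    if len(records) == 0:
        raise InvalidParameterError("records table is empty")
    df = records.copy()
    df.columns = [_canon(c) for c in df.columns]

    det = pd.to_datetime(df["determination_date"])
    birth = pd.to_datetime(df["birth_date"])
    age = (det - birth).dt.days
    if (age < 0).any():
        bad = int((age < 0).sum())
        raise InvalidRecordError(f"{bad} record(s) have determination before birth")

    gender = df["gender"].astype(str).str.strip().str.lower()
    if not gender.isin(["female", "male"]).all():
        raise InvalidRecordError("gender must be 'female' or 'male'")
    breed = df["breed"].astype(str).str.strip().str.upper()
    if not breed.isin(["S21", "S23"]).all():
        raise InvalidRecordError("breed must be 'S21' or 'S23'")

    height = pd.to_numeric(df["height"], errors="coerce")
    if height.isna().all() and height_median is None:
        raise ImputationError("every height is missing; median imputation impossible")
    median = float(np.nanmedian(height)) if height_median is None else float(height_median)
    height = height.fillna(median)

    out = pd.DataFrame(
        {
            "Chest": pd.to_numeric(df["chest"]).astype(float),
            "Abdomen": pd.to_numeric(df["abdominal"]).astype(float),
            "Waist": pd.to_numeric(df["waist"]).astype(float),
            "Length": pd.to_numeric(df["length"]).astype(float),
            "Height": height.astype(float),
            "Female": (gender == "female").astype(float),
            "Male": (gender == "male").astype(float),
            "S21": (breed == "S21").astype(float),
            "S23": (breed == "S23").astype(float),
            "Age": age.astype(float),
            "Weight": pd.to_numeric(df["weight"]).astype(float),
        }
    )
    for col in ("Chest", "Abdomen", "Waist", "Length", "Height"):
        if (out[col] <= 0).any():
            raise InvalidRecordError(f"non-positive {col} measurement")
    return out.reset_index(drop=True)


def row_norms(table: pd.DataFrame, include_weight: bool = True) -> np.ndarray:
    cols = FEATURE_COLUMNS + [LABEL_COLUMN] if include_weight else FEATURE_COLUMNS
    return np.linalg.norm(table[cols].to_numpy(dtype=float), axis=1)


def normalize_rows(table: pd.DataFrame, include_weight_in_norm: bool = True) -> pd.DataFrame:
    """Row-wise L2 normalization of the features; the weight label stays raw."""
    norms = row_norms(table, include_weight=include_weight_in_norm)
    if np.any(norms == 0):
        raise NormalizationError("zero-norm row cannot be normalized")
    out = table.copy()
    out[FEATURE_COLUMNS] = table[FEATURE_COLUMNS].to_numpy(dtype=float) / norms[:, None]
    return out


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation over the 10 features plus the weight."""
    cols = FEATURE_COLUMNS + [LABEL_COLUMN]
    if len(table) < 2:
        raise InvalidParameterError("need at least 2 rows for correlation")
    data = table[cols].to_numpy(dtype=float)
    stds = data.std(axis=0)
    constant = [c for c, s in zip(cols, stds) if s == 0]
    if constant:
        raise UndefinedCorrelationError(
            f"correlation undefined for constant column(s) {constant}"
        )
    return pd.DataFrame(np.corrcoef(data, rowvar=False), index=cols, columns=cols)


@dataclass(frozen=True)
class FeatureSelection:
    """Per-feature variance, the threshold, and the retained features."""

    variances: pd.Series
    threshold: float
    retained: list[str]


def variance_filter(table: pd.DataFrame, threshold: float) -> FeatureSelection:
    """Retain features whose population variance strictly exceeds the
    threshold (applied to a normalized table in the reference protocol)."""
    x = table[FEATURE_COLUMNS].to_numpy(dtype=float)
    vt = VarianceThreshold(threshold=threshold).fit(x)
    variances = pd.Series(vt.variances_, index=FEATURE_COLUMNS)
    retained = [c for c, v in variances.items() if v > threshold]
    return FeatureSelection(variances=variances, threshold=float(threshold), retained=retained)


def feature_set(model_id: int) -> list[str]:
    """Feature lists of the four weight-model variants.

    Model 1 uses all ten features; model 2 the height plus the three
    circumferences; model 3 just abdominal circumference and age; model 4
    length, age and the three circumferences.
    """
    try:
        return list(_MODEL_FEATURES[model_id])
    except (KeyError, TypeError):
        raise InvalidParameterError(f"unknown model id {model_id!r}; expected 1-4") from None


def example_records() -> pd.DataFrame:
    """Five cleaned example records used in the worked example.

    First five records of the herd study's cleaned table (measures in cm,
    age in days, weight in kg).
    """
    rows = [
        (110.0, 115.0, 107.0, 120.0, 63.0, 1.0, 0.0, 1.0, 0.0, 193.0, 113.5),
        (105.0, 116.0, 106.0, 119.0, 63.0, 1.0, 0.0, 1.0, 0.0, 192.0, 111.4),
        (109.0, 120.0, 104.0, 125.0, 63.0, 1.0, 0.0, 1.0, 0.0, 194.0, 114.6),
        (105.0, 112.0, 100.0, 123.0, 63.0, 1.0, 0.0, 1.0, 0.0, 192.0, 111.8),
        (107.0, 116.0, 106.0, 118.0, 63.0, 1.0, 0.0, 1.0, 0.0, 189.0, 114.2),
    ]
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS + [LABEL_COLUMN])


# ---------------------------------------------------------------------------
# sklearn-style transformers


class PigRecordCleaner(BaseEstimator, TransformerMixin):
    """Transformer wrapper around :func:`clean_records`.

    ``fit`` learns the height median; set ``use_fitted_median=True`` for a
    strict train-only imputation instead of the default whole-table median.
    """

    def __init__(self, use_fitted_median: bool = False):
        self.use_fitted_median = use_fitted_median

    def fit(self, X: pd.DataFrame, y=None):
        df = X.copy()
        df.columns = [_canon(c) for c in df.columns]
        height = pd.to_numeric(df["height"], errors="coerce")
        if height.isna().all():
            raise ImputationError("every height is missing; cannot fit a median")
        self.height_median_ = float(np.nanmedian(height))
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        median = self.height_median_ if self.use_fitted_median else None
        return clean_records(X, height_median=median)


class RowL2Normalizer(BaseEstimator, TransformerMixin):
    """Stateless transformer wrapper around :func:`normalize_rows`."""

    def __init__(self, include_weight_in_norm: bool = True):
        self.include_weight_in_norm = include_weight_in_norm

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return normalize_rows(X, include_weight_in_norm=self.include_weight_in_norm)


class VarianceFeatureSelector(BaseEstimator, TransformerMixin):
    """Variance-threshold feature selection over the 10 feature columns."""

    def __init__(self, threshold: float = 0.0):
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y=None):
        selection = variance_filter(X, self.threshold)
        self.variances_ = selection.variances
        self.retained_ = selection.retained
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        cols = self.retained_ + ([LABEL_COLUMN] if LABEL_COLUMN in X.columns else [])
        return X[cols]
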
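"""Constant-feature filtering, z-score normalization, and class labels.

Normalization is the usual z-score, x' = (x - mu) / sigma, with mu and
sigma computed per feature over ALL peptides in the family-specific
matrix (target and non-target alike).  Sigma uses the sample convention
(ddof=1) by default.  Constant features are removed first so sigma is
never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import FeatureMatrix


@dataclass
class NormalizationParams:
    """Per-feature mean and standard deviation, for projecting new data."""

    mean: pd.Series
    std: pd.Series
    ddof: int = 1

    def transform(self, data: pd.DataFrame) -> pd.DataFrame:
        return (data[self.mean.index] - self.mean) / self.std


@dataclass
class LabeledMatrix:
    """Numeric matrix plus the binary target / non-target labels.

    ``X`` is peptides x features, ``y`` is True for members of the family
    under study.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    peptide_ids: list[str]

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.peptide_ids), len(self.feature_names)):
            raise ValueError("shape mismatch")
        if not (self.y.any() and (~self.y).any()):
            raise ValueError("need at least one target and one non-target row")


def filter_constant(
    matrix: FeatureMatrix,
) -> tuple[FeatureMatrix, list[str]]:
    """Drop features constant across all peptides; report what was removed."""
    if matrix.data.shape[0] < 2:
        raise ValueError("need at least 2 peptides to detect constants")
    nunique = matrix.data.nunique(axis=0)
    removed = [c for c in matrix.data.columns if nunique[c] < 2]
    if len(removed) == matrix.data.shape[1]:
        raise ValueError("all features are constant")
    kept = matrix.data.drop(columns=removed)
    return FeatureMatrix(data=kept, labels=matrix.labels), removed


def normalize(
    matrix: FeatureMatrix, ddof: int = 1
) -> tuple[FeatureMatrix, NormalizationParams]:
    """Z-score each feature across all peptides.

    Requires constant features to have been filtered; raises if any
    feature still has zero standard deviation.
    """
    mean = matrix.data.mean(axis=0)
    std = matrix.data.std(axis=0, ddof=ddof)
    if (std == 0).any():
        bad = list(std.index[std == 0])[:5]
        raise ValueError(f"zero-variance features (filter first): {bad}")
    params = NormalizationParams(mean=mean, std=std, ddof=ddof)
    return (
        FeatureMatrix(data=params.transform(matrix.data), labels=matrix.labels),
        params,
    )


def make_labeled(matrix: FeatureMatrix, target_family: str) -> LabeledMatrix:
    """Attach binary target labels for the family under study."""
    if matrix.labels is None:
        raise ValueError("matrix carries no family labels")
    y = (matrix.labels == target_family).to_numpy()
    return LabeledMatrix(
        X=matrix.data.to_numpy(dtype=float),
        y=y,
        feature_names=list(matrix.data.columns),
        peptide_ids=list(matrix.data.index),
    )


def prepare(
    matrix: FeatureMatrix, target_family: str, ddof: int = 1
) -> tuple[LabeledMatrix, NormalizationParams, list[str]]:
    """filter_constant -> normalize -> label, in one call."""
    filtered, removed = filter_constant(matrix)
    normed, params = normalize(filtered, ddof=ddof)
    return make_labeled(normed, target_family), params, removed
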
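"""Probe filtering and centering that define the clustering input.

Three steps, applied in order: drop low-signal probes (mean intensity
below a log2 threshold, default 5.8), keep the most variable probes
(default 1,652, the count behind the discovery clustering), and mean
center every probe across samples.  Ties in variability are broken by
feature id so the selection is reproducible across platforms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import ExpressionMatrix

__all__ = [
    "LowSignalFilter",
    "TopVariableSelector",
    "GeneMeanCenterer",
    "filter_low_signal",
    "select_top_variable",
    "mean_center_genes",
    "clustering_input",
]


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))


class LowSignalFilter(TransformerMixin, BaseEstimator):
    """Drop features whose mean across samples is below ``threshold``.

    The boundary is inclusive: a feature with mean exactly at the
    threshold is retained.
    """

    def __init__(self, threshold: float = 5.8):
        self.threshold = threshold

    def fit(self, X, y=None):
        X = _as_frame(X)
        means = X.mean(axis=0)
        self.support_ = (means >= self.threshold).to_numpy()
        self.feature_names_out_ = X.columns[self.support_]
        if not self.support_.any():
            raise ValueError(f"low-signal filter at {self.threshold} removed every feature")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = _as_frame(X)
        return X.loc[:, self.support_]

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "support_")
        return np.asarray(self.feature_names_out_, dtype=object)


class TopVariableSelector(TransformerMixin, BaseEstimator):
    """Keep the ``k`` most variable features (SD or IQR), deterministic ties.

    Ties in the variability measure are broken by feature id in
    lexicographic order, so repeated runs and column-permuted inputs give
    the same selection.
    """

    def __init__(self, k: int = 1652, measure: str = "sd"):
        self.k = k
        self.measure = measure

    def fit(self, X, y=None):
        X = _as_frame(X)
        if self.k > X.shape[1]:
            raise ValueError(f"k={self.k} exceeds the {X.shape[1]} available features")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.measure == "sd":
            variability = X.std(axis=0, ddof=1)
        elif self.measure == "iqr":
            variability = X.quantile(0.75) - X.quantile(0.25)
        else:
            raise ValueError(f"unknown variability measure {self.measure!r}")
        order = sorted(X.columns, key=lambda f: (-variability[f], str(f)))
        sel = set(order[: self.k])
        # selected features keep their original column order
        self.selected_features_ = pd.Index([f for f in X.columns if f in sel])
        self.variability_ = variability
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_features_")
        X = _as_frame(X)
        return X.loc[:, self.selected_features_]

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "selected_features_")
        return np.asarray(self.selected_features_, dtype=object)


class GeneMeanCenterer(TransformerMixin, BaseEstimator):
    """Subtract each feature's mean across the samples it is fit on."""

    def fit(self, X, y=None):
        X = _as_frame(X)
        self.means_ = X.mean(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "means_")
        X = _as_frame(X)
        return X - self.means_


# ---------------------------------------------------------------------------
# ExpressionMatrix wrappers
# ---------------------------------------------------------------------------


def filter_low_signal(matrix: ExpressionMatrix, threshold: float = 5.8) -> ExpressionMatrix:
    """Retain features with mean >= threshold across all samples."""
    est = LowSignalFilter(threshold).fit(matrix.samples_by_features())
    return matrix.subset_features(est.feature_names_out_)


def select_top_variable(matrix: ExpressionMatrix, k: int = 1652, measure: str = "sd") -> ExpressionMatrix:
    """Keep the k most variable features (ties by feature id)."""
    est = TopVariableSelector(k, measure).fit(matrix.samples_by_features())
    return matrix.subset_features(est.selected_features_)


def mean_center_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Center each feature to mean zero across samples."""
    centered = matrix.values.sub(matrix.values.mean(axis=1), axis=0)
    return matrix.with_values(centered)


def clustering_input(
    matrix: ExpressionMatrix,
    threshold: float = 5.8,
    k: int = 1652,
    measure: str = "sd",
    quality_filter: bool = False,
) -> ExpressionMatrix:
    """The standard filter -> select -> center composition.

    ``quality_filter`` restricts to probes annotated with good or perfect
    annotation quality first (optional; the discovery clustering itself
    does not require it).
    """
    if quality_filter and matrix.feature_annot is not None and "quality" in matrix.feature_annot.columns:
        q = matrix.feature_annot["quality"].reindex(matrix.feature_ids)
        keep = matrix.feature_ids[q.isin(["good", "perfect"]).to_numpy()]
        matrix = matrix.subset_features(keep)
    out = filter_low_signal(matrix, threshold)
    k_eff = min(k, out.n_features)
    out = select_top_variable(out, k_eff, measure)
    return mean_center_genes(out)
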
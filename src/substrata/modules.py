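"""Signed gene-module scores and between-subgroup association statistics.

The module score of a sample is the weighted mean of the module's genes,

    m.s. = sum_i w_i x_i / sum_i |w_i|,   w_i in {+1, -1},

so a module whose up-genes are high and down-genes low scores high.  The
denominator uses |w_i|: with signed unit weights the plain sum of weights
can be zero or negative, whereas |w_i| makes the score a proper signed
average on the log2 expression scale.  Genes missing from the matrix are
dropped and reflected in the reported coverage.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import ExpressionMatrix, GeneSetCollection, normalize_symbol

logger = logging.getLogger("substrata")

__all__ = [
    "ModuleScorer",
    "compute_module_score",
    "module_score_table",
    "compare_scores_two_groups",
    "fisher_association",
]


def _score_frame(expr_by_symbol: pd.DataFrame, members: dict[str, int]) -> tuple[pd.Series, float]:
    weights = {normalize_symbol(g): w for g, w in members.items()}
    matched = [g for g in weights if g in expr_by_symbol.index]
    coverage = len(matched) / len(weights) if weights else 0.0
    if not matched:
        raise ValueError("no module genes matched the expression matrix")
    w = np.array([weights[g] for g in matched], dtype=float)
    X = expr_by_symbol.loc[matched].to_numpy()
    scores = (w @ X) / np.abs(w).sum()
    return pd.Series(scores, index=expr_by_symbol.columns, name="score"), coverage


def _by_symbol(matrix: ExpressionMatrix) -> pd.DataFrame:
    df = matrix.values.copy()
    df.index = matrix.symbols().to_numpy()
    if df.index.has_duplicates:
        df = df.groupby(level=0).mean()
    return df


def compute_module_score(matrix: ExpressionMatrix, module: dict[str, int]) -> tuple[pd.Series, float]:
    """Per-sample score for one signed module; returns (scores, coverage)."""
    return _score_frame(_by_symbol(matrix), module)


def module_score_table(matrix: ExpressionMatrix, collection: GeneSetCollection) -> tuple[pd.DataFrame, pd.Series]:
    """Scores for every module: (samples x modules table, per-module coverage)."""
    expr = _by_symbol(matrix)
    scores, coverage = {}, {}
    for name in collection:
        scores[name], coverage[name] = _score_frame(expr, collection[name])
    return pd.DataFrame(scores), pd.Series(coverage, name="coverage")


class ModuleScorer(TransformerMixin, BaseEstimator):
    """Transform samples x genes expression into samples x modules scores."""

    def __init__(self, gene_sets: GeneSetCollection | dict | None = None):
        self.gene_sets = gene_sets

    def fit(self, X, y=None):
        if self.gene_sets is None:
            raise ValueError("gene_sets is required")
        gs = self.gene_sets
        self.collection_ = gs if isinstance(gs, GeneSetCollection) else GeneSetCollection(dict(gs))
        X_df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        self.n_features_in_ = X_df.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "collection_")
        X_df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        table, self.coverage_ = module_score_table(ExpressionMatrix(X_df.T), self.collection_)
        return table

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "collection_")
        return np.asarray(list(self.collection_.sets), dtype=object)


def compare_scores_two_groups(scores, labels) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of scores between two groups.

    Exact enumeration when both groups have <= 10 observations and no
    ties; otherwise the tie-corrected normal approximation (no continuity
    correction, so identical multisets give p = 1 exactly).  Returns the
    Mann-Whitney U of the first (sorted) group and the p-value.
    """
    scores = pd.Series(np.asarray(scores, dtype=float))
    labels = pd.Series(np.asarray(labels), index=scores.index)
    groups = sorted(labels.unique(), key=str)
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    a = scores[(labels == groups[0]).to_numpy()].to_numpy()
    b = scores[(labels == groups[1]).to_numpy()].to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if max(len(a), len(b)) <= 10 and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", use_continuity=False)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def fisher_association(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 count table.

    Returns the conditional-MLE odds ratio and the two-sided p (sum of
    hypergeometric probabilities of tables at most as probable as the
    observed one).  Any zero margin gives p = 1.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if not np.allclose(t, np.round(t)) or (t < 0).any() or t.shape != (2, 2):
            raise ValueError("expected a 2x2 table of non-negative integers")
        t = np.round(t).astype(int)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    if t.sum() == 0 or (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return float("nan"), 1.0
    odds = stats.contingency.odds_ratio(t, kind="conditional").statistic
    return float(odds), float(p)
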
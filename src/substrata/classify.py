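"""Nearest-centroid subtype classification.

A centroid is the per-class mean of gene-centered expression over a fixed
gene list (for subtype discovery: the top SAM genes ranked by |d|).  Test
samples are centered with their own cohort's gene means — each dataset is
centered separately — and assigned to the class whose centroid they
correlate with most, or left unclassified when the best correlation falls
below the cutoff (default 0.2) or ties exactly.

Includes the builder for an ER+ luminal A/B classifier from a reference
female-breast-cancer cohort: subset to ER+ samples, center, SAM A vs B,
keep the top FDR-0 genes, and compute per-class centroids.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .io import ExpressionMatrix, normalize_symbol
from .sam import sam_two_class, significant_genes, top_genes_by_d

logger = logging.getLogger("substrata")

__all__ = [
    "CentroidSet",
    "ClassificationResult",
    "NearestCentroidSubtype",
    "build_centroids",
    "nearest_centroid_classify",
    "build_er_luminal_classifier",
    "write_centroids",
    "read_centroids",
]

UNCLASSIFIED = "unclassified"


@dataclass
class CentroidSet:
    """Per-class mean-centered reference profiles over one gene list."""

    profiles: pd.DataFrame  # genes (normalized symbols) x classes
    cutoff: float = 0.2
    source: str = ""
    training_gene_means: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.profiles.columns.has_duplicates:
            raise ValueError("duplicate class names in centroid set")
        self.profiles.index = pd.Index([normalize_symbol(g) for g in self.profiles.index])

    @property
    def classes(self) -> list[str]:
        return list(self.profiles.columns)

    @property
    def genes(self) -> pd.Index:
        return self.profiles.index


@dataclass
class ClassificationResult:
    assigned: pd.Series  # class label or "unclassified" per sample
    correlations: pd.DataFrame  # samples x classes
    gene_overlap: float  # fraction of centroid genes found in the test matrix

    def proportions(self, include_unclassified: bool = True) -> pd.Series:
        counts = self.assigned.value_counts()
        if not include_unclassified:
            counts = counts.drop(UNCLASSIFIED, errors="ignore")
        return counts / counts.sum()


def _collapse_by_symbol(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Feature matrix re-keyed by normalized symbol (duplicates averaged)."""
    df = matrix.values.copy()
    df.index = matrix.symbols().to_numpy()
    if df.index.has_duplicates:
        df = df.groupby(level=0).mean()
    return df


def build_centroids(
    matrix: ExpressionMatrix,
    labels,
    genes=None,
    cutoff: float = 0.2,
    source: str = "",
) -> CentroidSet:
    """Per-class centroids of gene-centered training expression.

    ``genes`` (symbols) restricts the profile; genes absent from the
    matrix are dropped with a warning.  Every class needs >= 2 members.
    """
    labels = pd.Series(np.asarray(labels), index=matrix.sample_ids).astype(str)
    counts = labels.value_counts()
    if (counts < 2).any():
        small = list(counts.index[counts < 2])
        raise ValueError(f"every class needs >= 2 members; offending: {small}")
    expr = _collapse_by_symbol(matrix)
    if genes is not None:
        wanted = pd.Index([normalize_symbol(g) for g in genes])
        missing = wanted.difference(expr.index)
        if len(missing) == len(wanted):
            raise ValueError("none of the requested centroid genes are present in the matrix")
        if len(missing):
            logger.warning("%d/%d centroid genes absent from the matrix; dropped", len(missing), len(wanted))
        expr = expr.loc[wanted.intersection(expr.index)]
    gene_means = expr.mean(axis=1)
    centered = expr.sub(gene_means, axis=0)
    profiles = pd.DataFrame(
        {cls: centered.loc[:, (labels == cls).to_numpy()].mean(axis=1) for cls in sorted(counts.index)}
    )
    return CentroidSet(profiles, cutoff=cutoff, source=source, training_gene_means=gene_means)


def _correlate(profile_matrix: pd.DataFrame, centroids: pd.DataFrame, method: str) -> pd.DataFrame:
    """Columns of ``profile_matrix`` (samples) vs columns of ``centroids``."""
    A = profile_matrix.to_numpy(dtype=float)
    B = centroids.to_numpy(dtype=float)
    if method == "spearman":
        A = np.apply_along_axis(rankdata, 0, A)
        B = np.apply_along_axis(rankdata, 0, B)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    denom = np.outer(np.sqrt((A**2).sum(axis=0)), np.sqrt((B**2).sum(axis=0)))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (A.T @ B) / denom
    return pd.DataFrame(corr, index=profile_matrix.columns, columns=centroids.columns)


def nearest_centroid_classify(
    matrix: ExpressionMatrix,
    centroids: CentroidSet,
    cutoff: float | None = None,
    min_overlap: float = 0.5,
    method: str = "pearson",
) -> ClassificationResult:
    """Correlation-based assignment against a centroid set.

    Test profiles are centered with the test cohort's own gene means over
    the shared genes.  ``cutoff=None`` uses the centroid set's stored
    cutoff; pass a negative cutoff to force an assignment for every
    sample.  An exact tie at the maximum leaves the sample unclassified.
    """
    cutoff = centroids.cutoff if cutoff is None else cutoff
    expr = _collapse_by_symbol(matrix)
    shared = centroids.genes.intersection(expr.index)
    overlap = len(shared) / len(centroids.genes)
    if overlap < min_overlap:
        raise ValueError(
            f"gene overlap {overlap:.2f} below the minimum {min_overlap:.2f} "
            f"({len(shared)}/{len(centroids.genes)} centroid genes present)"
        )
    logger.info("classifying with %d/%d centroid genes (overlap %.2f)", len(shared), len(centroids.genes), overlap)
    test = expr.loc[shared]
    test = test.sub(test.mean(axis=1), axis=0)  # each dataset centered separately
    corr = _correlate(test, centroids.profiles.loc[shared], method)

    assigned = []
    for sample, row in corr.iterrows():
        best = row.max()
        if not np.isfinite(best) or best < cutoff:
            assigned.append(UNCLASSIFIED)
        elif (row == best).sum() > 1:
            logger.warning("sample %r ties between centroids %s; unclassified", sample, list(row.index[row == best]))
            assigned.append(UNCLASSIFIED)
        else:
            assigned.append(row.idxmax())
    return ClassificationResult(
        pd.Series(assigned, index=corr.index, name="class"), corr, overlap
    )


class NearestCentroidSubtype(ClassifierMixin, BaseEstimator):
    """scikit-learn wrapper: fit builds centroids, predict classifies.

    X is samples x genes (columns = gene symbols).  ``predict`` centers
    the test cohort with its own gene means, mirroring how independent
    datasets are classified.
    """

    def __init__(self, cutoff: float = 0.2, genes=None, method: str = "pearson", min_overlap: float = 0.5):
        self.cutoff = cutoff
        self.genes = genes
        self.method = method
        self.min_overlap = min_overlap

    def fit(self, X, y):
        X_df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        matrix = ExpressionMatrix(X_df.T)
        self.centroids_ = build_centroids(matrix, pd.Series(np.asarray(y), index=X_df.index), genes=self.genes,
                                          cutoff=self.cutoff)
        self.classes_ = np.asarray(self.centroids_.classes)
        self.n_features_in_ = X_df.shape[1]
        return self

    def _classify(self, X) -> ClassificationResult:
        check_is_fitted(self, "centroids_")
        X_df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        matrix = ExpressionMatrix(X_df.T)
        return nearest_centroid_classify(
            matrix, self.centroids_, cutoff=self.cutoff, min_overlap=self.min_overlap, method=self.method
        )

    def predict(self, X):
        return self._classify(X).assigned.to_numpy()

    def decision_function(self, X):
        return self._classify(X).correlations.to_numpy()


def build_er_luminal_classifier(
    fbc_matrix: ExpressionMatrix,
    er_status,
    luminal_labels,
    n_genes: int = 300,
    n_perm: int = 500,
    seed: int | None = None,
    cutoff: float = 0.2,
) -> CentroidSet:
    """ER+ luminal A/B centroid classifier from a reference cohort.

    ER+ samples are extracted, genes mean-centered across them, a SAM
    A-vs-B run selects the top ``n_genes`` FDR-0 genes by |d| (all of
    them, with a warning, if fewer pass), and per-class centroids are
    computed over those genes.
    """
    er_status = pd.Series(np.asarray(er_status), index=fbc_matrix.sample_ids).astype(str)
    er_pos = fbc_matrix.sample_ids[(er_status == "pos").to_numpy()]
    sub = fbc_matrix.subset_samples(er_pos)
    lum = pd.Series(np.asarray(luminal_labels), index=fbc_matrix.sample_ids).astype(str).loc[er_pos]
    present = sorted(lum.dropna().unique())
    if len(present) != 2 or (lum.value_counts() < 2).any():
        raise ValueError(f"ER+ subset must contain both luminal classes with >= 2 samples, got {present}")
    centered = sub.with_values(sub.values.sub(sub.values.mean(axis=1), axis=0))
    result = sam_two_class(centered, lum, n_perm=n_perm, seed=seed)
    up, down = significant_genes(result, 0.0)
    n_pass = len(up) + len(down)
    if n_pass < n_genes:
        logger.warning("only %d FDR-0 genes available (requested %d); using all", n_pass, n_genes)
    chosen = top_genes_by_d(result, min(n_genes, n_pass), 0.0)
    sym = centered.symbols()
    gene_syms = [sym[g] for g in chosen]
    return build_centroids(centered, lum, genes=gene_syms, cutoff=cutoff, source="ER+ luminal A/B reference")


# ---------------------------------------------------------------------------
# Serialization (TSV profile table + JSON metadata sidecar)
# ---------------------------------------------------------------------------


def write_centroids(centroids: CentroidSet, prefix) -> None:
    prefix = Path(prefix)
    centroids.profiles.to_csv(prefix.with_suffix(".tsv"), sep="\t", index_label="gene")
    meta = {
        "cutoff": centroids.cutoff,
        "source": centroids.source,
        "classes": centroids.classes,
        "n_genes": int(len(centroids.genes)),
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")


def read_centroids(prefix) -> CentroidSet:
    prefix = Path(prefix)
    profiles = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t", index_col="gene")
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return CentroidSet(profiles, cutoff=float(meta.get("cutoff", 0.2)), source=meta.get("source", ""))
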
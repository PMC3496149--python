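"""Quantile normalization, log2 transform, empirical-Bayes batch correction and
PCA batch diagnostics.

The batch-correction stage implements the parametric empirical-Bayes
location/scale model of Johnson, Li & Rabinovic (ComBat): genes are
standardized against a batch-weighted grand mean and pooled variance,
per-batch location (gamma) and scale (delta^2) effects are estimated
gene-wise and shrunk toward batch-level normal / inverse-gamma priors
whose hyperparameters are fit by method of moments, and the adjusted
values are back-transformed.  Biological covariates supplied in the
design are estimated jointly and preserved in the output.

Estimators follow the scikit-learn convention (X = samples x features);
the module-level functions wrap them for the genes x samples
:class:`~substrata.io.ExpressionMatrix` container.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import ExpressionMatrix

logger = logging.getLogger("substrata")

__all__ = [
    "QuantileNormalizer",
    "ComBat",
    "BatchModel",
    "PCAReport",
    "quantile_normalize",
    "log2_transform",
    "combat_adjust",
    "collapse_replicates",
    "pca_report",
]


# ---------------------------------------------------------------------------
# Quantile normalization
# ---------------------------------------------------------------------------


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Force every sample onto the mean empirical distribution.

    ``fit`` computes the reference distribution (the mean, across samples,
    of each order statistic); ``transform`` replaces each sample's values
    by the reference value at the corresponding rank, averaging the
    reference over tied runs so tied inputs stay tied.
    """

    def fit(self, X, y=None):
        X = self._validate(X)
        self.n_features_in_ = X.shape[1]
        self.reference_distribution_ = np.sort(X, axis=1).mean(axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_distribution_")
        index = columns = None
        if isinstance(X, pd.DataFrame):
            index, columns = X.index, X.columns
        X = self._validate(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features but the reference has {self.n_features_in_}"
            )
        ref = self.reference_distribution_
        out = np.empty_like(X)
        for i, row in enumerate(X):
            order = np.argsort(row, kind="stable")
            row_sorted = row[order]
            assigned = ref.copy()
            # average the reference over runs of tied input values
            starts = np.flatnonzero(np.r_[True, row_sorted[1:] != row_sorted[:-1]])
            if len(starts) < len(row_sorted):
                sums = np.add.reduceat(assigned, starts)
                lengths = np.diff(np.r_[starts, len(row_sorted)])
                assigned = np.repeat(sums / lengths, lengths)
            out[i, order] = assigned
        if index is not None:
            return pd.DataFrame(out, index=index, columns=columns)
        return out

    @staticmethod
    def _validate(X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D samples x features array")
        if not np.isfinite(X).all():
            raise ValueError("quantile normalization requires finite values (no missing data)")
        return X


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize samples of a features x samples matrix.

    After normalization every sample (column) has exactly the same sorted
    values: the feature-wise means of the column order statistics.
    """
    if matrix.n_samples < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    X = matrix.samples_by_features()
    out = QuantileNormalizer().fit(X).transform(X)
    return matrix.with_values(out.T)


def log2_transform(matrix: ExpressionMatrix, offset: float = 0.0) -> ExpressionMatrix:
    """Elementwise log2(value + offset)."""
    vals = matrix.values + offset
    bad = vals <= 0
    if bad.to_numpy().any():
        cells = [
            (str(vals.index[r]), str(vals.columns[c]))
            for r, c in zip(*np.nonzero(bad.to_numpy()))
        ][:5]
        raise ValueError(f"log2 undefined for non-positive values at (feature, sample): {cells}")
    return matrix.with_values(np.log2(vals))


# ---------------------------------------------------------------------------
# ComBat empirical-Bayes batch correction
# ---------------------------------------------------------------------------


@dataclass
class BatchModel:
    """Fitted ComBat parameters (all gene-wise, one row per batch)."""

    batches: list[str]
    gamma_hat: pd.DataFrame  # batch x gene location estimates (standardized scale)
    delta_hat: pd.DataFrame  # batch x gene scale estimates
    gamma_star: pd.DataFrame  # EB-shrunk locations
    delta_star: pd.DataFrame  # EB-shrunk scales (> 0)
    gamma_bar: pd.Series  # per-batch normal prior mean
    tau2: pd.Series  # per-batch normal prior variance
    a_prior: pd.Series  # per-batch inverse-gamma shape
    b_prior: pd.Series  # per-batch inverse-gamma scale
    grand_mean: pd.Series  # gene-wise batch-weighted grand mean
    var_pooled: pd.Series  # gene-wise pooled variance used for standardization
    covariate_design: pd.DataFrame | None  # sample x covariate design (if any)
    covariate_coefs: pd.DataFrame | None  # covariate x gene coefficients


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_solve(z_batch, gamma_hat, delta_hat, gamma_bar, tau2, a, b, tol=1e-4, max_iter=500):
    """Iterative parametric EB point estimates for one batch (Johnson et al.)."""
    n = z_batch.shape[0]
    gamma_old, delta_old = gamma_hat.copy(), delta_hat.copy()
    for _ in range(max_iter):
        gamma_new = (n * tau2 * gamma_hat + delta_old * gamma_bar) / (n * tau2 + delta_old)
        ss = ((z_batch - gamma_new[None, :]) ** 2).sum(axis=0)
        delta_new = (b + 0.5 * ss) / (n / 2 + a - 1)
        change = max(
            np.abs(gamma_new - gamma_old).max() / np.abs(gamma_old).max() if np.abs(gamma_old).max() else 0,
            np.abs(delta_new - delta_old).max() / delta_old.max(),
        )
        gamma_old, delta_old = gamma_new, delta_new
        if change < tol:
            break
    return gamma_old, delta_old


class ComBat(TransformerMixin, BaseEstimator):
    """Parametric empirical-Bayes batch correction (samples x genes).

    Parameters
    ----------
    parametric : bool
        Only the parametric priors are implemented; kept as a parameter so
        the choice is explicit in pipelines.

    ``fit`` requires per-sample batch labels; an optional covariate design
    (samples x covariates, full rank and not confounded with batch)
    preserves biological effects during estimation.
    """

    def __init__(self, parametric: bool = True):
        self.parametric = parametric

    def fit(self, X, y=None, *, batch, covariates=None):
        if not self.parametric:
            raise NotImplementedError("only parametric priors are implemented")
        X_df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        Xv = X_df.to_numpy(dtype=float)
        if not np.isfinite(Xv).all():
            raise ValueError("ComBat requires finite values")
        batch = pd.Series(np.asarray(batch), index=X_df.index)
        levels = sorted(batch.unique(), key=str)
        counts = batch.value_counts()
        singles = [str(b) for b in levels if counts[b] < 2]
        if singles:
            raise ValueError(f"every batch needs >= 2 samples; offending batch(es): {singles}")
        n, g = Xv.shape

        onehot = np.column_stack([(batch == b).to_numpy(float) for b in levels])
        if covariates is not None:
            cov = pd.DataFrame(covariates).set_axis(X_df.index, axis=0)
            cov_mat = cov.to_numpy(dtype=float)
            design = np.column_stack([onehot, cov_mat])
            if np.linalg.matrix_rank(design) < design.shape[1]:
                raise ValueError(
                    "design matrix is rank-deficient: covariates are confounded with batch "
                    f"(batches={list(map(str, levels))}, covariates={list(cov.columns)})"
                )
        else:
            cov = None
            design = onehot

        beta = np.linalg.lstsq(design, Xv, rcond=None)[0]  # (B + p) x genes
        n_b = counts.reindex(levels).to_numpy(float)
        grand_mean = (n_b / n) @ beta[: len(levels)]
        fitted = design @ beta
        var_pooled = ((Xv - fitted) ** 2).mean(axis=0)
        if (var_pooled <= 0).any():
            var_pooled = np.maximum(var_pooled, 1e-12)

        stand_mean = np.tile(grand_mean, (n, 1))
        if cov is not None:
            stand_mean = stand_mean + cov_mat @ beta[len(levels):]
        Z = (Xv - stand_mean) / np.sqrt(var_pooled)[None, :]

        gamma_hat = np.vstack([Z[(batch == b).to_numpy()].mean(axis=0) for b in levels])
        delta_hat = np.vstack([Z[(batch == b).to_numpy()].var(axis=0, ddof=1) for b in levels])

        gamma_bar = gamma_hat.mean(axis=1)
        tau2 = gamma_hat.var(axis=1, ddof=1)
        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.empty_like(delta_hat)
        a_pri, b_pri = np.empty(len(levels)), np.empty(len(levels))
        for i, b in enumerate(levels):
            dh = delta_hat[i]
            if dh.var(ddof=1) <= 1e-12 or g < 2:
                # degenerate prior (e.g. one gene): no shrinkage possible
                a_pri[i] = np.nan
                b_pri[i] = np.nan
                gamma_star[i], delta_star[i] = gamma_hat[i], dh
                continue
            a_pri[i], b_pri[i] = _aprior(dh), _bprior(dh)
            gamma_star[i], delta_star[i] = _it_solve(
                Z[(batch == b).to_numpy()], gamma_hat[i], dh, gamma_bar[i], tau2[i], a_pri[i], b_pri[i]
            )

        genes = X_df.columns
        blab = [str(b) for b in levels]
        self.batches_ = blab
        self._batch_index = {str(b): i for i, b in enumerate(levels)}
        self.model_ = BatchModel(
            batches=blab,
            gamma_hat=pd.DataFrame(gamma_hat, index=blab, columns=genes),
            delta_hat=pd.DataFrame(delta_hat, index=blab, columns=genes),
            gamma_star=pd.DataFrame(gamma_star, index=blab, columns=genes),
            delta_star=pd.DataFrame(delta_star, index=blab, columns=genes),
            gamma_bar=pd.Series(gamma_bar, index=blab),
            tau2=pd.Series(tau2, index=blab),
            a_prior=pd.Series(a_pri, index=blab),
            b_prior=pd.Series(b_pri, index=blab),
            grand_mean=pd.Series(grand_mean, index=genes),
            var_pooled=pd.Series(var_pooled, index=genes),
            covariate_design=cov,
            covariate_coefs=(
                pd.DataFrame(beta[len(levels):], index=cov.columns, columns=genes) if cov is not None else None
            ),
        )
        self.n_features_in_ = g
        return self

    def transform(self, X, *, batch, covariates=None):
        """Remove the fitted batch effects from samples with known batch labels."""
        check_is_fitted(self, "model_")
        m = self.model_
        X_df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        Xv = X_df.to_numpy(dtype=float)
        batch = pd.Series(np.asarray(batch), index=X_df.index).astype(str)
        unknown = sorted(set(batch) - set(self.batches_))
        if unknown:
            raise ValueError(f"unknown batch label(s): {unknown}")
        n = Xv.shape[0]
        stand_mean = np.tile(m.grand_mean.to_numpy(), (n, 1))
        if m.covariate_coefs is not None:
            if covariates is None:
                raise ValueError("model was fit with covariates; supply them to transform")
            cov_mat = pd.DataFrame(covariates).to_numpy(dtype=float)
            stand_mean = stand_mean + cov_mat @ m.covariate_coefs.to_numpy()
        sd = np.sqrt(m.var_pooled.to_numpy())
        Z = (Xv - stand_mean) / sd[None, :]
        gstar = m.gamma_star.to_numpy()
        dstar = m.delta_star.to_numpy()
        rows = np.array([self._batch_index[b] for b in batch])
        adj = (Z - gstar[rows]) / np.sqrt(dstar[rows]) * sd[None, :] + stand_mean
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(adj, index=X.index, columns=X.columns)
        return adj


def combat_adjust(
    matrix: ExpressionMatrix,
    batch=None,
    covariates: pd.DataFrame | None = None,
) -> tuple[ExpressionMatrix, BatchModel]:
    """Empirical-Bayes batch correction of a features x samples matrix.

    ``batch`` defaults to the ``batch`` column of ``matrix.sample_annot``.
    A single batch leaves the data untouched (nothing to correct).
    """
    if batch is None:
        if matrix.sample_annot is None or "batch" not in matrix.sample_annot.columns:
            raise ValueError("no batch labels: pass `batch` or provide sample_annot['batch']")
        batch = matrix.sample_annot["batch"].reindex(matrix.sample_ids)
        if batch.isna().any():
            raise ValueError("batch label missing for some samples")
    batch = pd.Series(np.asarray(batch), index=matrix.sample_ids)
    if batch.nunique() < 2:
        logger.warning("single batch: nothing to correct, returning input unchanged")
        return matrix.with_values(matrix.values.copy()), None
    est = ComBat()
    X = matrix.samples_by_features()
    est.fit(X, batch=batch, covariates=covariates)
    adjusted = est.transform(X, batch=batch, covariates=covariates)
    return matrix.with_values(adjusted.T), est.model_


def collapse_replicates(matrix: ExpressionMatrix, tumor_of: pd.Series) -> ExpressionMatrix:
    """Collapse re-hybridized replicate columns to one column per tumor.

    ``tumor_of`` maps sample id -> tumor id.  For tumors measured more than
    once, the profile from the replicate hybridized in the later batch
    (last column in sample order, or by batch label order when batch
    annotation is present) is kept and relabeled with the tumor id.
    """
    tumor_of = tumor_of.reindex(matrix.sample_ids)
    if tumor_of.isna().any():
        raise ValueError("tumor id missing for some samples")
    keep: dict[str, str] = {}
    batch = None
    if matrix.sample_annot is not None and "batch" in matrix.sample_annot.columns:
        batch = matrix.sample_annot["batch"].reindex(matrix.sample_ids).astype(str)
    for sample, tumor in tumor_of.items():
        if tumor not in keep:
            keep[tumor] = sample
        else:
            prev = keep[tumor]
            if batch is None or str(batch[sample]) >= str(batch[prev]):
                keep[tumor] = sample
    values = matrix.values[[keep[t] for t in keep]].copy()
    values.columns = list(keep)
    annot = None
    if matrix.sample_annot is not None:
        annot = matrix.sample_annot.reindex([keep[t] for t in keep])
        annot.index = list(keep)
    return ExpressionMatrix(values, matrix.feature_annot, annot)


# ---------------------------------------------------------------------------
# PCA batch diagnostics
# ---------------------------------------------------------------------------


@dataclass
class PCAReport:
    """Principal components of the gene-centered matrix plus annotation tests."""

    scores: pd.DataFrame  # samples x components
    variance_explained: pd.Series  # per component, non-increasing
    associations: pd.DataFrame  # rows: (component, annotation, kind, statistic, p)

    def top_association(self, component: str = "PC1") -> pd.Series:
        sub = self.associations[self.associations["component"] == component]
        return sub.loc[sub["p"].idxmin()]

    def association_p(self, component: str, annotation: str) -> float:
        sub = self.associations
        row = sub[(sub["component"] == component) & (sub["annotation"] == annotation)]
        if row.empty:
            raise KeyError(f"no association recorded for {component} x {annotation}")
        return float(row["p"].iloc[0])


def pca_report(
    matrix: ExpressionMatrix,
    annotations: pd.DataFrame | None = None,
    n_components: int | None = None,
) -> PCAReport:
    """PCA of the gene-centered matrix with per-component annotation tests.

    Categorical annotations are tested against component scores with
    Kruskal-Wallis, continuous ones with Spearman correlation; p-values
    are reported untransformed.  Constant annotations are skipped with a
    warning.
    """
    if matrix.n_samples < 3:
        raise ValueError("PCA diagnostics need >= 3 samples")
    if annotations is None:
        annotations = matrix.sample_annot if matrix.sample_annot is not None else pd.DataFrame(index=matrix.sample_ids)
    annotations = annotations.reindex(matrix.sample_ids)

    centered = matrix.values.sub(matrix.values.mean(axis=1), axis=0)
    # SVD over samples: right singular vectors give sample scores
    U, s, Vt = np.linalg.svd(centered.to_numpy(), full_matrices=False)
    total = (s**2).sum()
    var_exp = (s**2) / total if total > 0 else np.zeros_like(s)
    k = n_components or int(min(10, (var_exp > 1e-12).sum() or 1))
    names = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame((Vt[:k].T * s[:k]), index=matrix.sample_ids, columns=names)

    rows = []
    for col in annotations.columns:
        ann = annotations[col]
        numeric = pd.api.types.is_numeric_dtype(ann)
        valid = ann.notna()
        if valid.sum() < 3 or ann[valid].nunique() < 2:
            logger.warning("annotation %r is constant or too sparse; skipped", col)
            continue
        for pc in names:
            x = scores.loc[valid, pc].to_numpy()
            if numeric:
                stat, p = stats.spearmanr(x, ann[valid].to_numpy(dtype=float))
                kind = "spearman"
            else:
                groups = [x[(ann[valid] == lv).to_numpy()] for lv in ann[valid].unique()]
                stat, p = stats.kruskal(*groups)
                kind = "kruskal"
            rows.append({"component": pc, "annotation": col, "kind": kind, "statistic": stat, "p": p})
    assoc = pd.DataFrame(rows, columns=["component", "annotation", "kind", "statistic", "p"])
    return PCAReport(scores, pd.Series(var_exp[:k], index=names), assoc)
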
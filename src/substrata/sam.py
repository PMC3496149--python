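"""Two-class unpaired Significance Analysis of Microarrays (SAM).

Per gene, the moderated relative difference

    d_i = (mean_2 - mean_1) / (s_i + s0)

uses the unpaired pooled standard error s_i and a fudge factor s0 chosen
among percentiles of the s_i to minimize the coefficient of variation of
the (MAD-based) spread of d across the range of s — the Tusher et al.
construction.  Significance is judged against label permutations: the
sorted observed d are compared with the permutation-averaged order
statistics, asymmetric cutoffs are derived for each threshold Delta, and
the FDR at Delta is the median permutation count of values beyond the
cutoffs divided by the number of genes called.  "FDR 0" therefore means
the median number of falsely called genes is zero.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .io import ExpressionMatrix

__all__ = ["SAMResult", "SAMTwoClass", "sam_two_class", "significant_genes"]

_S0_ALPHAS = np.round(np.arange(0.0, 1.01, 0.05), 2)  # percentile grid 0, 5, ..., 100


@dataclass
class SAMResult:
    """Everything SAM computes for one two-class comparison."""

    genes: pd.Index
    d: pd.Series  # relative difference per gene (positive = up in class 2)
    s: pd.Series  # pooled standard error per gene
    fold_change_log2: pd.Series  # mean_2 - mean_1 (log2 scale)
    s0: float
    s0_percentile: float
    dbar: np.ndarray  # permutation-averaged order statistics, ascending
    d_sorted: np.ndarray  # observed order statistics, ascending
    delta_table: pd.DataFrame  # delta, cut_low, cut_up, n_significant, median_false, fdr
    classes: tuple
    n_perm: int
    exhaustive: bool
    seed: int | None


def _pooled_se(X, idx1, idx2):
    """Unpaired pooled standard error per gene; X is genes x samples."""
    n1, n2 = len(idx1), len(idx2)
    x1, x2 = X[:, idx1], X[:, idx2]
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x2 - x2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    return np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))


def _choose_s0(r: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    """Fudge-factor search: minimize the CV of the MAD of d across s-windows."""
    quantiles = np.quantile(s, np.arange(0.0, 1.01, 0.01))
    bins = np.clip(np.searchsorted(quantiles, s, side="right") - 1, 0, 99)
    best = (np.inf, 0.0, 0.0)
    for alpha in _S0_ALPHAS:
        s0 = float(np.quantile(s, alpha))
        denom = s + s0
        denom = np.where(denom > 0, denom, np.finfo(float).tiny)
        d = r / denom
        mads = []
        for b in np.unique(bins):
            db = d[bins == b]
            if len(db):
                mads.append(np.median(np.abs(db - np.median(db))) / 0.64)
        mads = np.asarray(mads)
        if len(mads) < 2 or mads.mean() == 0:
            cv = np.inf
        else:
            cv = mads.std(ddof=1) / mads.mean()
        if cv < best[0]:
            best = (cv, s0, float(alpha))
    return best[1], best[2]


def _permutation_class2_sets(n, n2, n_perm, rng) -> tuple[np.ndarray, bool]:
    """Distinct assignments of samples to class 2 (rows of indices)."""
    total = math.comb(n, n2)
    if total <= n_perm:
        combos = np.array(list(itertools.combinations(range(n), n2)), dtype=int)
        return combos, True
    if total <= 2 * n_perm:
        combos = np.array(list(itertools.combinations(range(n), n2)), dtype=int)
        pick = rng.choice(total, size=n_perm, replace=False)
        return combos[np.sort(pick)], False
    seen: set[tuple] = set()
    rows = []
    while len(rows) < n_perm:
        c = tuple(sorted(rng.choice(n, size=n2, replace=False).tolist()))
        if c not in seen:
            seen.add(c)
            rows.append(c)
    return np.array(rows, dtype=int), False


def _delta_table(d_sorted, dbar, perm_d_sorted):
    """Asymmetric-cutoff delta/FDR table.

    Starting from the origin of the quantile-quantile plot (the index
    where the permutation-averaged order statistic crosses zero), the
    upper cutoff at Delta is the observed order statistic at the first
    index whose displacement d_(i) - dbar_(i) reaches Delta; the lower
    cutoff mirrors it downward.  Reported FDRs are monotonized (running
    minimum in Delta) so the table is non-increasing.
    """
    n = len(d_sorted)
    diff = d_sorted - dbar
    i0 = int(np.searchsorted(dbar, 0.0, side="left"))
    i0 = min(max(i0, 0), n - 1)

    # prefix maxima of displacement moving up / down from the origin
    up = np.maximum.accumulate(diff[i0:])
    down = np.maximum.accumulate(-diff[: i0 + 1][::-1])

    deltas = np.unique(np.concatenate([[0.0], up[up > -np.inf], down]))
    deltas = np.unique(np.round(deltas[deltas >= 0], 12))

    # first-crossing indices per delta (searchsorted on the prefix maxima)
    ju = np.searchsorted(up, deltas, side="left")  # offset from i0
    jd = np.searchsorted(down, deltas, side="left")  # offset downward from i0
    cut_up = np.where(ju < len(up), d_sorted[np.minimum(i0 + ju, n - 1)], np.inf)
    cut_up[ju >= len(up)] = np.inf
    cut_low = np.where(jd < len(down), d_sorted[np.maximum(i0 - jd, 0)], -np.inf)
    cut_low[jd >= len(down)] = -np.inf

    n_up = n - np.searchsorted(d_sorted, cut_up, side="left")
    n_down = np.searchsorted(d_sorted, cut_low, side="right")
    n_sig = n_up + n_down

    # permutation counts beyond the cutoffs -> median falsely called
    P = perm_d_sorted.shape[0]
    false_counts = np.empty((P, len(deltas)))
    for p in range(P):
        row = perm_d_sorted[p]
        false_counts[p] = (len(row) - np.searchsorted(row, cut_up, side="left")) + np.searchsorted(
            row, cut_low, side="right"
        )
    median_false = np.median(false_counts, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_raw = np.where(n_sig > 0, median_false / np.maximum(n_sig, 1), 0.0)
    fdr = np.minimum.accumulate(fdr_raw)  # non-increasing in delta
    fdr = np.minimum(fdr, 1.0)
    return pd.DataFrame(
        {
            "delta": deltas,
            "cut_low": cut_low,
            "cut_up": cut_up,
            "n_significant": n_sig.astype(int),
            "median_false": median_false,
            "fdr": fdr,
        }
    )


class SAMTwoClass(BaseEstimator):
    """scikit-learn style SAM: ``fit(X, y)`` with X samples x genes.

    Parameters
    ----------
    n_perm : int
        Maximum number of label permutations.  All distinct arrangements
        are enumerated exhaustively when their count does not exceed
        ``n_perm``; otherwise ``n_perm`` distinct arrangements are sampled
        without replacement.
    random_state : int or None
        Seed for permutation sampling.
    """

    def __init__(self, n_perm: int = 1000, random_state: int | None = None):
        self.n_perm = n_perm
        self.random_state = random_state

    def fit(self, X, y):
        X_df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        y = pd.Series(np.asarray(y), index=X_df.index)
        classes = sorted(pd.unique(y), key=str)
        if len(classes) != 2:
            raise ValueError(f"need exactly two classes, got {classes}")
        idx1 = np.flatnonzero((y == classes[0]).to_numpy())
        idx2 = np.flatnonzero((y == classes[1]).to_numpy())
        if min(len(idx1), len(idx2)) < 2:
            raise ValueError("each class needs >= 2 samples")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        Xg = X_df.to_numpy(dtype=float).T  # genes x samples
        n = Xg.shape[1]

        r = Xg[:, idx2].mean(axis=1) - Xg[:, idx1].mean(axis=1)
        s = _pooled_se(Xg, idx1, idx2)
        s0, s0_pct = _choose_s0(r, s)
        denom = s + s0
        denom = np.where(denom > 0, denom, np.finfo(float).tiny)
        d = r / denom

        rng = np.random.default_rng(self.random_state)
        # permutations are drawn as subsets of the smaller class so the same
        # seed yields mirrored permutations when the class labels are swapped
        # (keeps the up/down lists exactly antisymmetric)
        n2 = len(idx2)
        n1 = n - n2
        m_small = min(n1, n2)
        subsets, exhaustive = _permutation_class2_sets(n, m_small, self.n_perm, rng)

        # vectorized permutation d-statistics
        I_small = np.zeros((n, len(subsets)))
        for col, rowset in enumerate(subsets):
            I_small[rowset, col] = 1.0
        if n2 <= n1:
            I2 = I_small
            I1 = 1.0 - I2
        else:
            I1 = I_small
            I2 = 1.0 - I1
        sum1, sum2 = Xg @ I1, Xg @ I2
        sq = Xg**2
        ss1 = sq @ I1 - sum1**2 / n1
        ss2 = sq @ I2 - sum2**2 / n2
        r_p = sum2 / n2 - sum1 / n1
        s_p = np.sqrt((1.0 / n1 + 1.0 / n2) * np.maximum(ss1 + ss2, 0.0) / (n1 + n2 - 2))
        denom_p = s_p + s0
        denom_p = np.where(denom_p > 0, denom_p, np.finfo(float).tiny)
        d_p = (r_p / denom_p).T  # perms x genes
        perm_d_sorted = np.sort(d_p, axis=1)
        dbar = perm_d_sorted.mean(axis=0)
        d_sorted = np.sort(d)

        genes = X_df.columns
        self.result_ = SAMResult(
            genes=genes,
            d=pd.Series(d, index=genes, name="d"),
            s=pd.Series(s, index=genes, name="s"),
            fold_change_log2=pd.Series(r, index=genes, name="fold_change_log2"),
            s0=float(s0),
            s0_percentile=s0_pct,
            dbar=dbar,
            d_sorted=d_sorted,
            delta_table=_delta_table(d_sorted, dbar, perm_d_sorted),
            classes=tuple(classes),
            n_perm=len(subsets),
            exhaustive=exhaustive,
            seed=self.random_state,
        )
        self.n_features_in_ = X_df.shape[1]
        return self

    def significant_genes(self, fdr_cutoff: float = 0.0) -> tuple[list, list]:
        check_is_fitted(self, "result_")
        return significant_genes(self.result_, fdr_cutoff)


def significant_genes(result: SAMResult, fdr_cutoff: float = 0.0) -> tuple[list, list]:
    """(up, down) gene lists at the smallest Delta whose FDR meets the cutoff.

    Positive d means up in the second class.  Both lists are empty when no
    Delta achieves the cutoff with at least one gene called.
    """
    if not 0 <= fdr_cutoff <= 1:
        raise ValueError("fdr_cutoff must lie in [0, 1]")
    tab = result.delta_table
    ok = tab[tab["fdr"] <= fdr_cutoff]
    if ok.empty:
        return [], []
    row = ok.iloc[0]
    up = [g for g in result.genes if result.d[g] >= row["cut_up"]]
    down = [g for g in result.genes if result.d[g] <= row["cut_low"]]
    return up, down


def sam_two_class(
    matrix: ExpressionMatrix,
    labels,
    n_perm: int = 1000,
    seed: int | None = None,
) -> SAMResult:
    """Two-class unpaired SAM on a features x samples matrix."""
    labels = pd.Series(np.asarray(labels), index=matrix.sample_ids)
    est = SAMTwoClass(n_perm=n_perm, random_state=seed)
    est.fit(matrix.samples_by_features(), labels)
    return est.result_


def top_genes_by_d(result: SAMResult, n: int, fdr_cutoff: float = 0.0) -> list:
    """The n FDR-passing genes with largest |d| (centroid gene selection)."""
    up, down = significant_genes(result, fdr_cutoff)
    called = list(up) + list(down)
    ranked = sorted(called, key=lambda g: (-abs(result.d[g]), str(g)))
    return ranked[:n]
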
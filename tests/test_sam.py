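import itertools

import numpy as np
import pandas as pd
import pytest

from substrata import (
    ExpressionMatrix,
    SAMTwoClass,
    SimulationConfig,
    sam_two_class,
    significant_genes,
    simulate_expression,
    top_genes_by_d,
)


def _em(arr):
    arr = np.asarray(arr, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(
            arr,
            index=[f"g{i}" for i in range(arr.shape[0])],
            columns=[f"s{i}" for i in range(arr.shape[1])],
        )
    )


# ---------------------------------------------------------------------------
# Brute-force oracle: naive loops over genes and exhaustive label arrangements
# ---------------------------------------------------------------------------


def oracle_sam(X, y):
    classes = sorted(set(y))
    i1 = [i for i, v in enumerate(y) if v == classes[0]]
    i2 = [i for i, v in enumerate(y) if v == classes[1]]
    n1, n2 = len(i1), len(i2)
    G = X.shape[0]

    def stats(j1, j2):
        r, s = [], []
        for g in range(G):
            x1, x2 = X[g, j1], X[g, j2]
            r.append(x2.mean() - x1.mean())
            s.append(
                np.sqrt(
                    (1 / n1 + 1 / n2)
                    * (((x1 - x1.mean()) ** 2).sum() + ((x2 - x2.mean()) ** 2).sum())
                    / (n1 + n2 - 2)
                )
            )
        return np.array(r), np.array(s)

    r, s = stats(i1, i2)
    # fudge factor: same published definition, naive loops
    qs = np.quantile(s, np.arange(0, 1.01, 0.01))
    bins = np.clip(np.searchsorted(qs, s, side="right") - 1, 0, 99)
    best = (np.inf, 0.0)
    for alpha in np.round(np.arange(0, 1.01, 0.05), 2):
        s0 = float(np.quantile(s, alpha))
        d = r / np.where(s + s0 > 0, s + s0, np.finfo(float).tiny)
        mads = []
        for b in sorted(set(bins)):
            db = d[bins == b]
            if len(db):
                mads.append(np.median(np.abs(db - np.median(db))) / 0.64)
        mads = np.array(mads)
        cv = np.inf if len(mads) < 2 or mads.mean() == 0 else mads.std(ddof=1) / mads.mean()
        if cv < best[0]:
            best = (cv, s0)
    s0 = best[1]
    d = r / np.where(s + s0 > 0, s + s0, np.finfo(float).tiny)

    perm_sorted = []
    for c in itertools.combinations(range(n1 + n2), n2):
        j2 = list(c)
        j1 = [i for i in range(n1 + n2) if i not in c]
        rp, sp = stats(j1, j2)
        dp = rp / np.where(sp + s0 > 0, sp + s0, np.finfo(float).tiny)
        perm_sorted.append(np.sort(dp))
    perm_sorted = np.array(perm_sorted)
    dbar = perm_sorted.mean(axis=0)
    return d, dbar, s0, perm_sorted


def oracle_delta_table(d_sorted, dbar, perm_sorted):
    """Naive per-delta loops over the same published cutoff construction."""
    n = len(d_sorted)
    diff = d_sorted - dbar
    i0 = min(max(int(np.searchsorted(dbar, 0.0)), 0), n - 1)
    deltas = set([0.0])
    run = -np.inf
    for i in range(i0, n):
        run = max(run, diff[i])
        if run >= 0:
            deltas.add(round(run, 12))
    run = -np.inf
    for i in range(i0, -1, -1):
        run = max(run, -diff[i])
        if run >= 0:
            deltas.add(round(run, 12))
    rows = []
    for delta in sorted(deltas):
        cut_up = np.inf
        for i in range(i0, n):
            if max(diff[i0 : i + 1]) >= delta:
                cut_up = d_sorted[i]
                break
        cut_low = -np.inf
        for i in range(i0, -1, -1):
            if max(-diff[i : i0 + 1]) >= delta:
                cut_low = d_sorted[i]
                break
        n_sig = int((d_sorted >= cut_up).sum() + (d_sorted <= cut_low).sum())
        false = [int((row >= cut_up).sum() + (row <= cut_low).sum()) for row in perm_sorted]
        med = float(np.median(false))
        rows.append((delta, cut_low, cut_up, n_sig, med, med / n_sig if n_sig else 0.0))
    tab = pd.DataFrame(rows, columns=["delta", "cut_low", "cut_up", "n_significant", "median_false", "fdr"])
    tab["fdr"] = np.minimum(np.minimum.accumulate(tab["fdr"]), 1.0)
    return tab


class TestOracleEquality:
    @pytest.mark.parametrize("seed", [5, 6, 7])
    def test_three_vs_three_exhaustive(self, seed):
        """d, permutation-averaged order statistics and the full delta table
        match the brute-force enumeration oracle on 3-vs-3 designs (20 perms)."""
        rng = np.random.default_rng(seed)
        X = rng.normal(7, 1, (20, 6))
        y = ["a", "a", "a", "b", "b", "b"]
        d_o, dbar_o, s0_o, perm_o = oracle_sam(X, y)
        res = sam_two_class(_em(X), y, n_perm=1000, seed=0)
        assert res.exhaustive and res.n_perm == 20
        assert res.s0 == pytest.approx(s0_o)
        np.testing.assert_allclose(res.d_sorted, np.sort(d_o), atol=1e-10)
        np.testing.assert_allclose(res.dbar, dbar_o, atol=1e-10)
        tab_o = oracle_delta_table(np.sort(d_o), dbar_o, perm_o)
        tab = res.delta_table
        np.testing.assert_allclose(tab["delta"], tab_o["delta"], atol=1e-9)
        np.testing.assert_allclose(tab["cut_up"], tab_o["cut_up"])
        np.testing.assert_allclose(tab["cut_low"], tab_o["cut_low"])
        np.testing.assert_array_equal(tab["n_significant"], tab_o["n_significant"])
        np.testing.assert_allclose(tab["median_false"], tab_o["median_false"])
        np.testing.assert_allclose(tab["fdr"], tab_o["fdr"])

    @pytest.mark.parametrize("n1,n2", [(4, 4), (4, 3), (3, 3)])
    def test_small_unequal_designs(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        X = rng.normal(0, 1, (15, n1 + n2))
        y = ["a"] * n1 + ["b"] * n2
        d_o, dbar_o, s0_o, _ = oracle_sam(X, y)
        res = sam_two_class(_em(X), y, n_perm=10_000, seed=0)
        assert res.exhaustive
        np.testing.assert_allclose(res.d_sorted, np.sort(d_o), atol=1e-10)
        np.testing.assert_allclose(res.dbar, dbar_o, atol=1e-10)


class TestStatisticProperties:
    def test_swapping_labels_negates_d_and_swaps_lists(self, default_cohort):
        m, truth = default_cohort
        y = truth.subgroup
        a = sam_two_class(m, y.map({1: "g1", 2: "g2"}), n_perm=50, seed=1)
        b = sam_two_class(m, y.map({1: "g2", 2: "g1"}), n_perm=50, seed=1)
        np.testing.assert_allclose(a.d.to_numpy(), -b.d.to_numpy(), rtol=0, atol=1e-12)
        up_a, down_a = significant_genes(a, 0.0)
        up_b, down_b = significant_genes(b, 0.0)
        assert set(up_a) == set(down_b) and set(down_a) == set(up_b)

    def test_equal_class_means_give_zero_d(self):
        X = np.array([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0], [5.0, 6.0, 7.0, 5.0, 6.0, 7.0]])
        res = sam_two_class(_em(X), ["a", "a", "a", "b", "b", "b"], n_perm=20, seed=0)
        np.testing.assert_allclose(res.d.to_numpy(), 0.0, atol=1e-12)

    def test_constant_gene_handled_without_division_error(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (10, 8))
        X[0] = 5.0  # constant gene: s_i = 0
        res = sam_two_class(_em(X), ["a"] * 4 + ["b"] * 4, n_perm=30, seed=0)
        assert np.isfinite(res.d.to_numpy()).all()

    def test_class_with_one_sample_rejected(self):
        X = np.random.default_rng(0).normal(0, 1, (5, 4))
        with pytest.raises(ValueError, match=">= 2 samples"):
            sam_two_class(_em(X), ["a", "b", "b", "b"], n_perm=10)

    def test_fdr_and_counts_monotone_in_delta(self, default_cohort):
        m, truth = default_cohort
        res = sam_two_class(m, truth.subgroup, n_perm=50, seed=3)
        tab = res.delta_table
        assert (np.diff(tab["n_significant"]) <= 0).all()
        assert (np.diff(tab["fdr"]) <= 1e-12).all()
        assert res.s0 >= 0
        assert ((tab["fdr"] >= 0) & (tab["fdr"] <= 1)).all()

    def test_null_fdr_large_where_many_genes_called(self, null_cohort):
        """Correct null calibration in the bulk: deltas calling >= 5% of genes
        carry FDR near 1 on a null cohort."""
        m, truth = null_cohort
        res = sam_two_class(m, truth.subgroup, n_perm=100, seed=9)
        tab = res.delta_table
        bulk = tab[tab["n_significant"] >= 0.05 * len(res.genes)]
        assert (bulk["fdr"] > 0.5).all()


class TestSignificantGenes:
    def test_cutoff_one_returns_everything_beyond_minimal_delta(self, default_cohort):
        m, truth = default_cohort
        res = sam_two_class(m, truth.subgroup, n_perm=50, seed=2)
        up, down = significant_genes(res, 1.0)
        row = res.delta_table.iloc[0]
        expected = (res.d >= row["cut_up"]).sum() + (res.d <= row["cut_low"]).sum()
        assert len(up) + len(down) == expected

    def test_lists_disjoint_and_directional(self, default_cohort):
        m, truth = default_cohort
        res = sam_two_class(m, truth.subgroup, n_perm=100, seed=2)
        up, down = significant_genes(res, 0.0)
        assert not (set(up) & set(down))
        assert all(res.d[g] > 0 for g in up)
        assert all(res.d[g] < 0 for g in down)

    def test_recovery_against_generator_truth(self):
        """Informative genes recovered at FDR 0 with high precision and recall."""
        cfg = SimulationConfig(batch_shift_log2=0.0, seed=41)
        m, truth = simulate_expression(cfg)
        res = sam_two_class(m, truth.subgroup, n_perm=100, seed=5)
        up, down = significant_genes(res, 0.0)
        called = set(up) | set(down)
        tp = len(called & set(truth.informative.index))
        assert tp / max(len(called), 1) >= 0.95
        assert tp / len(truth.informative) >= 0.8
        # directions agree with the planted ones (positive d = up in subgroup 2)
        planted_up = set(truth.informative.index[truth.informative == 1])
        assert len(set(up) & planted_up) / max(len(up), 1) >= 0.95

    def test_top_genes_ranked_by_absolute_d(self, default_cohort):
        m, truth = default_cohort
        res = sam_two_class(m, truth.subgroup, n_perm=100, seed=2)
        top = top_genes_by_d(res, 10, 0.0)
        assert len(top) == 10
        mags = [abs(res.d[g]) for g in top]
        assert (np.diff(mags) <= 1e-12).all()

    def test_estimator_interface_matches_function(self, default_cohort):
        m, truth = default_cohort
        est = SAMTwoClass(n_perm=50, random_state=1).fit(m.samples_by_features(), truth.subgroup)
        res = sam_two_class(m, truth.subgroup, n_perm=50, seed=1)
        np.testing.assert_allclose(est.result_.d.to_numpy(), res.d.to_numpy())
        assert est.significant_genes(0.0) == significant_genes(res, 0.0)
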
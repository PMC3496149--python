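import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from substrata import (
    ExpressionMatrix,
    SimulationConfig,
    StabilitySubgrouper,
    au_probabilities,
    co_clustering_stability,
    cut_k,
    hcl,
    iterative_subgrouping,
    pearson_distance,
    simulate_expression,
)
from conftest import naive_complete_linkage


def _em(arr):
    arr = np.asarray(arr, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(
            arr,
            index=[f"g{i}" for i in range(arr.shape[0])],
            columns=[f"s{i}" for i in range(arr.shape[1])],
        )
    )


def _blob_cohort(seed=2, effect=3.0):
    cfg = SimulationConfig(
        n_samples=40, n_genes=300, n_informative=80, effect_size_log2=effect,
        batch_shift_log2=0.0, low_signal_fraction=0.0, seed=seed,
    )
    return simulate_expression(cfg)


class TestPearsonDistance:
    def test_self_distance_zero_and_anticorrelated_two(self):
        m = _em(np.array([[1.0, -1.0], [2.0, -2.0], [3.0, -3.0]]))
        d = pearson_distance(m)
        assert d.iloc[0, 0] == 0.0
        assert d.iloc[0, 1] == pytest.approx(2.0)

    def test_matches_naive_per_pair_loop(self):
        rng = np.random.default_rng(4)
        m = _em(rng.normal(0, 1, (25, 10)))
        d = pearson_distance(m).to_numpy()
        X = m.values.to_numpy()
        for a in range(10):
            for b in range(10):
                r = np.corrcoef(X[:, a], X[:, b])[0, 1]
                assert d[a, b] == pytest.approx(1 - r, abs=1e-10)

    def test_zero_variance_profile_names_sample(self):
        m = _em(np.array([[1.0, 1.0], [2.0, 1.0], [3.0, 1.0]]))
        with pytest.raises(ValueError, match="s1"):
            pearson_distance(m)


class TestHCL:
    def test_forced_three_point_merge_order(self):
        D = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]])
        dend = hcl(D)
        assert dend.merges == [(0, 1), (2, 3)]
        assert dend.heights == [0.1, 0.9]

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.integers(4, 15))
            D = rng.random((n, n))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0)
            dend = hcl(D)
            assert (np.diff(dend.heights) >= -1e-12).all()

    def test_nan_distance_rejected(self):
        D = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError, match="NaN"):
            hcl(D)

    @pytest.mark.parametrize("trial", range(20))
    def test_equals_naive_oracle_with_ties(self, trial):
        """Merge-for-merge equality with a brute-force O(n^3) agglomerator,
        half the fixtures drawn from a 3-level distance alphabet to force ties."""
        rng = np.random.default_rng(trial)
        n = int(rng.integers(3, 13))
        if trial % 2:
            D = rng.integers(1, 4, (n, n)).astype(float)
        else:
            D = rng.random((n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        dend = hcl(D)
        merges, heights = naive_complete_linkage(D)
        assert dend.merges == merges
        np.testing.assert_allclose(dend.heights, heights)

    def test_newick_export_contains_all_leaves(self, small_matrix):
        dend = hcl(pearson_distance(small_matrix))
        nwk = dend.to_newick()
        for s in small_matrix.sample_ids:
            assert str(s) in nwk


class TestCutK:
    def test_k_one_and_k_n(self):
        D = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]])
        dend = hcl(D)
        assert cut_k(dend, 1).nunique() == 1
        assert cut_k(dend, 3).nunique() == 3

    def test_forced_two_cluster_cut(self):
        D = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]])
        labels = cut_k(hcl(D), 2)
        assert labels.iloc[0] == labels.iloc[1] != labels.iloc[2]
        assert labels.iloc[0] == 1  # larger cluster gets label 1

    def test_label_sizes_descending(self):
        rng = np.random.default_rng(1)
        D = rng.random((12, 12))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        labels = cut_k(hcl(D), 3)
        sizes = labels.value_counts().sort_index()
        assert (np.diff(sizes.to_numpy()) <= 0).all()


class TestCoClustering:
    def test_separated_blobs_are_maximally_stable(self):
        m, truth = _blob_cohort()
        cc, rep = co_clustering_stability(m, k=2, n_boot=200, seed=5)
        assert (rep.cluster_stats["mean_within_frequency"] >= 0.95).all()
        assert rep.mean_between_frequency <= 0.05
        assert (rep.cluster_stats["jaccard"] == 1.0).all()
        assert adjusted_rand_score(truth.subgroup, rep.labels) == 1.0

    def test_frequency_diagonal_is_one_and_matrix_symmetric(self):
        m, _ = _blob_cohort(seed=3)
        cc, _ = co_clustering_stability(m, k=2, n_boot=50, seed=1)
        F = cc.frequencies.to_numpy()
        np.testing.assert_allclose(np.diag(F), 1.0)
        np.testing.assert_allclose(F, F.T)
        assert ((F >= 0) & (F <= 1)).all()

    def test_pure_noise_not_significantly_stable(self):
        """Within-cluster frequencies on a null cohort resemble between-cluster ones."""
        rng = np.random.default_rng(9)
        m = _em(rng.normal(0, 1, (150, 30)))
        _, rep = co_clustering_stability(m, k=2, n_boot=200, seed=2)
        within = rep.cluster_stats["mean_within_frequency"].min()
        assert within < 0.8  # far from the stability threshold

    def test_invariant_under_sample_relabeling(self):
        m, _ = _blob_cohort(seed=6)
        cc1, rep1 = co_clustering_stability(m, k=2, n_boot=100, seed=7)
        renamed = ExpressionMatrix(m.values.set_axis([f"x{i}" for i in range(m.n_samples)], axis=1))
        cc2, rep2 = co_clustering_stability(renamed, k=2, n_boot=100, seed=7)
        np.testing.assert_allclose(cc1.frequencies.to_numpy(), cc2.frequencies.to_numpy())
        assert (rep1.labels.to_numpy() == rep2.labels.to_numpy()).all()


class TestAU:
    def test_clamps_for_always_and_never_recovered(self):
        m, _ = _blob_cohort(seed=2)
        res = au_probabilities(m, scales=(0.6, 1.0, 1.4), n_boot_per_scale=40, seed=1)
        cut = res.au_for_cut(2)
        assert (cut["au"] >= 90.0).all()  # both subgroup clusters strongly supported
        high = res.edges[res.edges["flag"] == "clamped_high"]
        low = res.edges[res.edges["flag"] == "clamped_low"]
        assert len(high) and (high["au"] == 100.0).all()  # recovered in every replicate
        assert (low["au"] == 0.0).all()
        assert (res.edges["au"].dropna() >= 0).all() and (res.edges["au"].dropna() <= 100).all()

    def test_bp_at_scale_one_matches_independent_feature_bootstrap(self):
        """The raw BP column at r = 1 equals a from-scratch feature-bootstrap
        proportion computed with the naive oracle clusterer and the same
        seed protocol."""
        rng0 = np.random.default_rng(0)
        m = _em(rng0.normal(0, 1, (40, 9)))
        scales = (0.6, 1.0, 1.4)
        n_boot = 30
        seed = 42
        res = au_probabilities(m, scales=scales, n_boot_per_scale=n_boot, seed=seed)

        # replicate the documented seed protocol independently
        X = m.values.to_numpy()
        n_feat = X.shape[0]
        full_sets = {
            frozenset(res.dendrogram.leaves_under(v))
            for v in range(res.dendrogram.n_leaves, res.dendrogram.n_leaves + len(res.dendrogram.merges))
        }
        rng = np.random.default_rng(seed)
        counts = {s: 0 for s in full_sets}
        for si, r in enumerate(scales):
            mm = int(np.ceil(r * n_feat))
            for _ in range(n_boot):
                idx = rng.integers(0, n_feat, size=mm)
                sub = X[idx]
                Z = (sub - sub.mean(axis=0)) / sub.std(axis=0)
                D = 1 - (Z.T @ Z) / sub.shape[0]
                np.fill_diagonal(D, 0)
                merges, _ = naive_complete_linkage(np.clip(D, 0, 2))
                leafsets = []
                n = D.shape[0]
                nodes = {i: [i] for i in range(n)}
                for k, (a, b) in enumerate(merges):
                    nodes[n + k] = nodes[a] + nodes[b]
                    leafsets.append(frozenset(nodes[n + k]))
                if si == 1:  # only the r=1 proportions are compared
                    for s in full_sets:
                        if s in leafsets:
                            counts[s] += 1
        for node in res.bp_by_scale.index:
            s = frozenset(res.dendrogram.leaves_under(node))
            assert res.bp_by_scale.loc[node, "1"] == pytest.approx(counts[s] / n_boot)

    def test_au_at_least_bp_for_scale_decreasing_edges(self):
        """Shimodaira curvature: AU exceeds BP for clusters whose support
        falls with the resampling ratio."""
        m, _ = _blob_cohort(seed=8, effect=1.2)
        res = au_probabilities(m, n_boot_per_scale=60, seed=3)
        ok = res.edges.dropna(subset=["v"])
        r = np.asarray(res.scales)
        for node, row in ok.iterrows():
            bp_r = res.bp_by_scale.loc[node].to_numpy()
            decreasing = bp_r[0] > bp_r[-1] + 0.1
            if decreasing and 1.0 < row["bp"] < 99.0:
                assert row["au"] >= row["bp"] - 1e-6


class TestIterativeSubgrouping:
    def test_two_subgroup_cohort_recovered_exactly(self):
        m, truth = _blob_cohort(seed=12, effect=2.0)
        centered = m.with_values(m.values.sub(m.values.mean(axis=1), axis=0))
        a = iterative_subgrouping(centered, n_boot=200, seed=4)
        assert a.n_subgroups == 2
        assert adjusted_rand_score(truth.subgroup, a.labels) == 1.0

    def test_null_cohort_stays_one_group(self):
        rng = np.random.default_rng(21)
        m = _em(rng.normal(0, 1, (200, 40)))
        a = iterative_subgrouping(m, n_boot=200, seed=5)
        assert a.n_subgroups == 1
        assert len(a.provenance) == 1 and not a.provenance[0]["accepted"]

    def test_nested_three_subgroups_permissive_vs_strict(self):
        """A designed cohort with a strong primary and a weaker secondary split
        yields 3 leaves at permissive thresholds and 2 at strict ones."""
        rng = np.random.default_rng(17)
        nA, nB, nC = 30, 18, 12
        X = rng.normal(0, 0.5, (300, nA + nB + nC))
        X[:60, nA:] += 2.5
        X[60:100, nA + nB:] += 0.8
        m = _em(X)
        permissive = iterative_subgrouping(m, n_boot=200, seed=3)
        strict = iterative_subgrouping(m, min_frequency=0.97, min_jaccard=0.95, n_boot=200, seed=3)
        assert permissive.n_subgroups == 3
        assert strict.n_subgroups == 2
        truth3 = np.r_[np.ones(nA), np.full(nB, 2), np.full(nC, 3)]
        assert adjusted_rand_score(truth3, permissive.labels) == 1.0

    def test_sklearn_front_end_matches_function(self):
        m, truth = _blob_cohort(seed=12, effect=2.0)
        centered = m.with_values(m.values.sub(m.values.mean(axis=1), axis=0))
        est = StabilitySubgrouper(n_boot=200, random_state=4).fit(centered.samples_by_features())
        a = iterative_subgrouping(centered, n_boot=200, seed=4)
        assert (est.labels_ == a.labels.to_numpy()).all()
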
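"""Hierarchical clustering with two stability engines.

Subgroup discovery proceeds by complete-linkage hierarchical clustering on
Pearson correlation distances, validated two ways:

* sample-bootstrap co-clustering: resample samples with replacement,
  recluster, and record how often each pair of samples lands in the same
  cluster; the consensus dendrogram built on these frequencies is compared
  with the full-data cut (per-cluster Jaccard), and clusters whose members
  co-cluster consistently count as stable;
* multiscale bootstrap of the features, giving per-edge approximately
  unbiased (AU) probabilities via the signed-distance model
  ``z(BP) = v*sqrt(r) + c/sqrt(r)``, AU = Phi(-v + c).

Stable splits are accepted recursively (always k = 2, re-centering genes
within each accepted subset) until no further stable split exists.

The agglomeration itself is written here rather than taken from scipy so
that ties in the minimal distance are broken deterministically (by the
smallest pair of node ids), which makes every clustering reproducible and
directly comparable against a brute-force oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator, ClusterMixin

from .io import ExpressionMatrix

logger = logging.getLogger("substrata")

__all__ = [
    "Dendrogram",
    "CoClusteringMatrix",
    "StabilityReport",
    "AUResult",
    "SubgroupAssignment",
    "pearson_distance",
    "hcl",
    "cut_k",
    "co_clustering_stability",
    "au_probabilities",
    "iterative_subgrouping",
    "StabilitySubgrouper",
]


# ---------------------------------------------------------------------------
# Distances and agglomeration
# ---------------------------------------------------------------------------


def pearson_distance(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Sample-sample distance ``1 - r`` over the feature set.

    Raises if any sample profile has zero variance (correlation undefined).
    """
    X = matrix.values.to_numpy()  # features x samples
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = matrix.sample_ids[np.flatnonzero(sd == 0)[0]]
        raise ValueError(f"sample {bad!r} has a zero-variance profile; Pearson distance undefined")
    Z = (X - X.mean(axis=0)) / sd
    corr = (Z.T @ Z) / X.shape[0]
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return pd.DataFrame(d, index=matrix.sample_ids, columns=matrix.sample_ids)


@dataclass
class Dendrogram:
    """Agglomerative merge tree.

    Leaves carry node ids ``0..n-1`` in input order; the i-th merge creates
    node ``n + i``.  ``merges[i]`` is the (smaller id, larger id) pair
    joined at ``heights[i]``.
    """

    leaf_ids: list
    merges: list[tuple[int, int]]
    heights: list[float]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def children(self, node: int) -> tuple[int, int] | None:
        n = self.n_leaves
        return None if node < n else self.merges[node - n]

    def leaves_under(self, node: int) -> list[int]:
        """Leaf node ids under ``node`` in left-to-right traversal order."""
        n = self.n_leaves
        out: list[int] = []
        stack = [node]
        while stack:
            v = stack.pop()
            if v < n:
                out.append(v)
            else:
                a, b = self.merges[v - n]
                stack.extend((b, a))
        return out

    @property
    def leaf_order(self) -> list[int]:
        if not self.merges:
            return list(range(self.n_leaves))
        return self.leaves_under(self.n_leaves + len(self.merges) - 1)

    def to_newick(self) -> str:
        n = self.n_leaves

        def fmt(node: int, parent_height: float) -> str:
            if node < n:
                return f"{self.leaf_ids[node]}:{parent_height:.6g}"
            a, b = self.merges[node - n]
            h = self.heights[node - n]
            return f"({fmt(a, h)},{fmt(b, h)}):{max(parent_height - h, 0.0):.6g}"

        root = n + len(self.merges) - 1
        h_root = self.heights[-1] if self.heights else 0.0
        if not self.merges:
            return f"({self.leaf_ids[0]}:0);"
        a, b = self.merges[-1]
        return f"({fmt(a, h_root)},{fmt(b, h_root)});"


def hcl(distances, linkage: str = "complete") -> Dendrogram:
    """Agglomerative clustering with deterministic tie-breaking.

    At every step the pair of clusters at minimal linkage distance is
    merged; among tied pairs the one with the lexicographically smallest
    (smaller node id, larger node id) is chosen.
    """
    if linkage != "complete":
        raise ValueError("only complete linkage is supported")
    if isinstance(distances, pd.DataFrame):
        leaf_ids = list(distances.index)
        D = distances.to_numpy(dtype=float).copy()
    else:
        D = np.asarray(distances, dtype=float).copy()
        leaf_ids = list(range(D.shape[0]))
    n = D.shape[0]
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if n == 1:
        return Dendrogram(leaf_ids, [], [])

    ids = np.arange(n)  # node id of the cluster currently at each position
    active = np.ones(n, dtype=bool)
    work = D.copy()
    np.fill_diagonal(work, np.inf)
    merges: list[tuple[int, int]] = []
    heights: list[float] = []
    for step in range(n - 1):
        masked = np.where(np.outer(active, active), work, np.inf)
        np.fill_diagonal(masked, np.inf)
        m = masked.min()
        cand = np.argwhere(masked == m)
        pairs = [
            (min(ids[i], ids[j]), max(ids[i], ids[j]), i, j)
            for i, j in cand
            if i < j
        ]
        lo, hi, i, j = min(pairs)
        merges.append((int(lo), int(hi)))
        heights.append(float(m))
        # complete linkage: distance to the merged cluster is the max
        new_row = np.maximum(work[i], work[j])
        work[i] = new_row
        work[:, i] = new_row
        work[i, i] = np.inf
        active[j] = False
        ids[i] = n + step
    return Dendrogram(leaf_ids, merges, heights)


def cut_k(dendrogram: Dendrogram, k: int) -> pd.Series:
    """Labels from removing the k-1 highest merges.

    Labels are 1-based, ordered by cluster size descending, ties by the
    cluster's first leaf in the dendrogram leaf order.
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    kept = dendrogram.merges[: n - k]  # heights are non-decreasing
    parent = list(range(n + len(kept)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for idx, (a, b) in enumerate(kept):
        node = n + idx
        parent[find(a)] = node
        parent[find(b)] = node
    roots: dict[int, list[int]] = {}
    for leaf in range(n):
        roots.setdefault(find(leaf), []).append(leaf)
    order_pos = {leaf: pos for pos, leaf in enumerate(dendrogram.leaf_order)}
    clusters = sorted(roots.values(), key=lambda c: (-len(c), min(order_pos[x] for x in c)))
    labels = np.empty(n, dtype=int)
    for lab, members in enumerate(clusters, start=1):
        labels[members] = lab
    return pd.Series(labels, index=dendrogram.leaf_ids, name="cluster")


# ---------------------------------------------------------------------------
# Sample-bootstrap co-clustering stability
# ---------------------------------------------------------------------------


@dataclass
class CoClusteringMatrix:
    frequencies: pd.DataFrame  # symmetric, [0, 1]
    counts_together: pd.DataFrame
    counts_present: pd.DataFrame
    n_bootstrap: int
    k: int
    seed: int | None


@dataclass
class StabilityReport:
    """Cluster labels plus the stability evidence supporting them."""

    labels: pd.Series  # full-data cut
    consensus_labels: pd.Series  # cut of the HCL on co-clustering frequencies
    cluster_stats: pd.DataFrame  # per cluster: size, mean_within_frequency, jaccard
    mean_between_frequency: float

    def is_stable(self, min_size: int, min_frequency: float, min_jaccard: float) -> bool:
        s = self.cluster_stats
        return bool(
            (s["size"] >= min_size).all()
            and (s["mean_within_frequency"] >= min_frequency).all()
            and (s["jaccard"] >= min_jaccard).all()
        )


def _jaccard(a: set, b: set) -> float:
    return len(a & b) / len(a | b)


def co_clustering_stability(
    matrix: ExpressionMatrix,
    k: int = 2,
    n_boot: int = 10_000,
    seed: int | None = None,
    distances: pd.DataFrame | None = None,
) -> tuple[CoClusteringMatrix, StabilityReport]:
    """Bootstrap samples, recluster, and summarize pairwise co-clustering.

    For each bootstrap the samples drawn (duplicates collapsed) are
    reclustered on the fixed feature set and cut at ``k``; the frequency
    for a pair is the fraction of bootstraps containing both in which they
    shared a cluster.  A consensus HCL on ``1 - frequency`` is cut at the
    same ``k`` and compared with the full-data cut by per-cluster Jaccard.
    """
    if n_boot < 1 or k < 2:
        raise ValueError("need n_boot >= 1 and k >= 2")
    rng = np.random.default_rng(seed)
    D = pearson_distance(matrix) if distances is None else distances
    Dv = D.to_numpy()
    n = matrix.n_samples
    dend = hcl(D)
    labels_full = cut_k(dend, k)

    together = np.zeros((n, n), dtype=np.int64)
    present = np.zeros((n, n), dtype=np.int64)
    for _ in range(n_boot):
        draw = rng.integers(0, n, size=n)
        u = np.unique(draw)  # duplicates collapse before clustering
        if len(u) < k:
            continue
        sub = Dv[np.ix_(u, u)]
        lab = cut_k(hcl(sub), k).to_numpy()
        present[np.ix_(u, u)] += 1
        for c in range(1, k + 1):
            members = u[lab == c]
            together[np.ix_(members, members)] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(present > 0, together / np.maximum(present, 1), np.nan)
    defined = ~np.isnan(freq)
    off = ~np.eye(n, dtype=bool)
    if (~defined & off).any():
        fill = np.nanmean(freq[off]) if defined[off].any() else 0.5
        miss = int((~defined & off).sum() // 2)
        logger.warning("%d sample pairs never co-sampled; imputing global mean frequency %.3f", miss, fill)
        freq = np.where(defined, freq, fill)
    np.fill_diagonal(freq, np.where(np.diag(present) > 0, 1.0, 1.0))

    freq_df = pd.DataFrame(freq, index=matrix.sample_ids, columns=matrix.sample_ids)
    cons_d = 1.0 - freq
    np.fill_diagonal(cons_d, 0.0)
    cons_labels = cut_k(hcl(pd.DataFrame(cons_d, index=D.index, columns=D.columns)), k)

    stats_rows = []
    cons_sets = {c: set(cons_labels.index[cons_labels == c]) for c in cons_labels.unique()}
    iu = np.triu_indices(n, 1)
    between_mask = labels_full.to_numpy()[iu[0]] != labels_full.to_numpy()[iu[1]]
    mean_between = float(freq[iu][between_mask].mean()) if between_mask.any() else float("nan")
    for c in sorted(labels_full.unique()):
        members = labels_full.index[labels_full == c]
        pos = [labels_full.index.get_loc(s) for s in members]
        if len(pos) > 1:
            sub = freq[np.ix_(pos, pos)]
            mean_within = float(sub[np.triu_indices(len(pos), 1)].mean())
        else:
            mean_within = 1.0
        jac = max(_jaccard(set(members), cs) for cs in cons_sets.values())
        stats_rows.append(
            {"cluster": c, "size": len(members), "mean_within_frequency": mean_within, "jaccard": jac}
        )
    stats = pd.DataFrame(stats_rows).set_index("cluster")
    cc = CoClusteringMatrix(freq_df, pd.DataFrame(together, index=D.index, columns=D.columns),
                            pd.DataFrame(present, index=D.index, columns=D.columns), n_boot, k, seed)
    report = StabilityReport(labels_full, cons_labels, stats, mean_between)
    return cc, report


# ---------------------------------------------------------------------------
# Multiscale bootstrap (AU probabilities)
# ---------------------------------------------------------------------------

DEFAULT_SCALES: tuple[float, ...] = tuple(np.round(np.arange(0.5, 1.41, 0.1), 2))


@dataclass
class AUResult:
    """Per-edge AU/BP support for the full-data dendrogram."""

    dendrogram: Dendrogram
    edges: pd.DataFrame  # per internal node: size, bp, au, v, c, flag
    bp_by_scale: pd.DataFrame  # internal node x scale raw bootstrap proportions
    scales: tuple[float, ...]
    n_boot_per_scale: int
    seed: int | None

    def au_for_cut(self, k: int) -> pd.DataFrame:
        """AU/BP of the clusters obtained by cutting the dendrogram at k."""
        labels = cut_k(self.dendrogram, k)
        leafset_to_node = {
            frozenset(self.dendrogram.leaves_under(node)): node
            for node in range(self.dendrogram.n_leaves, self.dendrogram.n_leaves + len(self.dendrogram.merges))
        }
        rows = []
        for c in sorted(labels.unique()):
            members = frozenset(
                i for i, leaf in enumerate(self.dendrogram.leaf_ids) if labels[leaf] == c
            )
            node = leafset_to_node.get(members)
            rows.append(
                {
                    "cluster": c,
                    "size": len(members),
                    "au": float(self.edges.loc[node, "au"]) if node is not None else np.nan,
                    "bp": float(self.edges.loc[node, "bp"]) if node is not None else np.nan,
                }
            )
        return pd.DataFrame(rows).set_index("cluster")


def au_probabilities(
    matrix: ExpressionMatrix,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    n_boot_per_scale: int = 1000,
    seed: int | None = None,
) -> AUResult:
    """Multiscale bootstrap of features with AU correction per edge.

    For each scale ``r``, ``ceil(r * n_features)`` features are resampled
    with replacement and the samples are reclustered; an edge's bootstrap
    probability BP(r) is the fraction of replicates whose dendrogram
    contains exactly that leaf set.  Per edge, the signed-distance model
    ``Phi^{-1}(1 - BP(r)) = v*sqrt(r) + c/sqrt(r)`` is fit by weighted
    least squares and AU = Phi(-v + c) * 100 reported, with BP quoted at
    the scale closest to 1.
    """
    scales = tuple(scales)
    if len(scales) < 2 or min(scales) >= 1 or max(scales) <= 1:
        raise ValueError("need >= 2 scales spanning values below and above 1")
    rng = np.random.default_rng(seed)
    n_feat = matrix.n_features
    Xv = matrix.values.to_numpy()

    full = hcl(pearson_distance(matrix))
    n = full.n_leaves
    internal = list(range(n, n + len(full.merges)))
    edge_sets = {node: frozenset(full.leaves_under(node)) for node in internal}

    counts = {node: np.zeros(len(scales), dtype=np.int64) for node in internal}
    for si, r in enumerate(scales):
        m = int(np.ceil(r * n_feat))
        for _ in range(n_boot_per_scale):
            idx = rng.integers(0, n_feat, size=m)
            sub = ExpressionMatrix(
                pd.DataFrame(Xv[idx], columns=matrix.sample_ids,
                             index=pd.RangeIndex(m)),
            )
            try:
                dd = hcl(pearson_distance(sub))
            except ValueError:
                continue  # a degenerate resample (zero-variance profile)
            found = {frozenset(dd.leaves_under(v)) for v in range(n, n + len(dd.merges))}
            for node, s in edge_sets.items():
                if s in found:
                    counts[node][si] += 1

    r_arr = np.asarray(scales)
    bp_scale_idx = int(np.argmin(np.abs(r_arr - 1.0)))
    rows, bp_rows = [], []
    for node in internal:
        bp_r = counts[node] / n_boot_per_scale
        bp_rows.append(bp_r)
        bp1 = float(bp_r[bp_scale_idx])
        flag = ""
        if np.all(bp_r >= 1.0):
            au, v, c = 100.0, np.nan, np.nan
            flag = "clamped_high"
        elif np.all(bp_r <= 0.0):
            au, v, c = 0.0, np.nan, np.nan
            flag = "clamped_low"
        else:
            eps = 1.0 / (2 * n_boot_per_scale)
            bp_c = np.clip(bp_r, eps, 1 - eps)
            z = norm.ppf(1.0 - bp_c)
            X = np.column_stack([np.sqrt(r_arr), 1.0 / np.sqrt(r_arr)])
            w = n_boot_per_scale * norm.pdf(z) ** 2 / (bp_c * (1.0 - bp_c))
            WX = X * w[:, None]
            try:
                v, c = np.linalg.solve(X.T @ WX, WX.T @ z)
            except np.linalg.LinAlgError:
                v, c = np.nan, np.nan
            au = float(norm.cdf(-v + c) * 100.0) if np.isfinite(v) else np.nan
        rows.append(
            {"node": node, "size": len(edge_sets[node]), "bp": bp1 * 100.0, "au": au, "v": v, "c": c, "flag": flag}
        )
    edges = pd.DataFrame(rows).set_index("node")
    bp_by_scale = pd.DataFrame(bp_rows, index=internal, columns=[f"{r:g}" for r in scales])
    return AUResult(full, edges, bp_by_scale, scales, n_boot_per_scale, seed)


# ---------------------------------------------------------------------------
# Iterative stable subdivision
# ---------------------------------------------------------------------------


@dataclass
class SubgroupAssignment:
    """Final per-sample subgroup labels plus the recursion provenance."""

    labels: pd.Series  # 1-based, ordered by subgroup size descending
    provenance: list[dict] = field(default_factory=list)

    @property
    def n_subgroups(self) -> int:
        return int(self.labels.nunique())


def iterative_subgrouping(
    matrix: ExpressionMatrix,
    min_cluster_size: int = 10,
    min_frequency: float = 0.8,
    min_jaccard: float = 0.75,
    max_depth: int | None = None,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> SubgroupAssignment:
    """Depth-first stable subdivision at k = 2.

    A split is accepted only when both children meet the minimum size,
    mean within-cluster co-clustering frequency and Jaccard agreement
    thresholds; accepted children are recursed into on the same feature
    set re-centered within the subset.  A cohort with no stable split
    returns a single group.
    """
    ss = np.random.SeedSequence(seed)
    provenance: list[dict] = []
    leaves: list[list] = []

    def recurse(sub: ExpressionMatrix, path: str, depth: int, sseq: np.random.SeedSequence) -> None:
        node_info = {"path": path, "n": sub.n_samples, "accepted": False}
        if (max_depth is not None and depth >= max_depth) or sub.n_samples < 2 * min_cluster_size:
            provenance.append(node_info)
            leaves.append(list(sub.sample_ids))
            return
        centered = sub.with_values(sub.values.sub(sub.values.mean(axis=1), axis=0))
        child_seed = int(sseq.generate_state(1)[0] % (2**31))
        _, report = co_clustering_stability(centered, k=2, n_boot=n_boot, seed=child_seed)
        node_info["cluster_stats"] = report.cluster_stats.to_dict("index")
        node_info["mean_between_frequency"] = report.mean_between_frequency
        if report.is_stable(min_cluster_size, min_frequency, min_jaccard):
            node_info["accepted"] = True
            provenance.append(node_info)
            children = sseq.spawn(2)
            for c, child_ss in zip(sorted(report.labels.unique()), children):
                members = report.labels.index[report.labels == c]
                recurse(sub.subset_samples(members), f"{path}.{c}" if path else str(c), depth + 1, child_ss)
        else:
            provenance.append(node_info)
            leaves.append(list(sub.sample_ids))

    recurse(matrix, "", 0, ss)
    leaves.sort(key=lambda m: (-len(m), [list(matrix.sample_ids).index(s) for s in m][0]))
    labels = pd.Series(0, index=matrix.sample_ids, name="subgroup")
    for lab, members in enumerate(leaves, start=1):
        labels[members] = lab
    return SubgroupAssignment(labels, provenance)


class StabilitySubgrouper(ClusterMixin, BaseEstimator):
    """scikit-learn front end for stability-based subgroup discovery.

    ``fit(X)`` (samples x genes) runs the iterative bootstrap-validated
    subdivision and exposes ``labels_`` plus the stability provenance.
    """

    def __init__(
        self,
        min_cluster_size: int = 10,
        min_frequency: float = 0.8,
        min_jaccard: float = 0.75,
        max_depth: int | None = None,
        n_boot: int = 10_000,
        random_state: int | None = None,
    ):
        self.min_cluster_size = min_cluster_size
        self.min_frequency = min_frequency
        self.min_jaccard = min_jaccard
        self.max_depth = max_depth
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, X, y=None):
        X_df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        matrix = ExpressionMatrix(X_df.T)
        assignment = iterative_subgrouping(
            matrix,
            min_cluster_size=self.min_cluster_size,
            min_frequency=self.min_frequency,
            min_jaccard=self.min_jaccard,
            max_depth=self.max_depth,
            n_boot=self.n_boot,
            seed=self.random_state,
        )
        self.assignment_ = assignment
        self.labels_ = assignment.labels.to_numpy()
        self.n_features_in_ = X_df.shape[1]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
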
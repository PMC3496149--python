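import numpy as np
import pandas as pd
import pytest

from substrata import ExpressionMatrix, SimulationConfig, simulate_expression


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at reference conditions (66 samples, 70/30, effect 1.5)."""
    return simulate_expression(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def null_cohort():
    """No subgroup effect, no batch effect."""
    return simulate_expression(SimulationConfig(effect_size_log2=0.0, batch_shift_log2=0.0, seed=23))


@pytest.fixture()
def small_matrix():
    rng = np.random.default_rng(3)
    vals = pd.DataFrame(
        rng.normal(7, 1, (30, 8)),
        index=[f"g{i}" for i in range(30)],
        columns=[f"s{i}" for i in range(8)],
    )
    return ExpressionMatrix(vals)


def naive_complete_linkage(D: np.ndarray):
    """Brute-force O(n^3) complete-linkage oracle.

    Recomputes every inter-cluster maximum from the original distances at
    each step (no Lance-Williams update) and breaks ties by the smallest
    (node id, node id) pair, mirroring the documented merge rule.
    """
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges, heights = [], []
    next_id = n
    for _ in range(n - 1):
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                dist = max(D[x, y] for x in clusters[a] for y in clusters[b])
                key = (dist, a, b)
                if best is None or key < best[0]:
                    best = (key, a, b)
        (dist, _, _), a, b = best
        merges.append((a, b))
        heights.append(dist)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges, heights
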
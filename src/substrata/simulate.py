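"""Synthetic expression cohorts with known subgroup, batch and survival structure.

The generator emulates the statistical structure the analysis pipeline
assumes in a two-subgroup bulk-expression cohort: a log2 intensity matrix
with two latent sample subgroups of unequal size, a block of
subgroup-informative genes (half up-, half down-regulated in the smaller
subgroup) on a background of null genes, additive hybridization-batch
offsets optionally confounded with subgroup, a fraction of low-signal
genes below the intensity filter line, and subgroup-linked exponentially
distributed metastasis times under uniform administrative censoring.

All randomness flows through one ``numpy`` Generator seeded from
``SimulationConfig.seed``, so a config is a complete, reproducible
description of a cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import ClinicalTable, ExpressionMatrix, GeneSetCollection

__all__ = ["SimulationConfig", "SyntheticTruth", "simulate_expression", "simulate_survival", "simulate_cohort"]


@dataclass
class SimulationConfig:
    """Generating parameters for one synthetic cohort.

    Defaults describe the reference condition used throughout the test
    suite: 66 samples in a 70/30 subgroup split, 2,000 genes of which 200
    are informative with a 1.5 log2-unit shift, three hybridization
    batches with a 0.8 log2-unit additive offset, Gaussian noise with
    SD 0.5, and ~10% of genes drawn below the 5.8 low-signal filter line.
    """

    n_samples: int = 66
    subgroup_proportions: tuple[float, float] = (0.70, 0.30)
    n_genes: int = 2000
    n_informative: int = 200
    effect_size_log2: float = 1.5
    n_batches: int = 3
    batch_shift_log2: float = 0.8
    #: probability that a subgroup-1 sample lands in batch 1 (subgroup-2
    #: samples mirror onto the last batch); None = balanced (1/n_batches).
    batch_confounding: float | None = None
    noise_sd_log2: float = 0.5
    baseline_mean_log2: float = 7.0
    low_signal_fraction: float = 0.1
    #: per-subgroup exponential hazards (events per year) for DMFS
    hazards: tuple[float, float] = (0.12, 0.04)
    #: administrative censoring times drawn Uniform(0, censor_window) years
    censor_window: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.subgroup_proportions) - 1.0) > 1e-9:
            raise ValueError("subgroup_proportions must sum to 1")
        if min(self.n_samples, self.n_genes, self.n_batches) <= 0:
            raise ValueError("counts must be positive")
        if not 0 <= self.n_informative <= self.n_genes:
            raise ValueError("n_informative must lie in [0, n_genes]")
        sizes = self._subgroup_sizes()
        if min(sizes) == 0:
            raise ValueError(f"degenerate config: subgroup sizes {sizes}")
        if self.batch_confounding is not None and not 0 <= self.batch_confounding <= 1:
            raise ValueError("batch_confounding must be a probability")

    def _subgroup_sizes(self) -> tuple[int, int]:
        n1 = int(round(self.n_samples * self.subgroup_proportions[0]))
        return n1, self.n_samples - n1


@dataclass
class SyntheticTruth:
    """Ground truth for a generated cohort, used by recovery tests."""

    subgroup: pd.Series  # per-sample label, 1 (larger) or 2
    batch: pd.Series  # per-sample batch label, "batch1"...
    informative: pd.Series  # per informative gene id: +1 (up in subgroup 2) or -1
    config: SimulationConfig

    def signed_module(self, name: str = "informative") -> GeneSetCollection:
        """The informative genes as a signed gene set (up in subgroup 2 = +1)."""
        members = {str(g): int(w) for g, w in self.informative.items()}
        return GeneSetCollection({name: members}, {name: "generator truth module"})


def simulate_expression(
    config: SimulationConfig, template: SyntheticTruth | None = None
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate one log2 expression cohort.

    values = gene baseline + subgroup shift (informative genes, signed)
    + additive batch offset + N(0, noise_sd) noise.  Low-signal genes get
    baselines drawn uniformly in (4.5, 5.4), safely below the 5.8 filter
    line; all other baselines sit at >= 6.5 so the filter separates the
    two populations cleanly.

    ``template`` reuses another cohort's informative gene ids and signed
    directions (requires the same ``n_genes``), emulating an external
    validation cohort that carries the same subgroup biology.
    """
    rng = np.random.default_rng(config.seed)
    n1, n2 = config._subgroup_sizes()
    sample_ids = pd.Index([f"S{i + 1:03d}" for i in range(config.n_samples)], name="sample_id")
    gene_ids = pd.Index([f"G{i + 1:05d}" for i in range(config.n_genes)], name="feature_id")

    subgroup = pd.Series(np.r_[np.ones(n1, int), np.full(n2, 2)], index=sample_ids, name="subgroup")

    # gene baselines: low-signal Bernoulli draw, others near baseline_mean
    low = rng.random(config.n_genes) < config.low_signal_fraction
    baseline = np.maximum(rng.normal(config.baseline_mean_log2, 0.4, size=config.n_genes), 6.5)
    baseline[low] = rng.uniform(4.5, 5.4, size=low.sum())

    # informative genes drawn from the non-low pool, direction split 50/50
    if template is not None:
        if len(template.informative) > config.n_genes:
            raise ValueError("template informative set exceeds n_genes")
        info_idx = np.asarray([gene_ids.get_loc(g) for g in template.informative.index])
        direction = template.informative.to_numpy()
        low[info_idx] = False
        baseline[info_idx] = np.maximum(baseline[info_idx], 6.5)
    else:
        high_idx = np.flatnonzero(~low)
        if len(high_idx) < config.n_informative:
            raise ValueError("not enough high-signal genes for the requested n_informative")
        info_idx = rng.choice(high_idx, size=config.n_informative, replace=False)
        info_idx.sort()
        direction = np.ones(config.n_informative, int)
        direction[: config.n_informative // 2] = -1
        direction = rng.permutation(direction)

    # batch assignment, optionally confounded with subgroup
    p = 1.0 / config.n_batches if config.batch_confounding is None else config.batch_confounding
    other = (1.0 - p) / max(config.n_batches - 1, 1) if config.n_batches > 1 else 0.0
    probs1 = np.full(config.n_batches, other)
    probs1[0] = p
    probs2 = np.full(config.n_batches, other)
    probs2[-1] = p
    if config.n_batches == 1:
        probs1[:] = probs2[:] = 1.0
    # every hybridization batch must hold >= 2 samples (as a planned design
    # would); redraw the rare degenerate assignment
    for _ in range(1000):
        batch_codes = np.where(
            subgroup.to_numpy() == 1,
            rng.choice(config.n_batches, size=config.n_samples, p=probs1 / probs1.sum()),
            rng.choice(config.n_batches, size=config.n_samples, p=probs2 / probs2.sum()),
        )
        if np.all(np.bincount(batch_codes, minlength=config.n_batches) >= 2):
            break
    else:
        raise ValueError("could not draw a batch assignment with >= 2 samples per batch")
    # offsets are centered so the batch effect does not move the overall
    # intensity scale (keeps low-signal genes below the filter line)
    batch_offsets = config.batch_shift_log2 * (
        np.arange(config.n_batches) - (config.n_batches - 1) / 2.0
    )

    values = baseline[:, None] + rng.normal(0.0, config.noise_sd_log2, size=(config.n_genes, config.n_samples))
    shift = np.zeros((config.n_genes, config.n_samples))
    shift[np.ix_(info_idx, np.flatnonzero(subgroup.to_numpy() == 2))] = (
        config.effect_size_log2 * direction[:, None]
    )
    values = values + shift + batch_offsets[batch_codes][None, :]

    batch = pd.Series([f"batch{b + 1}" for b in batch_codes], index=sample_ids, name="batch")
    feature_annot = pd.DataFrame(
        {"symbol": gene_ids, "quality": np.where(low, "good", "perfect")}, index=gene_ids
    )
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        feature_annot=feature_annot,
        sample_annot=batch.to_frame(),
    )
    truth = SyntheticTruth(
        subgroup=subgroup,
        batch=batch,
        informative=pd.Series(direction, index=gene_ids[info_idx], name="direction"),
        config=config,
    )
    return matrix, truth


def simulate_survival(truth: SyntheticTruth, config: SimulationConfig | None = None) -> ClinicalTable:
    """Censored metastasis times plus clinical covariates for a cohort.

    Event times are exponential with the per-subgroup hazard; censoring
    times are Uniform(0, censor_window) years.  Covariates mirror the
    marginal mix of an elderly male breast-cancer cohort; the NAT1 marker
    is generated positively associated with the better-prognosis subgroup.
    """
    config = config or truth.config
    if min(config.hazards) <= 0:
        raise ValueError("hazards must be positive")
    if config.censor_window < 0:
        raise ValueError("censor_window must be >= 0")
    # separate stream so expression and survival can be generated independently
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    g = truth.subgroup.to_numpy()
    n = len(g)
    hazard = np.where(g == 1, config.hazards[0], config.hazards[1])
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(0.0, config.censor_window, size=n)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    def pick(levels, probs):
        return rng.choice(levels, size=n, p=probs)

    df = pd.DataFrame(
        {
            "dmfs_time": time,
            "dmfs_event": event,
            "age": np.clip(rng.normal(70, 11, size=n).round(), 25, 98),
            "tumor_size": pick(["T1", "T2"], [0.33, 0.67]),
            "node_status": pick(["N0", "N+"], [0.3, 0.7]),
            "nhg": pick(["1", "2", "3"], [0.05, 0.45, 0.5]),
            "er": pick(["pos", "neg"], [0.95, 0.05]),
            "pr": pick(["pos", "neg"], [0.84, 0.16]),
            "her2": pick(["pos", "neg"], [0.05, 0.95]),
            "endocrine_therapy": pick(["yes", "no"], [0.65, 0.35]),
            "chemotherapy": pick(["yes", "no"], [0.1, 0.9]),
            "radiotherapy": pick(["yes", "no"], [0.5, 0.5]),
            "nat1": np.where(rng.random(n) < np.where(g == 1, 0.4, 0.8), "pos", "neg"),
        },
        index=truth.subgroup.index,
    )
    return ClinicalTable(df)


def simulate_cohort(config: SimulationConfig) -> tuple[ExpressionMatrix, ClinicalTable, SyntheticTruth]:
    """Expression matrix, clinical table and ground truth in one call."""
    matrix, truth = simulate_expression(config)
    clinical = simulate_survival(truth, config)
    return matrix, clinical, truth


def truth_to_json(truth: SyntheticTruth) -> dict:
    """JSON-serializable dump of the ground truth (CLI output)."""
    return {
        "subgroup": {str(k): int(v) for k, v in truth.subgroup.items()},
        "batch": {str(k): str(v) for k, v in truth.batch.items()},
        "informative": {str(k): int(v) for k, v in truth.informative.items()},
        "config": asdict(truth.config),
    }
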
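# Methods

`substrata` implements a subtype-discovery pipeline for bulk log2
expression cohorts of the kind produced by bead-array profiling of a
tumor series: normalize and batch-correct, select discriminating probes,
find sample subgroups that survive bootstrap scrutiny, characterize them
by differential expression and signed module scores, classify external
cohorts against subtype centroids, and relate subgroups and markers to
censored survival. This note records the models, the defaults and why
they are set where they are, the numerical choices, and what the
synthetic cohorts do and do not establish.

## Preprocessing

**Quantile normalization** forces every sample onto the mean empirical
distribution: the reference is the across-sample mean of each order
statistic, and each sample's values are replaced by the reference at the
corresponding rank. Tied input values receive the mean of the reference
over the tied run, so ties stay ties and the transform is idempotent on
tie-free data. Missing values are rejected rather than imputed: the
pipeline assumes complete post-normalization matrices, and imputation is
a modeling step that should not happen silently inside a normalizer.

**Batch correction** is the parametric empirical-Bayes location/scale
model of Johnson, Li & Rabinovic. Genes are standardized against a
batch-size-weighted grand mean and pooled variance; per-gene, per-batch
location (γ) and scale (δ²) effects are estimated and shrunk toward
batch-level priors (normal for γ, inverse-gamma for δ², hyperparameters
by method of moments, point estimates by the standard fixed-point
iteration, tolerance 1e-4). The implementation was checked against the
Bioconductor reference implementation on a multi-batch fixture and agrees
to ~5e-6 (the residual is the iteration stopping rule). Only the
parametric prior is implemented; the Gaussian simulation and typical
log2 array data match it, and the non-parametric variant would add a
slow code path the rest of the package never exercises.

The design matrix is intercept-only by default, with optional biological
covariates ("supervised" correction). This option matters more than it
looks: when the batch composition is even mildly unbalanced in the
biology, intercept-only correction absorbs the batch-wise subgroup mix
into the batch location estimates and imprints a compensating shift on
the dominant expression axis. On synthetic cohorts this residual is
rank-detectable on PC1 even though per-gene batch means are equalized;
adding the subgroup covariate removes it. The batch diagnostics in the
acceptance script therefore run the supervised design. A
`collapse_replicates` helper reduces re-hybridized replicate columns to
one column per tumor, keeping the replicate from the later batch.

**PCA diagnostics** run on the gene-centered matrix; categorical sample
annotations are tested against component scores by Kruskal–Wallis,
continuous ones by Spearman correlation, p-values reported untransformed.
On default synthetic cohorts the batch axis dominates PC1 before
correction (p ~ 1e-11) and is undetectable afterwards, while the subgroup
association is retained.

## Probe selection

Three steps define the clustering input: drop probes with mean intensity
below 5.8 log2 units (inclusive boundary: a probe exactly at the
threshold stays); keep the `k` most variable probes (default 1,652,
standard deviation by default, IQR by option); mean-center each probe.
Ties in variability break by probe id so the selection is identical
across platforms and column orders. An optional annotation-quality filter
(keep probes marked good/perfect) is exposed but off by default for
clustering.

## Stability-based subgrouping

Samples are clustered by complete-linkage agglomeration on Pearson
correlation distance (d = 1 − r over the selected probes). The
agglomerator is written in-package rather than taken from scipy because
reproducibility demands a defined tie rule: among pairs at the minimal
linkage distance, the lexicographically smallest (node id, node id) pair
merges first. This makes every dendrogram bit-reproducible and lets the
test suite require merge-for-merge equality with a brute-force O(n³)
oracle, including on tie-saturated fixtures.

Two independent stability engines judge a candidate split:

* **Sample-bootstrap co-clustering.** Resample samples with replacement
  (duplicates collapsed before clustering — complete linkage on exact
  duplicates is degenerate, and co-occurrence counts use presence, not
  multiplicity), recluster, cut at k = 2, and accumulate per-pair
  co-clustering frequencies conditioned on both samples being drawn.
  Pairs never co-drawn (vanishingly rare at these sizes) get the global
  mean frequency, with a log message. A consensus dendrogram built on
  1 − frequency is cut at the same k and compared with the full-data cut
  by per-cluster best-match Jaccard.
* **Multiscale feature bootstrap (AU).** For resampling ratios
  r = 0.5 … 1.4 (ten scales, matching common practice for this
  procedure), resample ⌈r·G⌉ probes with replacement and recluster; an
  edge's BP(r) is the fraction of replicates whose dendrogram contains
  exactly its leaf set. Per edge the signed-distance model
  Φ⁻¹(1 − BP(r)) = v√r + c/√r is fit by weighted least squares
  (binomial-variance weights, BP clipped to [1/2B, 1 − 1/2B]), and
  AU = Φ(−v + c)·100. Edges recovered in every replicate (or never) are
  clamped to 100 (or 0) and flagged.

**Iterative subdivision** recurses depth-first: split at k = 2, accept
only if both children have ≥ 10 samples, mean within-cluster frequency
≥ 0.8 and Jaccard ≥ 0.75, then re-center genes within each accepted
child and repeat. The recursion is dichotomous by design — the stability
gate, not the cut granularity, decides the final number of subgroups. A
cohort with no stable split returns one group. "Stable" needs numbers
the procedure's verbal description does not supply; 0.8/0.75 follow
consensus-clustering practice and sit far from both the separated-cohort
values (≈ 1.0 within, 0 between) and the null-cohort values (≈ 0.55).
Bootstraps default to 10,000; the test and acceptance runs use 200,
which at these cohort sizes estimates a pair frequency to ±0.035
(binomial SE), comfortably inside the 0.25 gap the thresholds leave.
The feature set is fixed from the full data rather than re-selected per
bootstrap replicate — resampling is of samples, and re-selection would
conflate feature-selection variance with clustering stability.

## Differential expression (SAM)

The two-class unpaired moderated statistic is d = (x̄₂ − x̄₁)/(s + s0)
with the pooled unequal-n standard error and a fudge factor s0 chosen
among the 0, 5, …, 100 percentiles of s to minimize the coefficient of
variation of the windowed MAD spread of d (100 s-quantile windows).
Constant genes (s = 0) are safe: the denominator is floored at the
smallest positive float, so a zero mean difference gives d = 0.

Permutations enumerate all distinct label arrangements when their count
is within the permutation budget (default cap 1,000), otherwise sample
distinct arrangements without replacement under the seed. Arrangements
are drawn as subsets of the smaller class, which makes the permutation
set invariant under swapping the class labels — so relabeling negates
every d exactly and swaps the up/down lists, a property the suite tests.

For each threshold Δ, asymmetric cutoffs start at the origin of the
observed-vs-permutation-averaged order-statistic plot and take the first
index whose displacement reaches Δ in each direction; genes beyond the
cutoffs are called, the falsely-called count per permutation is the
number of permuted d beyond the same cutoffs, and
FDR(Δ) = median falsely-called / #called (0 when nothing is called).
The delta grid is the exact set of achievable crossing displacements, so
the table contains every distinct operating point. Reported FDRs are
monotonized by a running minimum in Δ. "FDR 0" selects the smallest Δ
whose (monotonized) FDR is 0 — equivalently, the median permutation
false count is zero.

A calibration caveat the acceptance run documents honestly: at the Δ
that isolates the one to four most extreme observed order statistics,
the observed d is exchangeable with the permutation d under the null, so
with probability near one half more than half the permutations have no
value beyond the cutoffs and the median false count is zero. A null
cohort therefore yields a non-empty FDR-0 list in roughly 40% of runs
(one to four genes). This is a property of the median-count FDR rule
itself, not of this implementation — the suite verifies the statistic
and delta table against exhaustive enumeration — and it is why the
null-control acceptance test on SAM is expected to fail at its stated
95% bound while the bulk-calibration checks (FDR ≈ 1 where many genes
are called on null data) pass.

## Centroid classification

Subtype centroids are per-class means of gene-centered training
expression over a fixed symbol list (for discovered subgroups: the top
124 FDR-0 genes by |d|; ranking by |d| is the natural order on the SAM
statistic and is exposed as a parameter). Test cohorts are centered with
their own gene means — every dataset is centered separately, so
cross-platform intensity scales cancel — and each sample is assigned to
the centroid with the highest Pearson correlation over the shared genes
(Spearman by option), or left unclassified below the cutoff (default
0.2) or on an exact tie. Gene matching is by trimmed, case-folded
symbol; duplicate probes per symbol are averaged; classification refuses
to run below 50% centroid-gene overlap and logs the overlap otherwise.
The ER+ luminal classifier builder follows the same recipe starting from
an ER+ subset of a reference cohort: center, SAM between luminal A and
B, keep the top 300 FDR-0 genes, build centroids (all available genes,
with a warning, if fewer pass).

## Module scores

A signed module scores a sample as m.s. = Σ wᵢxᵢ / Σ|wᵢ| with
wᵢ ∈ {+1, −1}. The denominator is Σ|wᵢ| deliberately: with signed unit
weights a plain sum of weights can be zero or negative, whereas Σ|wᵢ|
makes the score a weighted mean on the log2 scale with a clean shift
equivariance (adding c to all matched genes adds c·Σwᵢ/Σ|wᵢ|).
Unmatched genes are dropped and reported as coverage. Group contrasts
use the two-sided Wilcoxon rank-sum test — exact enumeration when both
groups have ≤ 10 observations and no ties, tie-corrected normal
approximation (no continuity correction) otherwise — and 2×2
associations use Fisher's exact test with the conditional-MLE odds
ratio.

## Survival

Outcome analyses take distant metastasis-free survival with an optional
horizon: events after the horizon are censored at the horizon before
fitting (five-year analyses use horizon 5.0). Kaplan–Meier curves and
the log-rank test come from lifelines, as does the Cox
partial-likelihood fit (Efron tie handling). Categorical covariates are
coded against fixed reference levels — T2 vs T1, N+ vs N0, NHG 3 vs 1–2,
marker negative vs positive — so hazard ratios read in the conventional
"risk level vs reference" direction. Complete-case handling is
per-analysis: a record missing any requested covariate is dropped from
that fit only. ER is excluded from the default multivariate template
because cohorts of this kind have too few ER-negative tumors to support
it.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
with defaults fixed at the reference condition used throughout the
tests: 66 samples in a 70/30 split; 2,000 genes with 200 informative
(log2 shift 1.5 in the smaller subgroup, directions split 50/50
up/down); Gaussian noise SD 0.5 in log2 space (the pipeline operates on
log2 quantile-normalized intensities, so simulation is in log2 space
directly); three hybridization batches with additive offsets of 0.8
log2 units, centered to zero mean so the intensity scale is preserved,
and an optional confounding knob that biases subgroup-1 samples into the
first batch (balanced by default) — included because a confounded batch
structure is exactly the pathology a correction step must be tested
against; ~10% low-signal genes drawn below the 5.8 filter line (4.5–5.4,
separated from the ≥ 6.5 baselines so the filter boundary is never
ambiguous); and per-subgroup exponential metastasis hazards (0.12/yr
vs 0.04/yr, hazard ratio 3) under Uniform(0, 15 yr) administrative
censoring, chosen to give the event fraction and follow-up range of an
elderly male breast-cancer cohort. Batch assignments that would leave a
batch with fewer than two samples are redrawn, as a planned
hybridization design would. A `template` option replays another cohort's
informative-gene panel so an "external validation" cohort carries the
same subgroup biology on the same genes. Clinical covariates mirror the
marginal mix of such a cohort; the NAT1-like marker is generated
associated with the better-prognosis subgroup (80% vs 40% positive), so
its marginal prognostic effect is the induced, attenuated one (~1.3),
not an independent marker effect — cohort-level survival contrasts are
therefore reported per subgroup, where the design value (HR 3, ~2.5
after five-year truncation and censoring) is well defined.

What passing tests on these cohorts show: the pipeline recovers planted
structure at realistic effect and noise scales, its engines agree with
brute-force oracles, and its null behavior is calibrated. What they do
not show: robustness to probe-level artifacts, intensity-dependent
noise, annotation error, or non-Gaussian batch effects — none of which
the generator models.

## Problem sizes in the tests and acceptance runs

Bootstrap counts of 200 (co-clustering), 100 per scale (AU), and 100
permutations (SAM) are used throughout the suite and the acceptance
script; these follow the desk-scale convention of quoting
Monte-Carlo-error-aware tolerances rather than production counts
(defaults remain 10,000 / 1,000 / 1,000). The Cox Monte-Carlo check uses
event-rich designs because hazard-ratio recovery bounds are only
attainable when the Wald standard error is small enough; the module test
docstrings state the designs used.

## Known limitations

Non-parametric batch priors, paired or multiclass SAM, competing risks,
time-varying covariates, and concordance metrics are out of scope. The
AU machinery reports per-edge support for the full-data dendrogram only;
it does not search alternative topologies. The GEO-dialect reader parses
the series-matrix table fence and quoting conventions but not the
metadata header beyond skipping it.
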
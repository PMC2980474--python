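# Methods

This note documents the models and procedures implemented in `mogasvm`,
the defaults and why they were chosen, the numerical edge-case rules, and
what the synthetic test substrate does and does not establish.

## Preprocessing

The pipeline is variance filter → log transform → per-sample z-score, in
that order (the filter therefore ranks genes on raw-scale variances):

- **Variance filter.** Keeps the `top_n = 200` genes with the largest
  across-sample variance, computed with the unbiased (n−1) estimator;
  relative gene order is preserved. `top_n ≥ n_genes` keeps everything
  with a logged warning.
- **Log transform.** `log2(max(v, 1e-8))` by default. Base and floor are
  configurable; non-positive cells (possible in ratio-format matrices)
  are floored rather than rejected, with the floored count logged. The
  step can be skipped (`apply_log=False`) for data already on a log-like
  scale — this is how the synthetic Gaussian data are processed.
- **Standardization.** Each sample profile is scaled to mean 0 and
  variance 1 using the population (n) variance so the result is exact per
  row; a constant profile is an error naming the sample. Missing values
  are rejected at load; no imputation is attempted.

## Multiobjective clustering

**Encoding and initialisation.** A chromosome holds K centers of dimension
d (the retained gene count). Initial centers are K distinct data points
drawn per chromosome.

**Objective evaluation** performs exactly one reassign/update cycle:
nearest-center assignment (ties to the lowest cluster index), center
recomputation, reassignment, and write-back of the updated centers into
the chromosome. Objectives:

- σ: the summed distance from every sample to its assigned center.
- 1/Sep with `Sep = min` pairwise center distance by default.

**Why minimum separation.** With the sum-of-pairs aggregate, ever-larger
center spread keeps paying on the separation objective, so the evolved
front stretches toward extreme-separation solutions whose one-step-k-means
labelings are distorted; majority voting over such a front inherits the
distortion. The minimum pairwise distance saturates once each center
occupies its own data cluster, so the front concentrates around genuinely
good partitions — which the downstream consensus step relies on. Measured
on planted four-class data (Δ = 3), the min variant recovers the planted
partition exactly across seeds while the sum variant does not; both remain
available via `GAConfig.separation`.

**Degenerate solutions.** Coincident centers (Sep = 0) receive worst
objectives (∞, ∞). A cluster left empty after assignment is repaired by
re-seeding its center at a uniformly random data point and reassigning
(bounded retries, then forced adoption of the re-seeded point); repairs
are counted in the front's provenance.

**Genetic machinery.** Standard elitist NSGA-II: fast non-dominated
sorting (vectorised dominance matrix), crowding distance (boundary members
infinite; a zero-range objective contributes 0 to interior members),
crowded binary tournament selection with a seeded coin flip on full ties,
single-point crossover on the flattened center string (cut points may fall
inside a center's coordinate block), and per-chromosome mutation that
moves one uniformly chosen center by a uniform draw within ±10% of the
per-gene data range (`mutation_scale = 0.1`). Each generation merges the
parent and child populations and truncates by rank then crowding. Defaults
— population 50, 100 generations, crossover probability 0.8, mutation
probability 0.01, Euclidean distance — are the standard settings for this
family of methods; Pearson correlation distance (1 − r) is available, and
behaves like Euclidean on per-sample standardized profiles.

**Medoid mode.** `center_update="medoid"` replaces the mean update by the
cluster member minimising the summed distance to its co-members (the full
sample–sample distance matrix is precomputed once per run). Medoid centers
are always actual data rows and are insensitive to mean-dragging by
moderately aberrant profiles.

## SVM-ensemble consensus

The front's S label vectors are aligned to the member with minimum σ
(chosen as a deterministic, quality-biased reference) by
maximum-agreement optimal assignment on the K×K contingency table —
alignment is a pure relabeling and never changes which samples are
co-clustered. A sample becomes a training point iff its most-voted label
has at least ⌈β·S⌉ votes and is the unique maximum; top-ties (possible
for β ≤ 0.5) are excluded so only unambiguous majorities train the
classifier, and coverage is therefore non-increasing in β. The default
β = 0.5 trades training-set size against confidence; behaviour is flat
across β ∈ [0.4, 0.6] on separable data.

Four one-against-all soft-margin SVMs are fitted per kernel (linear,
polynomial degree 3, sigmoidal, RBF; C = 1, γ = 1/d, coef0 = 0 — standard
defaults, as no tuning is part of the method). The maximum-margin
quadratic program is delegated to scikit-learn's solver behind the
`KernelSpec` contract. Training points always keep their voted labels;
only the remaining samples are classified. The four labelings are fused by
per-sample majority vote with seeded uniform tie-breaking.

**Missing-class fallback.** If the voted training set lacks one of the K
classes, β is lowered in steps of 0.1; if classes are still missing at
β = 0.1 the reference member's labels are returned, loudly logged. This
situation does not arise on well-separated data but occurs in hard
regimes (small effect sizes, or K above the true structure during sweeps).

## Cluster number, validation, significance

- **Silhouette.** s(x) = (b−a)/max(a,b) with a the mean within-cluster
  distance and b the smallest mean distance to another cluster; singleton
  clusters score 0. The index is the plain mean over samples.
- **K sweep.** For each K in [2, k_max] (default k_max = ⌊√n⌋, a standard
  heuristic bound), the full pipeline runs `runs_per_k` times (default 10)
  from derived seeds; each K is represented by its best run and the K with
  the highest best silhouette wins, ties to the smaller K. A run collapsing
  to one cluster scores −1.
- **%CA** = 100·(n11+n00)/total over sample pairs; **ARI** is the
  Hubert–Arabie chance-corrected form computed from the contingency table.
  ARI can be negative and is reported as computed; the degenerate 0/0 case
  (e.g. both partitions a single cluster) is defined as 1 for identical
  partitions, else 0.
- **t-test.** Pooled-variance two-sided by default (Welch available); two
  zero-variance groups with equal means return (t = 0, p = 1).

## Gene markers

One-vs-rest per cluster: SNR = (μ₁−μ₂)/(σ₁+σ₂) with sample (n−1) standard
deviations (the population convention is available via `ddof`), or a
Welch t statistic (pooled by flag). A zero denominator yields 0 when the
means agree and a signed ∞ when they differ, so perfectly separating
genes rank first instead of crashing. The 5 largest positive and 5 most
negative scores form the class's marker table, ordered by |score| with
ties broken by gene index; shortfalls are logged, never padded.
Aggregation across R runs (on one dataset) reports per-gene selection
frequency and keeps the 10 most frequent genes, ties by mean |score| then
gene id.

## Synthetic substrate

`SyntheticSpec` plants K classes (default 4 × 15 samples; unequal sizes
such as 23/8/12/20 supported), 200 genes, and 10 markers per class (5 up,
5 down) shifted by ±Δ·noise_sd in that class only, on an i.i.d. Gaussian
background (sd 1). Δ = 3 gives well-separated classes (a nearest-centroid
classifier on true labels reaches ARI 1), Δ = 1.5 a hard regime. Outlier
injection multiplies ⌈fraction·n⌉ whole sample profiles by a scale factor.
Everything derives from one seed and is byte-reproducible.

What this does **not** emulate: gene–gene correlation, heavy-tailed or
multiplicative noise, batch effects, dye bias, missing values, or class
structure expressed through correlated programs rather than mean shifts.
Passing tests establish algorithmic correctness and recovery under the
planted model, not performance on real cohorts, where score levels are
substantially lower.

## Known limitations

- Under extreme whole-profile outliers (profiles scaled ×10), isolating
  the outliers as singleton clusters dominates the planted structure on
  *both* objectives, so mean- and medoid-mode runs converge to the same
  outlier-isolating partitions; the medoid update protects the center
  estimate, not the objective landscape. Milder contamination is where the
  medoid variant is expected to pay off.
- The consensus step assumes the front is concentrated around good
  partitions; with the sum-separation objective, or K far above the true
  structure, voted training labels can be unreliable (mitigated by the
  fallback policy).
- One reassign/update cycle per evaluation is intentionally cheap; the GA,
  not the embedded step, is responsible for convergence.
- Problem sizes in the test suite and acceptance script (60–63 samples,
  200 retained genes, 5–20 runs per condition, 30 generations inside
  K sweeps) were chosen as the smallest configurations at which the
  planted-recovery and ordering properties are stable across seeds.
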
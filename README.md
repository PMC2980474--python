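# mogasvm

Unsupervised multi-class classification of tumor expression profiles by
**multiobjective evolutionary clustering with an SVM kernel-ensemble
consensus**, plus per-subtype gene-marker identification.

Microarray and bulk expression studies of cancer subtypes ship a samples ×
genes matrix and, often, no trustworthy sample labels. This package
clusters the samples without supervision, picks the number of clusters,
scores the result against a reference partition when one exists, and ranks
the genes that distinguish each discovered subtype. It is aimed at
computational biologists working with small-cohort tumor panels (tens to a
few hundred samples, after reduction to ~200 high-variance genes).

## Method

**Multiobjective clustering.** A candidate solution is a chromosome of K
cluster centers z₁…z_K in gene space (a flat real vector of length K·d).
Two conflicting criteria are minimised simultaneously with the elitist
NSGA-II evolutionary algorithm:

- global compactness σ = Σₖ Σ_{xᵢ∈Cₖ} D(xᵢ, zₖ) — summed distance of every
  sample to its assigned center; and
- 1/Sep, the reciprocal of cluster separation, with Sep = minₖ<ₗ D(zₖ, zₗ)
  (a sum-of-pairs variant is available).

Evaluating a chromosome embeds one k-means-style cycle: assign each sample
to its nearest center, recompute centers as cluster means (or medoids, for
outlier robustness), reassign, and write the updated centers back. The
final generation's non-dominated front is a set of near-Pareto-optimal
clusterings.

**SVM-ensemble consensus.** The front is fused into one partition:

1. decode every front member's label vector and make the labels consistent
   with the minimum-σ member by optimal assignment;
2. samples whose top label wins at least β·S of the S front votes (β = 0.5
   by default) become training points with that label;
3. K one-against-all soft-margin SVMs are trained under each of four
   kernels — linear, polynomial, sigmoidal, RBF — and classify the
   remaining low-confidence samples;
4. the four kernel labelings are fused by per-sample majority vote (ties
   broken randomly under the run seed).

**Model selection and validation.** The cluster number is chosen by
maximising the mean silhouette index s̄ over a K sweep. Partitions are
compared with %CA (pair-agreement percentage) and the Hubert–Arabie
adjusted Rand index; per-run score groups of competing methods can be
compared with a two-sample t-test.

**Gene markers.** For each cluster, genes are scored one-vs-rest with the
signal-to-noise ratio SNR = (μ₁−μ₂)/(σ₁+σ₂) (or a t statistic); the 5 most
positive (up-regulated) and 5 most negative (down-regulated) genes are the
subtype's markers, and selections can be aggregated across stochastic runs
by frequency.

A seeded synthetic generator plants this exact structure (K classes,
unequal sizes, marker genes shifted ±Δ within-class SD on a Gaussian
background, optional scaled-profile outliers) and backs the test suite.

## Worked example

```python
from mogasvm import (SyntheticSpec, generate, preprocess, GAConfig,
                     run_mogasvm, adjusted_rand, percent_ca,
                     markers_per_class, align_labels)

spec = SyntheticSpec(n_classes=4, samples_per_class=[23, 8, 12, 20],
                     n_genes=1000, effect_size=3.0, seed=7)
ds = generate(spec)                                # 63 samples x 1000 genes
X = preprocess(ds.X, top_n=200, apply_log=False)   # keep 200 genes, z-score
res = run_mogasvm(X.values, 4, GAConfig(seed=7))
print(res.report())
print(f"ARI vs truth : {adjusted_rand(ds.true_labels, res.labels):.4f}")
print(f"%CA vs truth : {percent_ca(ds.true_labels, res.labels):.4f}")

pred = align_labels(ds.true_labels, res.labels, 4)
print(markers_per_class(X.values, pred, gene_ids=X.gene_ids)[0].table)
```

Output:

```
K: 4
front size: 50
beta used: 0.5
training coverage: 1.0000
fallback to reference labels: False
kernels: linear, polynomial, sigmoidal, rbf
ARI vs truth : 1.0000
%CA vs truth : 100.0000
gene_id     score direction  rank  frequency_pct
  G0989  1.847988        up     1          100.0
  G0128  1.620987        up     2          100.0
  ...
  G0273 -1.858606      down     6          100.0
  ...
```

All 50 non-dominated solutions agree on every sample (coverage 1.0), the
consensus matches the planted subtypes exactly (ARI 1, %CA 100), and the
top-ranked markers for cluster 1 are genes planted as up-/down-regulated
for that class, with the sign of the SNR giving the direction.

The same pipeline is available from the shell:

```bash
mogasvm simulate --classes 4 --per-class 23,8,12,20 --genes 1000 \
    --effect 3 --seed 7 --out data.tsv --labels-out truth.tsv
mogasvm preprocess data.tsv --out pre.tsv --top-n 200 --skip-log
mogasvm run pre.tsv --k 4 --seed 7 --out labels.tsv
mogasvm select-k pre.tsv --runs 5 --generations 30
mogasvm evaluate pre.tsv --truth truth.tsv --pred labels.tsv
mogasvm markers pre.tsv --labels labels.tsv --scorer snr
```

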
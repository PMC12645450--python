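# Methods

## The model

`perturbnet` stratifies a disease cohort by how far each patient's gene
*interactions* — not individual gene levels — have drifted from a healthy
reference. The premise is that the relative ordering of interacting genes is
stable and conserved in healthy tissue and disrupted in disease.

For an expression matrix X (genes × samples) and a directed background
network of gene pairs, the construction is:

1. **Rank matrix.** Within each sample s, genes are ranked by expression,
   ascending (lowest expression → rank 1), with ties receiving the average
   rank. Average ties keep the per-sample rank sum at G(G+1)/2 and make the
   transform a pure function of the within-sample ordering.
2. **Delta-rank matrix.** For every network edge (a → b),
   d(e, s) = r(a, s) − r(b, s). Direction is fixed metadata: reversing an
   edge negates its row.
3. **Reference baseline.** b(e) = mean of d(e, ·) over the reference
   (healthy) samples. The arithmetic mean is used, not a robust location
   estimate; with ≥ 20 reference samples the mean is the natural estimator
   of the conserved delta-rank and keeps the construction linear.
4. **Interaction–perturbation matrix.** p(e, s) = d(e, s) − b(e). By
   construction the mean of p over the baseline-fitting reference samples is
   exactly zero for every edge; disease samples deviate where their
   interactions are disturbed.

Because every step depends only on within-sample orderings, the rank, delta
and perturbation matrices are *exactly* invariant under any strictly
increasing per-sample transform of the expression values. This is the
property that lets one cohort's subtypes transfer to cohorts measured on
other platforms without batch correction.

### Edge filtering

Edges that separate the conditions are retained by a per-edge two-sided
Wilcoxon rank-sum test of p(e, ·) between reference and disease samples,
with Benjamini–Hochberg adjustment and retention at q < 0.05 (the
nonparametric two-group test is the package's default policy; the source
method names no specific test). A `max_edges` cap keeps the smallest-q edges
(ties broken by larger absolute mean difference, then lexicographic edge
id) when a fixed feature count is wanted.

A scale-free diagnostic is reported for the constructed network: the
Pearson correlation between log10(degree) and log10(degree frequency) over
observed distinct degrees (no binning), on the undirected skeleton.

### Consensus clustering

Subtypes are discovered by Monti-style consensus clustering of the disease
samples in the retained edge-feature space, implemented from the
definition:

- For each k in 2..k_max (default 9): `reps` (default 1000) subsamples of
  ⌈p_item · n⌉ samples (default p_item 0.8; an optional `p_feature`
  subsamples features, default 1.0), k-means with Euclidean distance on
  each subsample (greedy k-means++ seeding, 10 restarts), and a consensus
  matrix M_k = co-clustering count / co-sampling count, with 0/0 := 0 and a
  unit diagonal. Features are used as-is (no scaling): perturbation values
  share a common rank-derived scale.
- Replicate seeds derive from the master seed by counter
  (`SeedSequence(seed, spawn_key=(k, rep))`), so replicates are order
  independent and the whole result is bit-reproducible.
- The final partition at each k cuts an average-linkage dendrogram of
  1 − M_k; clusters are renumbered by decreasing size (ties by smallest
  member id).

Stability diagnostics per k: the per-cluster consensus score (mean of M_k
over within-cluster pairs; singletons count as 1.0), the CDF of off-diagonal
co-sampled consensus values, its area A(k) (computed in closed form as
1 − mean of those values), the relative delta-area (Δ(2) = A(2),
Δ(k) = (A(k) − A(k−1))/A(k−1)), and the proportion of ambiguous clustering
PAC (CDF mass between consensus 0.1 and 0.9).

**Cluster-number recommendation.** The recommended k is the largest
delta-area *among stable k*, where a partition is stable when every cluster
consensus score is ≥ 0.75. The restriction matters: Δ(2) equals A(2), which
is ≥ 0.44 for any three balanced clusters, so an unrestricted argmax is
biased toward k = 2 — but exactly when the k = 2 merge inflates its
delta-area by being ambiguous, its cluster consensus drops below 0.75. The
two criteria are complementary, and both are published selection rules for
this family of methods. When no k is stable the plain argmax is returned
(and no k is flagged stable in the report).

### Subtype extension (nearest-template prediction)

Per-subtype marker templates are the top n_top (default 300) genes by
one-vs-rest Welch t statistic, positive side only; a gene topping several
subtypes is assigned to the one with the larger statistic so templates stay
disjoint. An unmoderated t is a deliberate simplification — only the
ordering is consumed, no inference is done on it.

Prediction standardizes the external cohort gene-wise (mean 0, SD 1 across
its own samples, ddof 1; constant genes are excluded with a warning), which
absorbs any gene-wise affine distortion. Each sample is assigned to the
subtype whose binary template vector (1 on its markers, 0 on other
templates' markers, over the union of template genes present in the cohort)
is nearest in cosine distance. Significance: each resample draws one random
gene set per subtype (same sizes, from all measured genes, shared across
samples); the null statistic is the *minimum* distance across those random
templates, matching the argmin selection of the observed statistic — without
this matching the p-values are anti-conservative under the null. p = (1 +
#{null ≤ observed}) / (n_resample + 1), then Benjamini–Hochberg across the
cohort; samples with FDR < 0.05 are called classifiable. Templates require
≥ 50% marker coverage in the external cohort.

### Scoring and survival

**ssGSEA.** Per sample, genes are walked from highest to lowest expression;
an in-set weighted ECDF (weight = (ascending rank)^alpha, alpha default
0.25, the originating method's default) is compared step by step with an
unweighted out-of-set ECDF, and the enrichment score is the sum of the
stepwise differences. The weight uses the gene's rank position rather than
its expression value, keeping scores platform-robust; at alpha = 0 the
statistic reduces to the unweighted running sum. Sets retaining fewer than
5 genes after projection are dropped.

**NRS.** The normalized risk score applies a per-gene coefficient table to
gene-wise standardized expression: NRS(s) = Σ_g coef(g) · z(g, s) over
shared genes (≥ 30% of coefficient genes must be measured; missing genes
contribute 0). The score is exactly equivariant in the coefficients. An
optional min–max normalization across the cohort is provided; the default
leaves the linear score untouched.

**Survival.** Kaplan–Meier product-limit curves per group and the k-group
log-rank test (lifelines). Score-based splits use the median, with ties —
and the extra sample at odd n — going to the low group.

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes, so
every stage is testable without external downloads.

- **Reference structure.** Gene baselines are drawn once
  (Normal(6, 2), a log2-intensity-like scale); every sample is baseline +
  Normal(0, noise_sd) noise (noise_sd default 1). Reference samples thus
  share a conserved within-sample ordering up to noise.
- **Network.** Barabási–Albert preferential attachment over the first
  n_nodes genes (defaults 200 nodes, 16 attachments per node), each edge
  given a random fixed direction. The density (~15 edges per node) is a
  desk-scale analog of pathway-derived functional-interaction backgrounds,
  which are dense (tens of edges per node); at this scale density is what
  couples the subtypes' disturbances through shared endpoint genes.
- **Planted subtypes.** Each subtype owns a disjoint set of planted edges
  (default 50 per subtype, drawn in a seeded random order). A planted edge
  perturbs its subtype's samples by shifting the two endpoint genes in
  opposite directions by perturbation_strength × noise_sd (default 3),
  against the baseline ordering, so the edge's delta-rank flips sign. A
  gene's shift direction is *intrinsic* — the same whenever any subtype
  hits it — reflecting that a gene's disease dysregulation direction is a
  property of the gene while subtypes differ in which interactions they
  disturb; directions propagate through shared endpoints, and an edge whose
  endpoints are already forced to the same direction is skipped during
  planting (its delta-rank flip would be undefined). Endpoint genes double
  as the subtype's expression signature for marker/NTP testing.
- **Platforms.** `regenerate_for_platform` applies a named strictly
  increasing transform (identity, cube root, logistic, affine) plus fresh
  noise — ranks are preserved exactly at zero noise.
- **Survival.** Disease samples draw exponential event times with
  subtype-specific hazards (defaults 0.08, 0.04, 0.02 per time unit,
  worst-to-best across subtypes) and independent exponential censoring
  calibrated to a 20% censoring fraction. Reference samples carry no
  follow-up, mirroring cohorts where healthy controls have no outcome data.

What the generator does **not** emulate: count-level noise (negative
binomial dispersion), correlated gene modules beyond the planted edges,
batch effects other than monotone distortions, informative censoring, and
covariate-driven hazards. Passing tests therefore demonstrate correctness
of the machinery and recoverability of planted structure under idealized
noise — not performance on real cohorts.

## Numerical choices and degenerate inputs

- Ranks: `scipy.stats.rankdata` (average ties); ssGSEA walk order breaks
  expression ties by gene position (stable sort).
- Consensus matrices are exactly symmetrized; pairs never co-sampled have
  consensus 0 and are excluded from the CDF.
- Wilcoxon tests use the SciPy Mann-Whitney implementation (normal
  approximation with ties correction at these sample sizes).
- Degenerate inputs raise typed errors rather than produce numbers: all-tied
  degree distributions (scale-free fit), constant scores (median split),
  zero events (log-rank), empty network/expression overlap, fewer than 2
  reference samples.
- Exact decimal round-trip of outputs uses 17-significant-digit text and
  round-trip float parsing.

## Problem sizes used in the checks

The default synthetic study conditions are 2,000 genes, 20 reference + 3×40
disease samples, 50 planted edges per subtype at strength 3. The test suite
and the acceptance script run consensus clustering at these conditions with
scaled replicate counts (100–500 replicates for single-cohort diagnostics,
60 replicates over k ≤ 4 for multi-cohort recovery loops; the full protocol
default remains 1000), and use a scaled cohort (300 genes, 60-node network,
10 reference + 3×12 disease) for the 20-replicate null-calibration checks.
These sizes are the package's reported experiment sizes; rerunning with
larger replicate counts does not change the conclusions, only the
granularity of the consensus estimates.

## Known limitations

- The edge filter tests reference vs all disease samples; a perturbation
  confined to a single small subtype with few reference samples has a hard
  power ceiling under any rank test, so subtype-exclusive edges are
  recovered less reliably than edges disturbed in several subtypes.
- NTP p-values rely on gene exchangeability under the null; strongly
  co-expressed marker sets in real data violate this and make the FDR
  approximate.
- The bulk NRS is one concrete reading of "apply the fitted per-gene
  coefficients to external data": coefficient-weighted standardized
  expression. Other readings (e.g., re-fitted intercepts, logistic link)
  would change the scale but not the ordering the package reports.
- ssGSEA scores are comparable across samples within a cohort; comparing
  raw scores across cohorts requires the optional min–max normalization and
  still carries platform effects for alpha > 0 only through rank positions.
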
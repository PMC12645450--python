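# perturbnet

Rank-based interaction-perturbation networks for molecular subtyping of bulk
expression cohorts — built for the sepsis setting (heterogeneous peripheral
blood cohorts, healthy controls as reference, survival follow-up), but
generic over any disease/reference design with a directed gene-interaction
background.

## The problem and the method

Single-gene panels miss how disease rewires the *relationships* between
genes. Within a healthy sample, the relative ordering of two interacting
genes is remarkably conserved; in disease it is not. `perturbnet` quantifies
that disruption per interaction and per patient:

- rank genes within each sample: r(g, s);
- for each directed edge (a → b) of a background network, take the
  delta-rank d(e, s) = r(a, s) − r(b, s);
- subtract the healthy baseline b(e) = mean of d(e, ·) over reference
  samples, giving the interaction–perturbation value
  p(e, s) = d(e, s) − b(e) — near zero in health, deviating in disease.

Everything downstream works on p: edges separating healthy from disease
samples are kept (Wilcoxon rank-sum + Benjamini–Hochberg), disease subtypes
are discovered by Monti-style consensus k-means over sample subsamples
(consensus matrices, CDF/delta-area, PAC, per-cluster consensus scores),
subtypes are extended to external cohorts by nearest-template prediction
(cosine distance to binary marker templates, resampling FDR), and subtypes
or per-sample scores (ssGSEA pathway activity, coefficient-based risk
scores) are tied to outcome with Kaplan–Meier curves and log-rank tests.
Because the features are within-sample ranks, results are exactly invariant
to any monotone per-sample distortion — the property that lets subtypes
transfer across array and RNA-seq platforms without batch correction.

A synthetic-cohort generator with planted ground truth (conserved reference
orderings, subtype-specific edge flips, platform distortions,
subtype-linked exponential survival) makes the whole pipeline testable end
to end. See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import perturbnet as pn
from sklearn.metrics import adjusted_rand_score

# a synthetic cohort with three planted subtypes and survival
cohort = pn.generate_cohort(pn.SyntheticCohortConfig(seed=1))

# expression -> ranks -> delta-ranks -> perturbation vs healthy baseline
ranks = pn.rank_transform(cohort.expression)
delta = pn.delta_rank(ranks, cohort.network)
pert = pn.perturbation_matrix(delta, cohort.expression.samples_with("reference"))

# keep significantly perturbed edges, cluster the disease samples
filt = pn.select_perturbed_edges(pert, cohort.expression.condition)
disease = cohort.expression.samples_with("disease")
res = pn.consensus_cluster(filt.values[disease], k_max=6, reps=100, seed=41)
labels = pn.assign_labels(res, res.recommended_k)

print("edges retained:", len(filt.edges))
print("recommended k:", res.recommended_k)
print("min cluster consensus:", min(res.cluster_consensus[3].values()))
print("ARI vs planted subtypes:",
      adjusted_rand_score(cohort.truth.subtype[labels.index], labels))

chi2, df, p = pn.logrank_test(cohort.survival, cohort.truth.subtype)
print(f"log-rank chi2={chi2:.2f}, df={df}, p={p:.2e}")
```

Output:

```
edges retained: 1980
recommended k: 3
min cluster consensus: 1.0
ARI vs planted subtypes: 1.0
log-rank chi2=19.13, df=2, p=7.00e-05
```

1,980 of 2,944 network edges are significantly perturbed in disease
(including 143/150 planted ones); consensus clustering finds exactly three
stable subtypes (every cluster consensus score 1.0 ≥ 0.75) that match the
planted labels perfectly, and the subtypes differ strongly in overall
survival, with the planted high-hazard subtype worst.

The same analysis runs from the shell:

```bash
perturbnet simulate --seed 1 --out cohort/
perturbnet perturb --expression cohort/expression.tsv \
    --condition cohort/condition.tsv --network cohort/network.tsv --out run/
perturbnet filter --perturbation run/perturbation.tsv \
    --condition cohort/condition.tsv --out run/edge_filter.tsv
perturbnet run --config pipeline.yaml   # full pipeline from a YAML config
```

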
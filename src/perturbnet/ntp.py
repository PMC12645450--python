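"""Subtype extension to external cohorts by nearest-template prediction.

Marker templates are built from a labeled training cohort: per gene and
subtype a one-vs-rest Welch t statistic ranks up-regulation, and the top
``n_top`` positive genes per subtype (after resolving cross-subtype
collisions to the subtype with the larger statistic) form a binary template.
An external sample is standardized gene-wise within its own cohort, which
absorbs platform scale and location, and assigned to the subtype whose
template is nearest in cosine distance over the union of template genes.
Significance comes from resampling: random gene sets of the same structure
yield a null distance distribution, giving a per-sample p-value with
add-one smoothing, then Benjamini-Hochberg across the cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, ValidationError

__all__ = ["SubtypeTemplates", "NTPResult", "select_markers", "ntp_predict",
           "crosstab_report"]


@dataclass
class SubtypeTemplates:
    """Per-subtype ordered marker genes with their ranking statistic."""

    markers: dict[str, list[str]]
    statistics: pd.DataFrame  # gene x subtype t statistics
    n_top: int

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, genes in self.markers.items():
            overlap = seen & set(genes)
            if overlap:
                raise ValidationError(
                    f"marker {sorted(overlap)[0]!r} assigned to multiple subtypes"
                )
            seen |= set(genes)
            if len(genes) > self.n_top:
                raise ValidationError(f"template {name!r} exceeds n_top")


@dataclass
class NTPResult:
    """Per-sample subtype calls with distances and resampling FDR."""

    table: pd.DataFrame  # sample-indexed: predicted, dist_*, p_value, fdr, classifiable
    fdr_threshold: float
    n_resample: int
    seed: int
    report: dict = field(default_factory=dict)

    @property
    def predicted(self) -> pd.Series:
        return self.table["predicted"]

    @property
    def classifiable(self) -> pd.Series:
        return self.table["classifiable"]


def select_markers(
    expr: ExpressionMatrix, labels: pd.Series, n_top: int = 300
) -> SubtypeTemplates:
    """Top up-regulated genes per subtype by one-vs-rest Welch t statistic.

    Only the ordering of the statistic is consumed (no inference), so an
    unmoderated t suffices.  Collisions — a gene topping more than one
    subtype — go to the subtype with the larger statistic, keeping templates
    disjoint.
    """
    labels = labels.reindex(expr.values.columns).dropna()
    subtypes = sorted(labels.unique())
    if len(subtypes) < 2:
        raise ValidationError("need at least 2 subtypes")
    for s in subtypes:
        if (labels == s).sum() < 3:
            raise ValidationError(f"subtype {s!r} has fewer than 3 samples")
    X = expr.values[labels.index].to_numpy(float)
    stat = np.zeros((X.shape[0], len(subtypes)))
    for j, s in enumerate(subtypes):
        mask = (labels == s).to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            t, _ = stats.ttest_ind(X[:, mask], X[:, ~mask], axis=1, equal_var=False)
        stat[:, j] = np.nan_to_num(t, nan=0.0)
    stat_df = pd.DataFrame(stat, index=expr.values.index, columns=subtypes)
    best = stat_df.to_numpy().argmax(axis=1)
    markers: dict[str, list[str]] = {}
    for j, s in enumerate(subtypes):
        own = stat_df.index[(best == j) & (stat_df[s].to_numpy() > 0)]
        ranked = stat_df.loc[own, s].sort_values(ascending=False)
        if len(ranked) < n_top:
            warnings.warn(
                f"subtype {s!r}: only {len(ranked)} positive markers available "
                f"(requested {n_top})"
            )
        markers[s] = list(ranked.index[:n_top])
    return SubtypeTemplates(markers=markers, statistics=stat_df, n_top=n_top)


def _standardize(values: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    constant = list(values.index[sd == 0])
    if constant:
        warnings.warn(f"{len(constant)} constant genes excluded from standardization")
    keep = values.index[sd > 0]
    z = values.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)
    return z, constant


def ntp_predict(
    expr: ExpressionMatrix,
    templates: SubtypeTemplates,
    n_resample: int = 1000,
    fdr_threshold: float = 0.05,
    seed: int = 0,
) -> NTPResult:
    """Classify each cohort sample to its nearest subtype template.

    The cohort is standardized gene-wise (mean 0, SD 1 across samples);
    each template is a binary vector over the union of template genes
    present in the cohort.  Cosine distance ranks templates per sample; the
    resampling null re-draws gene sets of identical sizes from all measured
    genes, and p = (1 + #{null distance <= observed}) / (n_resample + 1).
    """
    if expr.values.shape[1] < 2:
        raise ValidationError("gene-wise standardization needs at least 2 samples")
    measured = set(expr.values.index)
    shared: dict[str, list[str]] = {}
    for name, genes in templates.markers.items():
        present = [g for g in genes if g in measured]
        if len(present) < 0.5 * len(genes):
            raise ValidationError(
                f"template {name!r}: only {len(present)}/{len(genes)} marker genes "
                "measured (below 50% coverage)"
            )
        shared[name] = present
    z_all, _constant = _standardize(expr.values)
    shared = {n: [g for g in gs if g in set(z_all.index)] for n, gs in shared.items()}
    union = [g for gs in shared.values() for g in gs]
    union = list(dict.fromkeys(union))
    if not union:
        raise ValidationError("no usable template genes after standardization")
    Z = z_all.loc[union].to_numpy(float)  # union genes x samples
    names = list(shared)
    norms = np.linalg.norm(Z, axis=0)
    norms[norms == 0] = np.finfo(float).eps
    dists = np.empty((Z.shape[1], len(names)))
    pos = {g: i for i, g in enumerate(union)}
    for j, name in enumerate(names):
        rows = [pos[g] for g in shared[name]]
        num = Z[rows].sum(axis=0)
        cos = num / (np.sqrt(len(rows)) * norms)
        dists[:, j] = 1.0 - cos
    pred_idx = dists.argmin(axis=1)

    # Resampling null, matched to the selection rule: the observed distance
    # is a minimum over templates, so each resample draws one random gene
    # set per subtype (same sizes) and the null statistic is the minimum of
    # the resulting distances.  Random sets are shared across samples —
    # genes are exchangeable under the null.
    rng = np.random.default_rng(seed)
    A = z_all.to_numpy(float)
    A2 = A**2
    n_genes = A.shape[0]
    n_union = len(union)
    null_min = np.full((n_resample, A.shape[1]), np.inf)
    for j, name in enumerate(names):
        n_j = len(shared[name])
        chunk = max(1, int(5e6 // max(1, n_union * A.shape[1])))
        picks = np.empty((n_resample, n_union), dtype=int)
        for r in range(n_resample):
            picks[r] = rng.choice(n_genes, size=n_union, replace=False)
        for start in range(0, n_resample, chunk):
            sl = picks[start : start + chunk]
            ones_sum = A[sl[:, :n_j]].sum(axis=1)
            sq_sum = A2[sl].sum(axis=1)
            sq_sum[sq_sum == 0] = np.finfo(float).eps
            d_null = 1.0 - ones_sum / (np.sqrt(n_j) * np.sqrt(sq_sum))
            np.minimum(null_min[start : start + chunk], d_null,
                       out=null_min[start : start + chunk])

    d_obs = dists[np.arange(dists.shape[0]), pred_idx]
    pvals = (1.0 + (null_min <= d_obs[None, :]).sum(axis=0)) / (n_resample + 1.0)
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")

    table = pd.DataFrame(index=expr.values.columns)
    table["predicted"] = [names[j] for j in pred_idx]
    for j, name in enumerate(names):
        table[f"dist_{name}"] = dists[:, j]
    table["p_value"] = pvals
    table["fdr"] = fdr
    table["classifiable"] = fdr < fdr_threshold
    return NTPResult(
        table=table,
        fdr_threshold=fdr_threshold,
        n_resample=n_resample,
        seed=seed,
        report={
            "n_union_genes": n_union,
            "template_coverage": {n: len(g) for n, g in shared.items()},
        },
    )


def crosstab_report(
    ntp: NTPResult, truth: pd.Series | None = None
) -> dict[str, object]:
    """Confusion table + accuracy when truth is given, else call rates."""
    pred = ntp.predicted
    if truth is None:
        rates = pred.value_counts(normalize=True).sort_index()
        return {"call_rates": rates}
    truth = truth.reindex(pred.index).dropna()
    if truth.empty:
        raise ValidationError("truth labels share no sample ids with predictions")
    common = truth.index
    confusion = pd.crosstab(
        truth, pred.loc[common], rownames=["truth"], colnames=["predicted"]
    )
    accuracy = float((pred.loc[common] == truth).mean())
    classifiable = ntp.classifiable.loc[common]
    acc_classifiable = (
        float((pred.loc[common][classifiable] == truth[classifiable]).mean())
        if classifiable.any()
        else float("nan")
    )
    return {
        "confusion": confusion,
        "accuracy": accuracy,
        "accuracy_classifiable": acc_classifiable,
        "fraction_classifiable": float(classifiable.mean()),
    }
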
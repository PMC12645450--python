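"""Per-sample pathway activity, linear risk scores, and survival association.

ssGSEA scores each sample against each gene set from the sample's own gene
ranking: walking the genes from highest to lowest expression, an in-set
weighted empirical CDF (weight = rank^alpha, where rank is the gene's
ascending within-sample rank so the top gene carries the largest weight)
is compared step by step with an unweighted out-of-set ECDF; the enrichment
score is the sum of the stepwise differences.  At alpha = 0 this reduces to
the unweighted Kolmogorov-style running sum.

The normalized risk score (NRS) applies a published per-gene coefficient
table to gene-wise standardized expression: NRS(s) = sum_g coef(g) * z(g,s),
a linear read-out of how strongly a sample expresses the high-risk
signature.  Survival association uses the Kaplan-Meier product-limit
estimator and the k-group log-rank test (lifelines).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .io import ExpressionMatrix, ValidationError

__all__ = [
    "KMCurve",
    "ssgsea_score",
    "nrs_score",
    "km_estimate",
    "logrank_test",
    "dichotomize_and_test",
]

MIN_SET_SIZE = 5


@dataclass
class KMCurve:
    """Product-limit estimate for one group."""

    label: str
    table: pd.DataFrame  # time-indexed: at_risk, events, survival
    median_survival: float


def ssgsea_score(
    expr: ExpressionMatrix,
    sets: dict[str, list[str]],
    alpha: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """Single-sample enrichment scores (sets x samples).

    Sets are projected onto the measured genes; sets retaining fewer than
    5 genes are dropped with a warning.  ``normalize`` applies min-max
    scaling across samples per set.
    """
    genes = list(expr.values.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    projected: dict[str, np.ndarray] = {}
    for name, members in sets.items():
        idx = np.array(sorted({gene_pos[g] for g in members if g in gene_pos}), int)
        if len(idx) < MIN_SET_SIZE:
            warnings.warn(
                f"gene set {name!r} retains {len(idx)} genes after projection; dropped"
            )
            continue
        projected[name] = idx
    if not projected:
        raise ValidationError("no gene set retains enough genes after projection")

    X = expr.values.to_numpy(float)
    n_genes, n_samples = X.shape
    ranks = stats.rankdata(X, axis=0)  # ascending: top gene has rank n_genes
    scores = np.zeros((len(projected), n_samples))
    set_names = list(projected)
    for s in range(n_samples):
        order = np.argsort(-X[:, s], kind="stable")
        w = ranks[order, s] ** alpha
        in_set = np.zeros(n_genes, dtype=bool)
        for si, name in enumerate(set_names):
            in_set[:] = False
            in_set[projected[name]] = True
            mask = in_set[order]
            m = mask.sum()
            cdf_in = np.cumsum(np.where(mask, w, 0.0))
            cdf_in /= cdf_in[-1]
            cdf_out = np.cumsum(~mask) / (n_genes - m)
            scores[si, s] = float(np.sum(cdf_in - cdf_out))
    out = pd.DataFrame(scores, index=set_names, columns=expr.values.columns)
    if normalize:
        rng_ = out.max(axis=1) - out.min(axis=1)
        rng_[rng_ == 0] = 1.0
        out = out.sub(out.min(axis=1), axis=0).div(rng_, axis=0)
    return out


def nrs_score(
    expr: ExpressionMatrix,
    coef: pd.Series,
    normalize: bool = False,
) -> pd.Series:
    """Coefficient-weighted sum of gene-wise standardized expression.

    Requires at least 30% of coefficient genes to be measured; missing
    genes contribute zero.  ``normalize`` min-max scales across the cohort.
    """
    shared = [g for g in coef.index if g in set(expr.values.index)]
    if not shared:
        raise ValidationError("no coefficient gene measured in the cohort")
    if len(shared) < 0.3 * len(coef):
        raise ValidationError(
            f"only {len(shared)}/{len(coef)} coefficient genes measured (below 30%)"
        )
    sub = expr.values.loc[shared]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    ok = sd > 0
    if (~ok).any():
        warnings.warn(f"{int((~ok).sum())} constant coefficient genes contribute 0")
    z = sub[ok].sub(mu[ok], axis=0).div(sd[ok], axis=0)
    nrs = z.mul(coef[z.index], axis=0).sum(axis=0)
    nrs.name = "nrs"
    nrs.attrs["missing_genes"] = len(coef) - len(shared)
    if normalize:
        span = nrs.max() - nrs.min()
        nrs = (nrs - nrs.min()) / (span if span > 0 else 1.0)
    return nrs


def _aligned(surv: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    groups = groups.dropna()
    missing = [s for s in groups.index if s not in surv.index]
    if missing:
        raise ValidationError(f"sample {missing[0]!r} has no survival data")
    df = surv.loc[groups.index].copy()
    df["group"] = groups
    return df


def km_estimate(surv: pd.DataFrame, groups: pd.Series) -> list[KMCurve]:
    """Kaplan-Meier product-limit estimate per group (censoring handled)."""
    df = _aligned(surv, groups)
    curves: list[KMCurve] = []
    for label, block in df.groupby("group", sort=True):
        if block.empty:
            warnings.warn(f"group {label!r} has no samples; dropped")
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(block["time"], block["event"], label=str(label))
        et = kmf.event_table
        table = pd.DataFrame(
            {
                "at_risk": et["at_risk"],
                "events": et["observed"],
                "survival": kmf.survival_function_.iloc[:, 0],
            }
        )
        table.index.name = "time"
        curves.append(
            KMCurve(
                label=str(label),
                table=table,
                median_survival=float(kmf.median_survival_time_),
            )
        )
    return curves


def logrank_test(surv: pd.DataFrame, groups: pd.Series) -> tuple[float, int, float]:
    """k-group log-rank test: (chi-square statistic, df, p)."""
    df = _aligned(surv, groups)
    n_groups = df["group"].nunique()
    if n_groups < 2:
        raise ValidationError("log-rank needs at least 2 non-empty groups")
    if df["event"].sum() == 0:
        raise ValidationError("log-rank undefined: zero events")
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return float(res.test_statistic), n_groups - 1, float(res.p_value)


def dichotomize_and_test(
    score: pd.Series, surv: pd.DataFrame, rule: str = "median"
) -> dict[str, object]:
    """Median-split a score (ties to the low group) and compare survival."""
    if rule != "median":
        raise ValidationError(f"unknown dichotomization rule {rule!r}")
    common = [s for s in score.index if s in surv.index]
    if len(common) < 4:
        raise ValidationError("need at least 4 samples with both score and survival")
    sc = score.loc[common]
    if sc.nunique() == 1:
        raise ValidationError("cannot dichotomize a constant score")
    cut = sc.median()
    groups = pd.Series(
        np.where(sc <= cut, "low", "high"), index=sc.index, name="group"
    )
    curves = km_estimate(surv, groups)
    chi2, dof, p = logrank_test(surv, groups)
    return {
        "groups": groups,
        "cut": float(cut),
        "curves": curves,
        "chi2": chi2,
        "df": dof,
        "p": p,
    }
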
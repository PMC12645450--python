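"""Interaction-perturbation matrix construction and feature selection.

The core transform: within each sample, genes are ranked by expression
(ascending, average ties).  For every directed network edge (a -> b) the
delta-rank d = rank(a) - rank(b) captures the relative ordering of the two
interacting genes.  Gene interactions are stable and conserved in healthy
samples, so the mean delta-rank over reference samples serves as a baseline
b(e); the interaction-perturbation value p(e, s) = d(e, s) - b(e) is near
zero in health and deviates in disease.  Because everything is built from
within-sample ranks, the whole construction is exactly invariant under any
strictly increasing per-sample transform of the expression values — which
is what makes it usable across platforms without batch correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CONDITIONS, ExpressionMatrix, InteractionNetwork, ValidationError

__all__ = [
    "RankMatrix",
    "DeltaRankMatrix",
    "PerturbationMatrix",
    "FilteredPerturbation",
    "ScaleFreeFit",
    "rank_transform",
    "delta_rank",
    "perturbation_matrix",
    "scale_free_fit",
    "select_perturbed_edges",
    "disturbance_summary",
    "edge_id",
]


def edge_id(source: str, target: str) -> str:
    return f"{source}|{target}"


@dataclass
class RankMatrix:
    """Within-sample ascending expression ranks (genes x samples)."""

    ranks: pd.DataFrame

    @property
    def n_genes(self) -> int:
        return self.ranks.shape[0]


@dataclass
class DeltaRankMatrix:
    """Per-edge rank differences (edges x samples), rows indexed "SRC|TGT"."""

    values: pd.DataFrame
    edges: list[tuple[str, str]]
    report: dict = field(default_factory=dict)


@dataclass
class PerturbationMatrix:
    """Delta-ranks minus the reference baseline (edges x samples).

    ``baseline`` is the per-edge mean delta-rank over the reference samples
    used to fit it; by construction the mean perturbation over those samples
    is exactly zero for every edge.
    """

    values: pd.DataFrame
    baseline: pd.Series
    edges: list[tuple[str, str]]
    reference_ids: list[str]


@dataclass
class FilteredPerturbation:
    """Edges retained as significantly perturbed, with test diagnostics."""

    table: pd.DataFrame  # edge, statistic, p, q, mean_diff, retained
    values: pd.DataFrame  # retained edges x samples
    edges: list[tuple[str, str]]
    nodes: set[str]
    alpha: float


@dataclass
class ScaleFreeFit:
    r: float
    p_value: float
    degree_table: pd.DataFrame  # degree, frequency


def rank_transform(expr: ExpressionMatrix) -> RankMatrix:
    """Rank genes within each sample (ascending, average ties).

    The per-sample rank sum is G(G+1)/2 regardless of ties, and the output
    is unchanged by any strictly increasing per-sample value transform.
    """
    values = expr.values.to_numpy(float)
    if values.shape[0] < 2:
        raise ValidationError("rank transform needs at least 2 genes")
    if not np.isfinite(values).all():
        raise ValidationError("rank transform requires finite values")
    ranks = stats.rankdata(values, axis=0)
    return RankMatrix(
        ranks=pd.DataFrame(ranks, index=expr.values.index, columns=expr.values.columns)
    )


def delta_rank(ranks: RankMatrix, net: InteractionNetwork) -> DeltaRankMatrix:
    """d(e, s) = rank(source) - rank(target) for every projectable edge.

    Edges with an endpoint missing from the rank matrix are dropped and
    counted in the report; the projection mirrors mapping cohort genes onto
    a pathway-derived background network.
    """
    genes = ranks.ranks.index
    pos = {g: i for i, g in enumerate(genes)}
    kept: list[tuple[str, str]] = []
    dropped = 0
    for s, t in net.edges:
        if s in pos and t in pos:
            kept.append((s, t))
        else:
            dropped += 1
    if not kept:
        raise ValidationError("network/expression gene overlap empty")
    r = ranks.ranks.to_numpy()
    src = np.fromiter((pos[s] for s, _ in kept), dtype=int, count=len(kept))
    tgt = np.fromiter((pos[t] for _, t in kept), dtype=int, count=len(kept))
    d = r[src, :] - r[tgt, :]
    idx = [edge_id(s, t) for s, t in kept]
    return DeltaRankMatrix(
        values=pd.DataFrame(d, index=idx, columns=ranks.ranks.columns),
        edges=kept,
        report={"edges_in": len(net.edges), "edges_dropped": dropped},
    )


def perturbation_matrix(
    delta: DeltaRankMatrix, reference_ids: list[str] | set[str]
) -> PerturbationMatrix:
    """Subtract the per-edge mean reference delta-rank from every sample."""
    reference_ids = list(reference_ids)
    if len(reference_ids) < 2:
        raise ValidationError("need at least 2 reference samples for a baseline")
    missing = [s for s in reference_ids if s not in delta.values.columns]
    if missing:
        raise ValidationError(f"reference sample {missing[0]!r} absent from cohort")
    baseline = delta.values[reference_ids].mean(axis=1)
    p = delta.values.sub(baseline, axis=0)
    return PerturbationMatrix(
        values=p, baseline=baseline, edges=list(delta.edges),
        reference_ids=reference_ids,
    )


def scale_free_fit(net: InteractionNetwork) -> ScaleFreeFit:
    """Log-log correlation between degree and degree frequency.

    Degrees are taken on the undirected skeleton; each observed distinct
    degree contributes one point (no binning).  A strongly negative Pearson
    r diagnoses a scale-free-like topology.
    """
    deg: dict[str, int] = {}
    for s, t in net.edges:
        deg[s] = deg.get(s, 0) + 1
        deg[t] = deg.get(t, 0) + 1
    degrees, counts = np.unique(np.array(list(deg.values())), return_counts=True)
    if len(degrees) < 3:
        raise ValidationError("degenerate degree distribution")
    r, p = stats.pearsonr(np.log10(degrees), np.log10(counts))
    table = pd.DataFrame({"degree": degrees, "frequency": counts})
    return ScaleFreeFit(r=float(r), p_value=float(p), degree_table=table)


def _split_by_condition(
    columns: pd.Index, labels: pd.Series
) -> tuple[np.ndarray, np.ndarray]:
    labels = labels.reindex(columns)
    if labels.isna().any():
        missing = labels.index[labels.isna()][0]
        raise ValidationError(f"sample {missing!r} has no condition label")
    bad = set(labels.unique()) - set(CONDITIONS)
    if bad:
        raise ValidationError(f"unknown condition labels {sorted(bad)}")
    ref = (labels == "reference").to_numpy()
    dis = (labels == "disease").to_numpy()
    return ref, dis


def select_perturbed_edges(
    p: PerturbationMatrix,
    labels: pd.Series,
    alpha: float = 0.05,
    max_edges: int | None = None,
) -> FilteredPerturbation:
    """Retain edges whose perturbation separates reference from disease.

    Per edge: two-sided Wilcoxon rank-sum of p(e, .) between conditions,
    Benjamini-Hochberg adjustment, retain q < ``alpha``.  With ``max_edges``
    the smallest-q edges are kept up to the cap (ties broken by larger
    absolute mean difference, then lexicographic edge id).
    """
    ref_mask, dis_mask = _split_by_condition(p.values.columns, labels)
    if ref_mask.sum() < 3 or dis_mask.sum() < 3:
        raise ValidationError("each condition needs at least 3 samples")
    x = p.values.to_numpy()[:, ref_mask]
    y = p.values.to_numpy()[:, dis_mask]
    res = stats.mannwhitneyu(x, y, axis=1, alternative="two-sided")
    pvals = np.asarray(res.pvalue, float)
    stat = np.asarray(res.statistic, float)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    mean_diff = y.mean(axis=1) - x.mean(axis=1)
    table = pd.DataFrame(
        {
            "statistic": stat,
            "p": pvals,
            "q": qvals,
            "mean_diff": mean_diff,
        },
        index=p.values.index,
    )
    retained = table["q"] < alpha
    if max_edges is not None and retained.sum() > max_edges:
        sub = table[retained]
        order = np.lexsort(
            (
                sub.index.to_numpy(),
                -np.abs(sub["mean_diff"].to_numpy()),
                sub["q"].to_numpy(),
            )
        )
        keep = set(sub.index.to_numpy()[order][:max_edges])
        retained = retained & table.index.isin(keep)
    table["retained"] = retained
    kept_ids = set(table.index[retained])
    edges = [e for e in p.edges if edge_id(*e) in kept_ids]
    nodes = {g for e in edges for g in e}
    return FilteredPerturbation(
        table=table,
        values=p.values.loc[table.index[retained]],
        edges=edges,
        nodes=nodes,
        alpha=alpha,
    )


def disturbance_summary(p: PerturbationMatrix, labels: pd.Series) -> pd.DataFrame:
    """Per-condition mean |p| and value range — no inference, description only."""
    labels = labels.reindex(p.values.columns)
    if labels.isna().any():
        missing = labels.index[labels.isna()][0]
        raise ValidationError(f"sample {missing!r} has no condition label")
    bad = set(labels.unique()) - set(CONDITIONS)
    if bad:
        raise ValidationError(f"unknown condition labels {sorted(bad)}")
    rows = {}
    for cond in CONDITIONS:
        cols = labels.index[labels == cond]
        if len(cols) == 0:
            continue
        block = p.values[cols].to_numpy()
        rows[cond] = {
            "n_samples": len(cols),
            "mean_abs_perturbation": float(np.abs(block).mean()),
            "min": float(block.min()),
            "max": float(block.max()),
        }
    return pd.DataFrame(rows).T
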
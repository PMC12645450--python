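"""Resampling-based consensus clustering with stability diagnostics.

Implements the Monti-style consensus protocol from its definition: for each
candidate cluster number k, samples are repeatedly subsampled (fraction
``p_item``), k-means with Euclidean distance partitions each subsample, and
the consensus matrix M_k records for every sample pair the fraction of
co-sampled replicates in which the pair co-clustered.  The final partition
at each k cuts an average-linkage dendrogram of 1 - M_k.  Stability is read
off M_k: per-cluster consensus scores (mean within-cluster consensus), the
CDF of off-diagonal consensus values, its area, the relative delta-area
between successive k (used to recommend k), and the proportion of ambiguous
clustering (PAC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .io import ValidationError
from .perturbation import FilteredPerturbation

__all__ = [
    "ConsensusResult",
    "consensus_cluster",
    "stability_report",
    "assign_labels",
]

STABILITY_THRESHOLD = 0.75  # every-cluster consensus score flagged as stable


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, partitions and stability diagnostics."""

    ks: list[int]
    matrices: dict[int, pd.DataFrame]
    assignments: dict[int, pd.Series]
    cluster_consensus: dict[int, dict[int, float]]
    offdiag_values: dict[int, np.ndarray]  # sorted co-sampled off-diagonal consensus
    area: dict[int, float]
    delta_area: dict[int, float]
    pac: dict[int, float]
    reps: int
    p_item: float
    p_feature: float
    seed: int
    sample_ids: list[str] = field(default_factory=list)

    @property
    def recommended_k(self) -> int:
        """Largest delta-area among stable k.

        A partition is stable when every cluster's consensus score reaches
        0.75; restricting the delta-area argmax to stable k combines the two
        published selection criteria (an unstable split can gain CDF area
        merely by being ambiguous).  If no k is stable, the plain argmax is
        returned.
        """
        stable = [
            k for k in self.ks
            if min(self.cluster_consensus[k].values()) >= STABILITY_THRESHOLD
        ]
        pool = stable or self.ks
        return max(pool, key=lambda k: self.delta_area[k])


def _replicate_rng(seed: int, k: int, rep: int) -> tuple[np.random.Generator, int]:
    """Counter-derived replicate randomness: order-independent, reproducible."""
    ss = np.random.SeedSequence(seed, spawn_key=(k, rep))
    rng = np.random.default_rng(ss)
    km_seed = int(ss.generate_state(2)[1] % (2**31 - 1))
    return rng, km_seed


def _as_feature_array(features) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, FilteredPerturbation):
        df = features.values
    elif isinstance(features, pd.DataFrame):
        df = features
    else:
        raise TypeError("features must be a FilteredPerturbation or DataFrame")
    # rows are edge features, columns are samples; cluster the samples
    X = df.to_numpy(float).T
    if not np.isfinite(X).all():
        raise ValidationError("features must be finite")
    return X, list(df.columns)


def consensus_cluster(
    features,
    k_max: int = 9,
    reps: int = 1000,
    p_item: float = 0.8,
    seed: int = 0,
    p_feature: float = 1.0,
    k_min: int = 2,
    n_init: int = 10,
) -> ConsensusResult:
    """Consensus k-means over sample subsamples for k in ``k_min..k_max``.

    Each replicate draws ceil(p_item * n) samples without replacement
    (optionally a ``p_feature`` fraction of features), partitions them with
    k-means (greedy k-means++ seeding, ``n_init`` restarts, replicate seeds
    derived by counter from ``seed``), and accumulates co-clustering and
    co-sampling counts.  M_k = co-cluster / co-sample with 0/0 := 0 and a
    unit diagonal.
    """
    X, sample_ids = _as_feature_array(features)
    n = X.shape[0]
    if k_max < 2:
        raise ValidationError("k_max must be at least 2")
    if not (0 < p_item <= 1):
        raise ValidationError("p_item must be in (0, 1]")
    if not (0 < p_feature <= 1):
        raise ValidationError("p_feature must be in (0, 1]")
    if n < k_max + 2:
        raise ValidationError(f"need at least k_max + 2 = {k_max + 2} samples")
    n_sub = math.ceil(p_item * n)
    if n_sub < k_max:
        raise ValidationError("p_item * n smaller than the largest k")
    n_feat = max(1, math.ceil(p_feature * X.shape[1]))

    ks = list(range(k_min, k_max + 1))
    matrices: dict[int, pd.DataFrame] = {}
    assignments: dict[int, pd.Series] = {}
    cluster_consensus: dict[int, dict[int, float]] = {}
    offdiag: dict[int, np.ndarray] = {}
    area: dict[int, float] = {}
    pac: dict[int, float] = {}

    iu = np.triu_indices(n, k=1)
    for k in ks:
        conn = np.zeros((n, n))
        indic = np.zeros((n, n))
        for rep in range(reps):
            rng, km_seed = _replicate_rng(seed, k, rep)
            idx = np.sort(rng.choice(n, size=n_sub, replace=False))
            cols = (
                np.sort(rng.choice(X.shape[1], size=n_feat, replace=False))
                if p_feature < 1.0
                else slice(None)
            )
            km = KMeans(n_clusters=k, n_init=n_init, random_state=km_seed)
            labels = km.fit_predict(X[idx][:, cols])
            indic[np.ix_(idx, idx)] += 1.0
            same = labels[:, None] == labels[None, :]
            conn[np.ix_(idx, idx)] += same
        M = np.divide(conn, indic, out=np.zeros_like(conn), where=indic > 0)
        np.fill_diagonal(M, 1.0)
        M = (M + M.T) / 2.0

        # final partition: average-linkage agglomeration of 1 - M cut at k
        dist = 1.0 - M
        np.fill_diagonal(dist, 0.0)
        Z = linkage(squareform(dist, checks=False), method="average")
        raw = fcluster(Z, t=k, criterion="maxclust")
        labels_k = _renumber(raw, sample_ids)

        co_sampled = indic[iu] > 0
        vals = np.sort(M[iu][co_sampled])
        offdiag[k] = vals
        area[k] = float(1.0 - vals.mean()) if len(vals) else 0.0
        pac[k] = float(np.mean(vals <= 0.9) - np.mean(vals <= 0.1)) if len(vals) else 0.0
        cc: dict[int, float] = {}
        for lab in np.unique(labels_k):
            members = np.flatnonzero(labels_k == lab)
            if len(members) < 2:
                cc[int(lab)] = 1.0  # singleton: no pairs to disagree
                continue
            sub = M[np.ix_(members, members)]
            su = sub[np.triu_indices(len(members), k=1)]
            cc[int(lab)] = float(su.mean())
        matrices[k] = pd.DataFrame(M, index=sample_ids, columns=sample_ids)
        assignments[k] = pd.Series(labels_k, index=sample_ids, name="cluster")
        cluster_consensus[k] = cc

    delta_area: dict[int, float] = {}
    for i, k in enumerate(ks):
        if i == 0:
            delta_area[k] = area[k]
        else:
            prev = area[ks[i - 1]]
            delta_area[k] = (area[k] - prev) / prev if prev > 0 else 0.0

    return ConsensusResult(
        ks=ks,
        matrices=matrices,
        assignments=assignments,
        cluster_consensus=cluster_consensus,
        offdiag_values=offdiag,
        area=area,
        delta_area=delta_area,
        pac=pac,
        reps=reps,
        p_item=p_item,
        p_feature=p_feature,
        seed=seed,
        sample_ids=sample_ids,
    )


def _renumber(raw: np.ndarray, sample_ids: list[str]) -> np.ndarray:
    """Renumber clusters 1..k by decreasing size, ties by smallest member id."""
    order = []
    for lab in np.unique(raw):
        members = np.flatnonzero(raw == lab)
        smallest = min(sample_ids[i] for i in members)
        order.append((-len(members), smallest, lab))
    order.sort()
    mapping = {lab: i + 1 for i, (_, _, lab) in enumerate(order)}
    return np.array([mapping[lab] for lab in raw], dtype=int)


def stability_report(res: ConsensusResult) -> pd.DataFrame:
    """One row per k: min cluster consensus, delta-area, PAC, stability flag.

    The recommended k (argmax delta-area) is stored in ``.attrs`` and marked
    in the ``recommended`` column; ``stable`` flags k where every cluster
    consensus score reaches 0.75.
    """
    rows = []
    rec = res.recommended_k
    for k in res.ks:
        cc = res.cluster_consensus[k]
        rows.append(
            {
                "k": k,
                "min_cluster_consensus": min(cc.values()),
                "delta_area": res.delta_area[k],
                "pac": res.pac[k],
                "stable": min(cc.values()) >= STABILITY_THRESHOLD,
                "recommended": k == rec,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["recommended_k"] = rec
    return df


def cdf_table(res: ConsensusResult, grid_points: int = 101) -> pd.DataFrame:
    """Empirical CDF of off-diagonal consensus values, one row per (k, x)."""
    grid = np.linspace(0.0, 1.0, grid_points)
    rows = []
    for k in res.ks:
        vals = res.offdiag_values[k]
        for x in grid:
            f = float(np.mean(vals <= x)) if len(vals) else 0.0
            rows.append({"k": k, "consensus": float(x), "cdf": f})
    return pd.DataFrame(rows)


def assign_labels(res: ConsensusResult, k: int) -> pd.Series:
    """Deterministic sample -> cluster mapping at k (clusters 1..k by size)."""
    if k not in res.assignments:
        raise ValidationError(f"k={k} outside computed range {res.ks}")
    return res.assignments[k].copy()
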
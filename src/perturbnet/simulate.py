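"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates the premises of perturbation subtyping: reference
samples share a conserved within-sample gene ordering (a fixed baseline
profile plus independent noise), each disease subtype carries planted
rank-shifts on its own disjoint set of network edges (implemented as
opposite-sign expression shifts on the edge's endpoint genes, which flips
the edge's delta-rank sign while keeping the matrix valid expression data
for every downstream stage), external cohorts differ by monotone "platform"
distortions, and survival follows subtype-specific exponential hazards with
independent censoring.  Everything is a pure function of the config,
including the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io as cio
from .io import ExpressionMatrix, InteractionNetwork, ValidationError

__all__ = [
    "SyntheticCohortConfig",
    "SyntheticTruth",
    "SyntheticCohort",
    "generate_network",
    "generate_cohort",
    "regenerate_for_platform",
    "write_cohort",
    "DISTORTIONS",
]


def _affine(x: np.ndarray) -> np.ndarray:
    return 1.5 * x + 2.0


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


DISTORTIONS = {
    "identity": lambda x: x,
    "cube_root": np.cbrt,
    "logistic": _logistic,
    "affine": _affine,
}


@dataclass
class SyntheticCohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults: 2,000 genes, 20 reference samples, three disease subtypes of
    40 samples each, a 200-node preferential-attachment network with 16
    attachments per node (a desk-scale analog of dense pathway-derived
    functional-interaction networks, whose density couples subtype
    disturbances through shared genes), 50 planted edges per subtype,
    perturbation strength 3 (expression shift in units of the within-gene
    noise SD, applied with opposite signs to the two endpoint genes so the
    edge's delta-rank flips), unit noise SD, and exponential survival
    hazards ordered worst-to-best across subtypes with 20% censoring.
    """

    seed: int
    n_genes: int = 2000
    n_reference: int = 20
    samples_per_subtype: tuple[int, ...] = (40, 40, 40)
    n_nodes: int = 200
    n_attach: int = 16
    n_perturbed_edges_per_subtype: int = 50
    perturbation_strength: float = 3.0
    noise_sd: float = 1.0
    baseline_mean: float = 6.0
    baseline_sd: float = 2.0
    hazard_per_subtype: tuple[float, ...] = (0.08, 0.04, 0.02)
    censoring_rate: float = 0.2

    def validate(self) -> None:
        if self.n_genes < 2 or self.n_reference < 2:
            raise ValidationError("counts must be positive (>= 2)")
        if any(n < 1 for n in self.samples_per_subtype):
            raise ValidationError("each subtype needs at least 1 sample")
        if len(self.hazard_per_subtype) != len(self.samples_per_subtype):
            raise ValidationError("one hazard per subtype required")
        if any(h <= 0 for h in self.hazard_per_subtype):
            raise ValidationError("hazards must be positive")
        if not (0 <= self.censoring_rate < 1):
            raise ValidationError("censoring_rate must be in [0, 1)")
        if self.n_nodes > self.n_genes:
            raise ValidationError("network nodes cannot exceed gene count")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")


@dataclass
class SyntheticTruth:
    """Planted ground truth consistent with the emitted cohort."""

    subtype: pd.Series  # disease sample -> subtype name
    planted_edges: dict[str, list[tuple[str, str]]]
    signature_genes: dict[str, list[str]]
    hazard: pd.Series  # disease sample -> hazard used


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    network: InteractionNetwork
    survival: pd.DataFrame
    truth: SyntheticTruth
    config: SyntheticCohortConfig = None


def generate_network(n_nodes: int, m: int, seed: int) -> InteractionNetwork:
    """Directed preferential-attachment network over genes G00000..

    Each undirected Barabasi-Albert edge receives a random fixed direction;
    the result is deterministic per seed.
    """
    if not (n_nodes > m >= 1):
        raise ValidationError("need n_nodes > m >= 1")
    g = nx.barabasi_albert_graph(n_nodes, m, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    edges: list[tuple[str, str]] = []
    for u, v in sorted(g.edges()):
        a, b = (u, v) if rng.random() < 0.5 else (v, u)
        edges.append((_gene(a), _gene(b)))
    return InteractionNetwork(edges=edges)


def _gene(i: int) -> str:
    return f"G{i:05d}"


def generate_cohort(cfg: SyntheticCohortConfig) -> SyntheticCohort:
    """Draw a full cohort (expression, network, survival, truth) from cfg."""
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(0,)))
    net_seed = int(np.random.SeedSequence(cfg.seed, spawn_key=(1,)).generate_state(1)[0]
                   % (2**31 - 1))
    network = generate_network(cfg.n_nodes, cfg.n_attach, seed=net_seed)
    n_subtypes = len(cfg.samples_per_subtype)
    demand = n_subtypes * cfg.n_perturbed_edges_per_subtype
    if demand > len(network.edges):
        raise ValidationError(
            f"{demand} planted edges requested but network has {len(network.edges)}"
        )

    genes = [_gene(i) for i in range(cfg.n_genes)]
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    subtype_names = [f"C{i + 1}" for i in range(n_subtypes)]
    # Plant edges so that every planted edge admits a coherent delta-rank
    # flip.  A gene's dysregulation direction is intrinsic — the same
    # whenever any subtype hits it — so directions propagate through shared
    # endpoints, and an edge whose endpoints are already forced to the SAME
    # direction cannot be flipped and is skipped (its planted perturbation
    # would be undefined).
    order = rng.permutation(len(network.edges))
    direction: dict[int, float] = {}
    planted: dict[str, list[tuple[str, str]]] = {name: [] for name in subtype_names}
    cursor = 0
    for name in subtype_names:
        while len(planted[name]) < cfg.n_perturbed_edges_per_subtype:
            if cursor >= len(order):
                raise ValidationError(
                    "network too small for the requested planted edges"
                )
            s, t = network.edges[order[cursor]]
            cursor += 1
            si, ti = gene_pos[s], gene_pos[t]
            du, dv = direction.get(si), direction.get(ti)
            if du is not None and dv is not None and du == dv:
                continue  # unflippable under the intrinsic-direction constraint
            if du is None and dv is None:
                sign = 1.0 if baseline[si] >= baseline[ti] else -1.0
                direction[si], direction[ti] = -sign, sign
            elif du is None:
                direction[si] = -dv
            elif dv is None:
                direction[ti] = -du
            planted[name].append((s, t))
    signatures: dict[str, list[str]] = {}
    for name in subtype_names:
        sig: list[str] = []
        for s, t in planted[name]:
            if s not in sig:
                sig.append(s)
            if t not in sig:
                sig.append(t)
        signatures[name] = sig

    ref_ids = [f"REF{i + 1:03d}" for i in range(cfg.n_reference)]
    dis_ids: list[str] = []
    dis_subtype: list[str] = []
    for name, n_s in zip(subtype_names, cfg.samples_per_subtype):
        for i in range(n_s):
            dis_ids.append(f"{name}S{i + 1:03d}")
            dis_subtype.append(name)
    sample_ids = ref_ids + dis_ids
    n_total = len(sample_ids)

    X = baseline[:, None] + rng.normal(0.0, cfg.noise_sd, (cfg.n_genes, n_total))
    shift = cfg.perturbation_strength * cfg.noise_sd
    for name in subtype_names:
        cols = [len(ref_ids) + i for i, s in enumerate(dis_subtype) if s == name]
        shifted: set[int] = set()
        for s, t in planted[name]:
            shifted.add(gene_pos[s])
            shifted.add(gene_pos[t])
        for gi in shifted:
            X[gi, cols] += direction[gi] * shift

    condition = pd.Series(
        ["reference"] * len(ref_ids) + ["disease"] * len(dis_ids),
        index=sample_ids,
        name="condition",
    )
    expr = ExpressionMatrix(
        values=pd.DataFrame(X, index=genes, columns=sample_ids),
        condition=condition,
    )

    subtype = pd.Series(dis_subtype, index=dis_ids, name="subtype")
    hazard_map = dict(zip(subtype_names, cfg.hazard_per_subtype))
    hazards = subtype.map(hazard_map).astype(float)
    event_t = rng.exponential(1.0 / hazards.to_numpy())
    if cfg.censoring_rate > 0:
        c = cfg.censoring_rate
        cens_rate = hazards.to_numpy() * c / (1.0 - c)
        censor_t = rng.exponential(1.0 / cens_rate)
    else:
        censor_t = np.full(len(dis_ids), np.inf)
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    survival = pd.DataFrame(
        {"time": time, "event": event}, index=pd.Index(dis_ids, name="sample_id")
    )

    truth = SyntheticTruth(
        subtype=subtype,
        planted_edges=planted,
        signature_genes=signatures,
        hazard=hazards,
    )
    return SyntheticCohort(
        expression=expr, network=network, survival=survival, truth=truth, config=cfg
    )


def regenerate_for_platform(
    cohort: SyntheticCohort | ExpressionMatrix,
    distortion: str,
    extra_noise_sd: float = 0.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Element-wise monotone transform plus fresh noise; labels carry over.

    Emulates measuring the same cohort on a different platform: any strictly
    increasing transform preserves within-sample rankings exactly, so only
    the added noise can move ranks.
    """
    expr = cohort.expression if isinstance(cohort, SyntheticCohort) else cohort
    if distortion not in DISTORTIONS:
        raise ValidationError(
            f"unknown distortion {distortion!r}; choose from {sorted(DISTORTIONS)}"
        )
    rng = np.random.default_rng(seed)
    X = DISTORTIONS[distortion](expr.values.to_numpy(float))
    if extra_noise_sd > 0:
        X = X + rng.normal(0.0, extra_noise_sd, X.shape)
    return ExpressionMatrix(
        values=pd.DataFrame(X, index=expr.values.index, columns=expr.values.columns),
        condition=None if expr.condition is None else expr.condition.copy(),
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, str]:
    """Emit the full fixture set as TSV/JSON via the standard writers."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": str(out / "expression.tsv"),
        "condition": str(out / "condition.tsv"),
        "network": str(out / "network.tsv"),
        "survival": str(out / "survival.tsv"),
        "truth": str(out / "truth.json"),
    }
    cio.write_matrix(cohort.expression.values, paths["expression"], index_label="gene")
    cohort.expression.condition.rename("condition").to_csv(
        paths["condition"], sep="\t", index_label="sample_id"
    )
    with open(paths["network"], "w") as fh:
        for s, t in cohort.network.edges:
            fh.write(f"{s}\t{t}\n")
    cohort.survival.to_csv(paths["survival"], sep="\t", index_label="sample_id")
    truth = {
        "subtype": cohort.truth.subtype.to_dict(),
        "planted_edges": {
            k: [list(e) for e in v] for k, v in cohort.truth.planted_edges.items()
        },
        "signature_genes": cohort.truth.signature_genes,
        "hazard": cohort.truth.hazard.to_dict(),
        "config": asdict(cohort.config) if cohort.config else None,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
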
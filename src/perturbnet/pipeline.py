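"""End-to-end orchestration: perturb -> filter -> cluster -> markers ->
(optional NTP) -> scoring/survival, with deterministic seeding and a
machine-readable run report.

One master seed drives everything; per-stage seeds are derived from it by a
fixed counter scheme (SeedSequence spawn keys indexed by stage), so toggling
one stage never shifts another stage's randomness.  All numeric outputs go
to files; the JSON report records parameters, derived seeds, input
checksums and per-stage summaries.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from . import io as cio
from .consensus import assign_labels, cdf_table, consensus_cluster, \
    stability_report
from .io import ExpressionMatrix, ValidationError
from .ntp import ntp_predict, select_markers
from .perturbation import (
    delta_rank,
    disturbance_summary,
    perturbation_matrix,
    rank_transform,
    scale_free_fit,
    select_perturbed_edges,
)
from .scoring import dichotomize_and_test, km_estimate, logrank_test, nrs_score, \
    ssgsea_score

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]

# stage order fixes the seed-derivation counter
STAGES = ("perturb", "filter", "cluster", "markers", "ntp", "score", "survival")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    expression: str
    condition: str
    out_dir: str
    seed: int
    network: str | None = None
    survival: str | None = None
    gene_sets: str | None = None
    coefficients: str | None = None
    external_expression: str | None = None
    transpose: bool = False
    alpha: float = 0.05
    max_edges: int | None = None
    k_max: int = 9
    k_select: int | None = None  # override the delta-area recommendation
    reps: int = 1000
    p_item: float = 0.8
    p_feature: float = 1.0
    n_top: int = 300
    n_resample: int = 1000
    ntp_fdr: float = 0.05
    ssgsea_alpha: float = 0.25
    stages: tuple[str, ...] = STAGES

    def validate(self) -> None:
        for name in ("expression", "condition"):
            p = getattr(self, name)
            if p is None or not Path(p).exists():
                raise ValidationError(f"config path {name!r} missing: {p}")
        for name in ("network", "survival", "gene_sets", "coefficients",
                     "external_expression"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"config path {name!r} missing: {p}")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValidationError(f"unknown stages {sorted(unknown)}")
        if self.seed is None:
            raise ValidationError("seed is mandatory")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    return PipelineConfig(**raw)


def stage_seed(master: int, stage: str) -> int:
    idx = STAGES.index(stage)
    return int(
        np.random.SeedSequence(master, spawn_key=(idx,)).generate_state(1)[0]
        % (2**31 - 1)
    )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Execute the configured stages; returns (and writes) the run report."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "alpha": cfg.alpha, "max_edges": cfg.max_edges, "k_max": cfg.k_max,
            "reps": cfg.reps, "p_item": cfg.p_item, "p_feature": cfg.p_feature,
            "n_top": cfg.n_top, "n_resample": cfg.n_resample,
            "ntp_fdr": cfg.ntp_fdr, "ssgsea_alpha": cfg.ssgsea_alpha,
        },
        "inputs": {},
        "stages": {},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    for name in ("expression", "condition", "network", "survival", "gene_sets",
                 "coefficients", "external_expression"):
        p = getattr(cfg, name)
        if p:
            report["inputs"][name] = {"path": str(p), "sha256": _sha256(p)}

    try:
        expr = cio.read_expression(cfg.expression, cfg.condition,
                                   transpose=cfg.transpose)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"[load] {e}") from e

    filt = None
    labels_k = None
    templates = None

    if "perturb" in cfg.stages:
        try:
            if expr.condition is None:
                raise ValidationError("expression cohort has no condition labels")
            if cfg.network is None:
                raise ValidationError("perturb stage requires a network path")
            net = cio.read_network(cfg.network)
            ranks = rank_transform(expr)
            delta = delta_rank(ranks, net)
            refs = expr.samples_with("reference")
            pert = perturbation_matrix(delta, refs)
            cio.write_matrix(pert.values, out / "perturbation.tsv",
                             index_label="edge")
            cio.write_series(pert.baseline, out / "baseline.tsv",
                             index_label="edge", value_label="baseline")
            summary = disturbance_summary(pert, expr.condition)
            summary.to_csv(out / "disturbance_summary.tsv", sep="\t",
                           index_label="condition")
            try:
                sf = scale_free_fit(net)
                sf_info = {"r": sf.r, "p": sf.p_value}
            except ValidationError:
                sf_info = None
            report["stages"]["perturb"] = {
                "edges_in": delta.report["edges_in"],
                "edges_dropped": delta.report["edges_dropped"],
                "edges": len(pert.edges),
                "n_reference": len(refs),
                "scale_free": sf_info,
            }
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"[perturb] {e}") from e
    else:
        pert = None

    if "filter" in cfg.stages:
        try:
            if pert is None:
                raise ValidationError("filter stage needs the perturb stage")
            filt = select_perturbed_edges(pert, expr.condition, alpha=cfg.alpha,
                                          max_edges=cfg.max_edges)
            filt.table.to_csv(out / "edge_filter.tsv", sep="\t",
                              index_label="edge", float_format="%.17g")
            report["stages"]["filter"] = {
                "edges_retained": int(filt.table["retained"].sum()),
                "nodes_retained": len(filt.nodes),
                "alpha": cfg.alpha,
            }
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"[filter] {e}") from e

    if "cluster" in cfg.stages:
        try:
            if filt is None:
                raise ValidationError("cluster stage needs the filter stage")
            disease = expr.samples_with("disease")
            features = filt.values[disease]
            res = consensus_cluster(
                features, k_max=cfg.k_max, reps=cfg.reps, p_item=cfg.p_item,
                p_feature=cfg.p_feature, seed=stage_seed(cfg.seed, "cluster"),
            )
            stab = stability_report(res)
            stab.to_csv(out / "stability.tsv", sep="\t", index=False,
                        float_format="%.17g")
            chosen_k = cfg.k_select or stab.attrs["recommended_k"]
            labels_k = assign_labels(res, chosen_k).map(lambda c: f"C{c}")
            labels_k.rename("cluster").to_csv(out / "assignments.tsv", sep="\t",
                                              index_label="sample_id")
            for k in res.ks:
                cio.write_matrix(res.matrices[k], out / f"consensus_k{k}.tsv",
                                 index_label="sample_id")
            cdf_table(res).to_csv(out / "consensus_cdf.tsv", sep="\t",
                                  index=False, float_format="%.17g")
            report["stages"]["cluster"] = {
                "chosen_k": int(chosen_k),
                "recommended_k": int(stab.attrs["recommended_k"]),
                "cluster_consensus": {
                    str(c): v for c, v in res.cluster_consensus[chosen_k].items()
                },
                "min_cluster_consensus": float(
                    min(res.cluster_consensus[chosen_k].values())
                ),
                "stability": stab.drop(columns=["recommended"]).to_dict("records"),
            }
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"[cluster] {e}") from e

    if "markers" in cfg.stages:
        try:
            if labels_k is None:
                raise ValidationError("markers stage needs the cluster stage")
            disease_expr = ExpressionMatrix(
                values=expr.values[labels_k.index], condition=None
            )
            templates = select_markers(disease_expr, labels_k, n_top=cfg.n_top)
            cio.write_gmt(templates.markers, out / "templates.gmt")
            templates.statistics.to_csv(out / "marker_statistics.tsv", sep="\t",
                                        index_label="gene", float_format="%.17g")
            report["stages"]["markers"] = {
                "n_top": cfg.n_top,
                "template_sizes": {k: len(v) for k, v in templates.markers.items()},
            }
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"[markers] {e}") from e

    if "ntp" in cfg.stages and cfg.external_expression:
        try:
            if templates is None:
                raise ValidationError("ntp stage needs the markers stage")
            ext = cio.read_expression(cfg.external_expression,
                                      transpose=cfg.transpose)
            ntp_res = ntp_predict(
                ext, templates, n_resample=cfg.n_resample,
                fdr_threshold=cfg.ntp_fdr, seed=stage_seed(cfg.seed, "ntp"),
            )
            ntp_res.table.to_csv(out / "ntp_predictions.tsv", sep="\t",
                                 index_label="sample_id", float_format="%.17g")
            report["stages"]["ntp"] = {
                "n_samples": int(ntp_res.table.shape[0]),
                "fraction_classifiable": float(ntp_res.classifiable.mean()),
                "calls": ntp_res.predicted.value_counts().to_dict(),
            }
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"[ntp] {e}") from e

    if "score" in cfg.stages and (cfg.gene_sets or cfg.coefficients):
        try:
            stage_info: dict[str, Any] = {}
            if cfg.gene_sets:
                sets = cio.read_gmt(cfg.gene_sets)
                scores = ssgsea_score(expr, sets, alpha=cfg.ssgsea_alpha)
                cio.write_matrix(scores, out / "ssgsea_scores.tsv",
                                 index_label="gene_set")
                stage_info["n_sets_scored"] = int(scores.shape[0])
            if cfg.coefficients:
                coef = cio.read_coefficients(cfg.coefficients)
                nrs = nrs_score(expr, coef)
                cio.write_series(nrs, out / "nrs.tsv", value_label="nrs")
                stage_info["nrs_missing_genes"] = nrs.attrs.get("missing_genes", 0)
            report["stages"]["score"] = stage_info
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"[score] {e}") from e

    if "survival" in cfg.stages and cfg.survival:
        try:
            if labels_k is None:
                raise ValidationError("survival stage needs the cluster stage")
            surv = cio.read_survival(cfg.survival)
            groups = labels_k[labels_k.index.isin(surv.index)]
            curves = km_estimate(surv, groups)
            for c in curves:
                c.table.to_csv(out / f"km_{c.label}.tsv", sep="\t",
                               float_format="%.17g")
            chi2, dof, p = logrank_test(surv, groups)
            report["stages"]["survival"] = {
                "logrank_chi2": chi2,
                "df": dof,
                "p": p,
                "median_survival": {
                    c.label: (c.median_survival if np.isfinite(c.median_survival)
                              else None)
                    for c in curves
                },
            }
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"[survival] {e}") from e

    cio.write_json(report, out / "run_report.json")
    return report
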
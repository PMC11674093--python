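"""Single-pass pipeline: selection -> augmentation-aware CV -> clustering.

Runs each stage exactly once in that order, writing every intermediate
artifact plus a manifest (config echo, seeds, versions) under the output
directory.  Reruns with the same config and seed reproduce the outputs
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster import align_and_score, cluster, dendrogram_newick
from .consensus import ConsensusSelection, consensus_select
from .data import (
    ExpressionMatrix,
    LabelVector,
    align,
    write_report,
    write_selection,
)
from .evaluate import CvConfig, CvReport, run_cv
from .gan import GanConfig
from .learners import default_learners
from .ranking import anova_f, correlation_with_label, rfe_rank

__all__ = ["PipelineConfig", "PipelineResult", "select_panel", "run_pipeline"]


@dataclass
class PipelineConfig:
    target_size: int = 30
    final_size: int = 10
    step_fraction: float = 0.1
    vote_min: int = 2
    learner_hyperparameters: dict = field(default_factory=dict)
    augment: bool = True
    gan: GanConfig | None = None
    per_class_multiplier: int = 10
    k: int = 3
    cluster_k: int | None = None  # default: number of classes
    cluster_method: str = "kmeans"
    cluster_linkage: str = "ward"
    group_map: dict[str, str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.final_size > self.target_size:
            raise ValueError(
                f"final_size={self.final_size} exceeds target_size={self.target_size}"
            )


@dataclass
class PipelineResult:
    selection: ConsensusSelection
    subsets: list
    cv_report: CvReport
    verification: object
    gene_stats: dict


def select_panel(
    X: ExpressionMatrix,
    y: LabelVector,
    target_size: int = 30,
    final_size: int = 10,
    step_fraction: float = 0.1,
    vote_min: int = 2,
    hyperparameters: dict | None = None,
    seed: int = 0,
):
    """Three-learner RFE to ``target_size`` genes each, then 2-of-3 consensus."""
    learners = default_learners(seed)
    if hyperparameters:
        from .learners import LearnerSpec

        learners = [
            LearnerSpec(l.kind, hyperparameters=dict(hyperparameters), seed=seed)
            for l in learners
        ]
    subsets = [
        rfe_rank(X, y, spec, target_size=target_size, step_fraction=step_fraction)
        for spec in learners
    ]
    selection = consensus_select(subsets, vote_min=vote_min, final_size=final_size)
    return selection, subsets


def run_pipeline(
    X: ExpressionMatrix,
    y: LabelVector,
    cfg: PipelineConfig,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Execute selection -> CV evaluation -> clustering verification.

    Gene selection runs once on the full dataset before CV (the single-pass
    flow); synthetic augmentation stays confined to training folds inside
    run_cv.  If ``outdir`` is given, all artifacts and a manifest are
    written there.
    """
    X, y = align(X, y)

    selection, subsets = select_panel(
        X,
        y,
        target_size=cfg.target_size,
        final_size=cfg.final_size,
        step_fraction=cfg.step_fraction,
        vote_min=cfg.vote_min,
        hyperparameters=cfg.learner_hyperparameters,
        seed=cfg.seed,
    )

    X_sel = X.restrict_genes(selection.gene_ids)
    stats = anova_f(X, y)
    corr = correlation_with_label(X_sel, y)

    gan_cfg = cfg.gan if cfg.gan is not None else GanConfig(seed=cfg.seed)
    cv_cfg = CvConfig(
        k=cfg.k,
        augmentation=gan_cfg if cfg.augment else None,
        per_class_multiplier=cfg.per_class_multiplier,
        seed=cfg.seed,
    )
    report = run_cv(X, y, selection, cv_cfg)

    K = cfg.cluster_k if cfg.cluster_k is not None else y.n_classes
    assignments = cluster(
        X_sel, K, method=cfg.cluster_method, linkage=cfg.cluster_linkage, seed=cfg.seed
    )
    newick = (
        dendrogram_newick(X_sel, cfg.cluster_linkage)
        if cfg.cluster_method == "agglomerative"
        else None
    )
    verification = align_and_score(
        assignments, y, group_map=cfg.group_map, method=cfg.cluster_method, dendrogram=newick
    )

    gene_stats = {
        "f_scores": {g: stats.f_scores[g] for g in selection.gene_ids},
        "degenerate": {g: stats.degenerate[g] for g in selection.gene_ids},
        "correlation_names": corr.correlation_names,
        "correlations": np.asarray(corr.correlations).tolist(),
    }

    result = PipelineResult(
        selection=selection,
        subsets=subsets,
        cv_report=report,
        verification=verification,
        gene_stats=gene_stats,
    )
    if outdir is not None:
        _write_artifacts(result, cfg, Path(outdir))
    return result


def _config_dict(cfg: PipelineConfig) -> dict:
    d = dict(cfg.__dict__)
    if d.get("gan") is not None:
        d["gan"] = dict(d["gan"].__dict__)
        d["gan"]["hidden_sizes"] = list(d["gan"]["hidden_sizes"])
    return d


def _write_artifacts(result: PipelineResult, cfg: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_selection(result.selection, outdir / "panel.tsv")
    for sub in result.subsets:
        pd.DataFrame(
            {"gene_id": sub.gene_ids, "importance": sub.scores}
        ).to_csv(outdir / f"subset_{sub.learner.kind}.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "gene_id": list(result.gene_stats["f_scores"]),
            "f_score": list(result.gene_stats["f_scores"].values()),
        }
    ).to_csv(outdir / "f_scores.tsv", sep="\t", index=False)
    names = result.gene_stats["correlation_names"]
    pd.DataFrame(
        result.gene_stats["correlations"], index=names, columns=names
    ).to_csv(outdir / "correlations.tsv", sep="\t")

    write_report(result.cv_report.as_dict(), outdir / "cv_report.json")

    v = result.verification
    pd.DataFrame(
        {"sample_id": list(v.assignments), "cluster": list(v.assignments.values())}
    ).to_csv(outdir / "cluster_assignments.tsv", sep="\t", index=False)
    pd.DataFrame(v.confusion, index=v.cluster_ids, columns=v.class_names).to_csv(
        outdir / "cluster_confusion.tsv", sep="\t"
    )
    write_report(
        {
            "method": v.method,
            "purity": v.purity,
            "ari": v.ari,
            "mapping": {str(k): c for k, c in v.mapping.items()},
        },
        outdir / "cluster_metrics.json",
    )
    if v.dendrogram:
        (outdir / "dendrogram.nwk").write_text(v.dendrogram + "\n")

    cfg_dict = _config_dict(cfg)
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "artifacts": sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"),
    }
    write_report(manifest, outdir / "manifest.json")
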
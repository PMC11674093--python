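"""Per-learner recursive feature elimination and per-gene statistics.

RFE repeatedly fits a boosted learner on the surviving genes, ranks them by
the learner's importance criterion and drops the weakest fraction until the
target panel size remains.  ANOVA F scores and gene/label correlations are
the univariate diagnostics reported alongside a selected panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionMatrix, LabelVector
from .learners import FittedLearner, LearnerSpec, fit_learner

__all__ = [
    "RankedFeatureSet",
    "GeneStats",
    "rfe_rank",
    "anova_f",
    "correlation_with_label",
    "standardize_genes",
]


@dataclass
class RankedFeatureSet:
    """One learner's RFE output: surviving genes, most important first."""

    learner: LearnerSpec
    gene_ids: list[str]
    scores: list[float]
    elimination_trace: list[tuple[int, list[str]]] = field(default_factory=list)


@dataclass
class GeneStats:
    f_scores: dict[str, float]
    degenerate: dict[str, bool]
    correlations: np.ndarray | None = None
    correlation_names: list[str] | None = None
    undefined: np.ndarray | None = None


def standardize_genes(values: np.ndarray) -> np.ndarray:
    """Scale each gene (row) to zero mean, unit variance across samples.

    Constant genes are left at zero rather than divided by zero.  Applied
    before ANOVA-adjacent statistics and clustering, but not before tree
    learners (which are scale-invariant).
    """
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (values - mu) / sd


def _order_genes(
    genes: list[str],
    score: dict[str, float],
    prev_score: dict[str, float],
) -> list[str]:
    """Most- to least-important; ties by earlier-iteration score, then id."""
    return sorted(
        genes,
        key=lambda g: (-score[g], -prev_score.get(g, 0.0), g),
    )


def rfe_rank(
    X: ExpressionMatrix,
    y: LabelVector,
    learner: LearnerSpec,
    target_size: int = 30,
    step_fraction: float = 0.1,
) -> RankedFeatureSet:
    """Recursive feature elimination down to ``target_size`` genes.

    Each iteration fits the learner on the surviving genes and removes the
    ceil(step_fraction * surviving) lowest-importance genes, never dropping
    below target_size (the final iteration removes exactly enough to land on
    it).  Survivors are ordered by final-model importance with ties broken
    by earlier-iteration importance and then lexicographic gene id.
    Deterministic given the learner seed.
    """
    p = X.n_genes
    if not (1 <= target_size <= p):
        raise ValueError(f"target_size must be in [1, {p}], got {target_size}")
    if not (0 < step_fraction < 1):
        raise ValueError("step_fraction must be in (0, 1)")
    if y.n_classes < 2 or len(set(y.labels)) < 2:
        raise ValueError("RFE needs at least two classes present")

    surviving = list(X.gene_ids)
    prev_score: dict[str, float] = {}
    trace: list[tuple[int, list[str]]] = []
    rng = np.random.default_rng(learner.seed)
    iteration = 0
    score: dict[str, float] = {}

    while True:
        sub = X.restrict_genes(surviving)
        fitted = fit_learner(learner, sub.samples_view(), y.labels, y.class_order)
        imp = fitted.importances(sub.samples_view(), rng)
        score = dict(zip(surviving, imp.tolist()))
        ordered = _order_genes(surviving, score, prev_score)
        if len(surviving) == target_size:
            break
        n_drop = min(
            math.ceil(step_fraction * len(surviving)),
            len(surviving) - target_size,
        )
        removed = ordered[len(surviving) - n_drop :]
        trace.append((iteration, list(removed)))
        surviving = ordered[: len(surviving) - n_drop]
        prev_score.update(score)
        iteration += 1

    final_order = _order_genes(surviving, score, prev_score)
    return RankedFeatureSet(
        learner=learner,
        gene_ids=final_order,
        scores=[score[g] for g in final_order],
        elimination_trace=trace,
    )


def anova_f(X: ExpressionMatrix, y: LabelVector) -> GeneStats:
    """One-way ANOVA F per gene across the class groups.

    F = (between-group SS / (g - 1)) / (within-group SS / (n - g)).  Constant
    genes (both sums ~ 0) are flagged degenerate with F = 0; genes with zero
    within-group variance but real between-group spread are flagged
    degenerate with F = inf.
    """
    if y.n_classes < 2:
        raise ValueError("ANOVA needs at least two classes")
    counts = y.class_counts()
    tiny = [c for c, k in counts.items() if k < 2]
    if tiny:
        raise ValueError(f"classes with fewer than 2 samples: {tiny}")

    V = X.values
    codes = y.codes()
    n = V.shape[1]
    g = y.n_classes
    grand = V.mean(axis=1, keepdims=True)
    ssb = np.zeros(V.shape[0])
    ssw = np.zeros(V.shape[0])
    for c in range(g):
        mask = codes == c
        nc = mask.sum()
        mc = V[:, mask].mean(axis=1)
        ssb += nc * (mc - grand[:, 0]) ** 2
        ssw += ((V[:, mask] - mc[:, None]) ** 2).sum(axis=1)

    eps = 1e-12 * np.maximum(1.0, (V**2).sum(axis=1))
    const = (ssb <= eps) & (ssw <= eps)
    perfect = (ssw <= eps) & ~const
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / (g - 1)) / (ssw / (n - g))
    F = np.where(const, 0.0, F)
    F = np.where(perfect, np.inf, F)

    return GeneStats(
        f_scores=dict(zip(X.gene_ids, F.tolist())),
        degenerate=dict(zip(X.gene_ids, (const | perfect).tolist())),
    )


def correlation_with_label(
    X_sel: ExpressionMatrix,
    y: LabelVector,
    coding: dict[str, float] | None = None,
) -> GeneStats:
    """Pearson correlation matrix over selected genes plus a coded label row.

    coding defaults to class_order positions (0, 1, 2, ...), the
    stage-progression direction.  Zero-variance genes get undefined (NaN)
    correlations, flagged in ``undefined`` rather than silently zeroed.
    """
    if coding is None:
        coding = {c: float(i) for i, c in enumerate(y.class_order)}
    if len(set(coding.values())) != len(coding):
        raise ValueError("coding must assign distinct numbers per class")
    coded = np.array([coding[l] for l in y.labels], dtype=float)

    rows = np.vstack([X_sel.values, coded[None, :]])
    names = list(X_sel.gene_ids) + ["label"]
    sd = rows.std(axis=1)
    zero_var = sd == 0

    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(rows)
    corr = np.asarray(corr)
    np.fill_diagonal(corr, 1.0)
    undefined = zero_var[:, None] | zero_var[None, :]
    np.fill_diagonal(undefined, False)
    corr[undefined] = np.nan

    stats_f = {g: float("nan") for g in X_sel.gene_ids}
    return GeneStats(
        f_scores=stats_f,
        degenerate={g: bool(z) for g, z in zip(X_sel.gene_ids, zero_var)},
        correlations=corr,
        correlation_names=names,
        undefined=undefined,
    )
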
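"""Stratified k-fold evaluation with fold-confined GAN augmentation.

Synthetic samples are generated from, and appended to, each training fold
only; every test fold contains exclusively original samples, and the run
aborts (never warns) if that invariant is violated.  The classifier is a
soft-voting ensemble of boosted learners: class-probability vectors are
averaged across learners and the argmax taken, ties broken by class order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .consensus import ConsensusSelection
from .data import ExpressionMatrix, LabelVector
from .gan import GanConfig, generate, train_gan
from .learners import FittedLearner, LearnerSpec, default_learners, fit_learner

__all__ = [
    "CvConfig",
    "CvReport",
    "LeakageError",
    "stratified_folds",
    "ensemble_predict",
    "run_cv",
]


class LeakageError(AssertionError):
    """A synthetic-origin sample reached a test fold."""


@dataclass
class CvConfig:
    k: int = 3
    learners: list[LearnerSpec] | None = None
    augmentation: GanConfig | None = None
    per_class_multiplier: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.per_class_multiplier < 0:
            raise ValueError("per_class_multiplier must be >= 0")


@dataclass
class CvReport:
    fold_assignments: dict[str, int]
    per_fold: list[dict]
    overall_accuracy: float  # percent
    n_correct: int
    n_total: int
    per_class_recall: dict[str, float]
    predictions: dict[str, tuple[str, str]]  # sample_id -> (true, predicted)
    config_echo: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "fold_assignments": self.fold_assignments,
            "per_fold": self.per_fold,
            "overall_accuracy": self.overall_accuracy,
            "overall_fraction": f"{self.n_correct}/{self.n_total}",
            "n_correct": self.n_correct,
            "n_total": self.n_total,
            "per_class_recall": self.per_class_recall,
            "predictions": {s: list(tp) for s, tp in self.predictions.items()},
            "config_echo": self.config_echo,
        }


def stratified_folds(y: LabelVector, k: int, seed: int = 0) -> dict[str, int]:
    """Assign samples to k folds preserving class proportions.

    Members of each class are shuffled (seeded) and dealt round-robin,
    continuing from the fold where the previous class stopped so fold sizes
    stay balanced; per-fold class proportions land within one sample of the
    global proportions.  Classes with fewer than k members still spread one
    sample per fold as far as they go.
    """
    n = len(y.sample_ids)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    offset = 0
    for cls in y.class_order:
        members = [s for s, l in zip(y.sample_ids, y.labels) if l == cls]
        members = [members[i] for i in rng.permutation(len(members))]
        for j, s in enumerate(members):
            assignment[s] = (offset + j) % k
        offset = (offset + len(members)) % k
    return assignment


def ensemble_predict(
    learners: list[FittedLearner],
    X: np.ndarray,
    class_order: list[str],
) -> tuple[list[str], np.ndarray]:
    """Soft vote: mean class-probability vector, argmax, ties by class_order."""
    if not learners:
        raise ValueError("at least one fitted learner required")
    probs = np.mean([l.predict_proba(X) for l in learners], axis=0)
    # np.argmax returns the first maximum, i.e. the earliest class in order
    picks = [class_order[i] for i in np.argmax(probs, axis=1)]
    return picks, probs


def run_cv(
    X: ExpressionMatrix,
    y: LabelVector,
    panel: ConsensusSelection | list[str],
    cfg: CvConfig,
) -> CvReport:
    """Evaluate the boosting ensemble on the panel under leakage-safe k-fold CV.

    Per fold: restrict to panel genes, optionally train the GAN on the
    training fold and append per_class_multiplier x (real per-class count)
    synthetic samples to it, fit every learner, soft-vote the test fold.
    Accuracy is pooled: 100 * total correct / n original samples.
    """
    panel_genes = panel.gene_ids if isinstance(panel, ConsensusSelection) else list(panel)
    X_sel = X.restrict_genes(panel_genes)
    _, y = _aligned(X_sel, y)
    learners = cfg.learners if cfg.learners is not None else default_learners(cfg.seed)

    folds = stratified_folds(y, cfg.k, cfg.seed)
    original_ids = set(y.sample_ids)
    predictions: dict[str, tuple[str, str]] = {}
    per_fold: list[dict] = []

    for fold in range(cfg.k):
        test_ids = [s for s in y.sample_ids if folds[s] == fold]
        train_ids = [s for s in y.sample_ids if folds[s] != fold]
        X_tr = X_sel.restrict_samples(train_ids)
        y_tr = y.subset(train_ids)
        X_te = X_sel.restrict_samples(test_ids)
        y_te = y.subset(test_ids)

        train_mat = X_tr.samples_view()
        train_labels = list(y_tr.labels)
        train_origin_ids = list(train_ids)

        if cfg.augmentation is not None and cfg.per_class_multiplier > 0:
            gan_cfg = GanConfig(**{**cfg.augmentation.__dict__, "seed": cfg.augmentation.seed + fold})
            model = train_gan(X_tr, y_tr, gan_cfg)
            counts = y_tr.class_counts()
            for ci, cls in enumerate(y.class_order):
                n_syn = counts.get(cls, 0) * cfg.per_class_multiplier
                if n_syn == 0:
                    continue
                batch = generate(model, cls, n_syn, seed=gan_cfg.seed * 1000 + ci)
                train_mat = np.vstack([train_mat, batch.values])
                train_labels.extend(batch.labels)
                train_origin_ids.extend(batch.sample_ids)

        # leakage invariant: synthetic ids never intersect the test fold
        synthetic_ids = {s for s in train_origin_ids if s.startswith("synthetic:")}
        if synthetic_ids & set(test_ids):
            raise LeakageError("synthetic sample found in a test fold")

        fitted = [
            fit_learner(spec, train_mat, train_labels, y.class_order)
            for spec in learners
        ]
        picks, _ = ensemble_predict(fitted, X_te.samples_view(), y.class_order)
        for s, true, pred in zip(test_ids, y_te.labels, picks):
            if s not in original_ids or s.startswith("synthetic:"):
                raise LeakageError("prediction on a non-original sample")
            predictions[s] = (true, pred)
        n_correct = sum(t == p for t, p in zip(y_te.labels, picks))
        per_fold.append(
            {
                "fold": fold,
                "n_test": len(test_ids),
                "n_correct": n_correct,
                "accuracy": 100.0 * n_correct / len(test_ids) if test_ids else 0.0,
            }
        )

    n_total = len(y.sample_ids)
    if sum(f["n_test"] for f in per_fold) != n_total or len(predictions) != n_total:
        raise LeakageError("every original sample must be tested exactly once")
    n_correct = sum(t == p for t, p in predictions.values())
    recall = {}
    for cls in y.class_order:
        cls_ids = [s for s, l in zip(y.sample_ids, y.labels) if l == cls]
        if cls_ids:
            recall[cls] = sum(predictions[s][1] == cls for s in cls_ids) / len(cls_ids)

    return CvReport(
        fold_assignments=folds,
        per_fold=per_fold,
        overall_accuracy=100.0 * n_correct / n_total,
        n_correct=n_correct,
        n_total=n_total,
        per_class_recall=recall,
        predictions=predictions,
        config_echo={
            "k": cfg.k,
            "seed": cfg.seed,
            "per_class_multiplier": cfg.per_class_multiplier,
            "augmentation": None
            if cfg.augmentation is None
            else {k_: v for k_, v in cfg.augmentation.__dict__.items()},
            "learners": [
                {
                    "kind": l.kind,
                    "importance_criterion": l.importance_criterion,
                    "hyperparameters": l.params(),
                    "seed": l.seed,
                }
                for l in learners
            ],
            "panel": panel_genes,
        },
    )


def _aligned(X: ExpressionMatrix, y: LabelVector):
    from .data import align

    return align(X, y)
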
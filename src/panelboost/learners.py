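"""Boosted-learner contract: fit, predict probabilities, report importances.

Three learner kinds are distinguished by the importance criterion they rank
genes with, not by vendor internals:

- ``gbdt``          -> split-count ("weight") importance,
- ``catboost_like`` -> prediction-value-change importance (how much the
  model's predicted probabilities move when a feature is permuted),
- ``xgboost_like``  -> gain importance.

Tree building itself is delegated to LightGBM / XGBoost; only the
importance criteria and the surrounding contract live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["LearnerSpec", "FittedLearner", "default_learners", "fit_learner"]

_CRITERION_FOR_KIND = {
    "gbdt": "weight",
    "catboost_like": "prediction_value_change",
    "xgboost_like": "gain",
}

DEFAULT_HYPERPARAMETERS = {
    "n_estimators": 200,
    "max_depth": 3,
    "learning_rate": 0.1,
    # per-tree feature subsampling: without it boosting saturates on one or
    # two discriminative genes and masks the rest with zero importance,
    # which cripples recursive elimination on redundant planted signal
    "colsample_bytree": 0.3,
}


@dataclass(frozen=True)
class LearnerSpec:
    """One boosted learner: its kind, importance criterion and hyperparameters."""

    kind: str
    importance_criterion: str = ""
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _CRITERION_FOR_KIND:
            raise ValueError(f"unknown learner kind {self.kind!r}")
        expected = _CRITERION_FOR_KIND[self.kind]
        if not self.importance_criterion:
            object.__setattr__(self, "importance_criterion", expected)
        elif self.importance_criterion != expected:
            raise ValueError(
                f"kind {self.kind!r} requires criterion {expected!r}, "
                f"got {self.importance_criterion!r}"
            )

    def params(self) -> dict:
        p = dict(DEFAULT_HYPERPARAMETERS)
        p.update(self.hyperparameters)
        return p


def default_learners(seed: int = 0) -> list[LearnerSpec]:
    """The standard trio used for ensemble selection and soft voting."""
    return [
        LearnerSpec("gbdt", seed=seed),
        LearnerSpec("catboost_like", seed=seed),
        LearnerSpec("xgboost_like", seed=seed),
    ]


@dataclass
class FittedLearner:
    spec: LearnerSpec
    model: object
    classes: list[str]
    n_features: int

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """n x C class-probability matrix, columns in ``self.classes`` order."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            proba = np.asarray(self.model.predict_proba(X), dtype=float)
        if proba.ndim != 2 or proba.shape[1] != len(self.classes):
            raise RuntimeError("backend returned a malformed probability matrix")
        sums = proba.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise RuntimeError("learner probability vectors do not sum to 1")
        return proba

    def importances(self, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Per-feature importance under the spec's criterion (>= 0)."""
        crit = self.spec.importance_criterion
        if crit == "weight":
            imp = self.model.booster_.feature_importance(importance_type="split")
            return np.asarray(imp, dtype=float)
        if crit == "gain":
            booster = self.model.get_booster()
            score = booster.get_score(importance_type="gain")
            imp = np.zeros(self.n_features)
            for name, v in score.items():
                imp[int(name[1:])] = v
            return imp
        # prediction_value_change: mean absolute change of predicted
        # probabilities when one feature column is permuted (seeded).
        base = self.predict_proba(X)
        imp = np.zeros(self.n_features)
        perm = rng.permutation(X.shape[0])
        for j in range(self.n_features):
            Xp = X.copy()
            Xp[:, j] = X[perm, j]
            imp[j] = np.mean(np.abs(self.predict_proba(Xp) - base))
        return imp


def _encode(y_labels: list[str], classes: list[str]) -> np.ndarray:
    pos = {c: i for i, c in enumerate(classes)}
    return np.array([pos[l] for l in y_labels], dtype=int)


def fit_learner(
    spec: LearnerSpec,
    X: np.ndarray,
    y_labels: list[str],
    classes: list[str],
) -> FittedLearner:
    """Fit one boosted learner on an n x p matrix with string labels.

    Class columns of the fitted model follow ``classes`` (class_order), not
    the backend's internal sorting.
    """
    if len(set(y_labels)) < 2:
        raise ValueError("cannot fit a classifier on a single class")
    y_full = _encode(y_labels, classes)
    # backends need consecutive 0..k-1 labels even if a class is absent
    present = sorted(set(y_full))
    remap = {cls: i for i, cls in enumerate(present)}
    y = np.array([remap[v] for v in y_full], dtype=int)
    params = spec.params()
    if spec.kind == "gbdt":
        import lightgbm as lgb

        kwargs = dict(
            random_state=spec.seed,
            deterministic=True,
            force_row_wise=True,
            n_jobs=1,
            verbose=-1,
            # tiny-cohort settings: default leaf minimums would forbid any split
            min_child_samples=2,
            min_split_gain=0.0,
            min_child_weight=1e-3,
        )
        kwargs.update(params)
        if "colsample_bytree" in kwargs:  # lightgbm's name for per-tree sampling
            kwargs["feature_fraction"] = kwargs.pop("colsample_bytree")
        model = lgb.LGBMClassifier(**kwargs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, y)
    else:  # catboost_like and xgboost_like share the XGBoost backend
        import xgboost as xgb

        kwargs = dict(
            random_state=spec.seed,
            n_jobs=1,
            tree_method="hist",
            eval_metric="mlogloss",
        )
        kwargs.update(params)
        model = xgb.XGBClassifier(**kwargs)
        model.fit(X, y)

    wrapper = _ClassReorder(model, present=present, n_classes=len(classes))
    return FittedLearner(spec=spec, model=wrapper, classes=list(classes), n_features=X.shape[1])


class _ClassReorder:
    """Expand backend probability columns to the full class_order.

    A training fold may lack a class entirely (degenerate stratification);
    the missing class then gets probability 0 so that soft voting stays
    well-defined across folds.
    """

    def __init__(self, model, present: list[int], n_classes: int):
        self._model = model
        self._present = present
        self._n_classes = n_classes

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        raw = np.asarray(self._model.predict_proba(X), dtype=float)
        if raw.shape[1] == self._n_classes and self._present == list(range(self._n_classes)):
            return raw
        out = np.zeros((raw.shape[0], self._n_classes))
        for col, cls in enumerate(self._present):
            out[:, cls] = raw[:, col]
        return out

    def __getattr__(self, name):
        return getattr(self._model, name)
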
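"""Two-layer stacking ensemble.

Level-0: gradient-boosted trees (XGBoost), a CART decision tree, a
random forest, and the training-free one-shot classifier, with the
framework's reference hyperparameters. Each base learner's out-of-fold
(OOF) probabilities — predictions for each row made by a fold model that
never saw that row — form an (n x 4) matrix. Level-1: a logistic
regression meta-model fit on the OOF matrix; its learned coefficients
realize the adaptive weighting of the base learners. After OOF
construction every base learner is refit on all rows for inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from ddapre.oneshot import OneShotClassifier

BASE_LEARNER_KINDS = ("gbt", "cart", "rf", "oneshot")


@dataclass(frozen=True)
class BaseLearnerSpec:
    """One Level-0 learner; ``params`` override the reference defaults."""

    kind: str
    params: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in BASE_LEARNER_KINDS:
            raise ValueError(f"unknown learner kind {self.kind!r}")

    def build(self, seed: int = 42):
        params = dict(self.params)
        if self.kind == "gbt":
            defaults = dict(
                colsample_bytree=0.8,
                subsample=0.8,
                learning_rate=0.1,
                max_depth=5,
                n_estimators=100,
                random_state=42,
                eval_metric="logloss",
                n_jobs=1,
            )
            defaults.update(params)
            return XGBClassifier(**defaults)
        if self.kind == "cart":
            defaults = dict(
                min_samples_leaf=5, min_samples_split=10, max_depth=None,
                random_state=42,
            )
            defaults.update(params)
            return DecisionTreeClassifier(**defaults)
        if self.kind == "rf":
            defaults = dict(
                min_samples_leaf=10,
                min_samples_split=15,
                max_depth=5,
                n_estimators=30,
                random_state=42,
                n_jobs=1,
            )
            defaults.update(params)
            return RandomForestClassifier(**defaults)
        defaults = dict(h=1024, k_pca=128, seed=seed)
        defaults.update(params)
        return OneShotClassifier(**defaults)


def default_specs() -> list[BaseLearnerSpec]:
    return [BaseLearnerSpec(k) for k in BASE_LEARNER_KINDS]


@dataclass
class StackingModel:
    """Fitted two-layer stack with its OOF bookkeeping."""

    specs: list[BaseLearnerSpec]
    base_learners: list  # refit on all rows
    meta_model: LogisticRegression
    oof_matrix: np.ndarray  # (n, n_learners)
    fold_assignment: np.ndarray  # fold index per training row
    n_folds: int
    seed: int
    n_features: int

    def predict_scores(self, features: np.ndarray) -> np.ndarray:
        X = np.asarray(features, dtype=np.float64)
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension {X.shape[1]} != fitted {self.n_features}"
            )
        base = np.column_stack(
            [m.predict_proba(X)[:, 1] for m in self.base_learners]
        )
        return self.meta_model.predict_proba(base)[:, 1]

    @property
    def meta_coefficients(self) -> np.ndarray:
        return self.meta_model.coef_.ravel()


def fit_stacking(
    features: np.ndarray,
    labels: np.ndarray,
    specs: list[BaseLearnerSpec] | None = None,
    n_folds: int = 5,
    seed: int = 0,
    meta_C: float = 1.0,
) -> StackingModel:
    """Fit the stack: OOF matrix -> meta-model -> full refit of bases."""
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    specs = specs if specs is not None else default_specs()

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**31))
    oof = np.full((len(y), len(specs)), np.nan)
    fold_assignment = np.full(len(y), -1, dtype=int)
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError(f"fold {fold}: single-class training split")
        fold_assignment[test_idx] = fold
        for m, spec in enumerate(specs):
            learner = spec.build(seed=seed)
            learner.fit(X[train_idx], y[train_idx])
            oof[test_idx, m] = learner.predict_proba(X[test_idx])[:, 1]
    assert not np.isnan(oof).any()

    meta = LogisticRegression(C=meta_C, max_iter=1000)
    meta.fit(oof, y)

    base_learners = []
    for spec in specs:
        learner = spec.build(seed=seed)
        learner.fit(X, y)
        base_learners.append(learner)

    return StackingModel(
        specs=list(specs),
        base_learners=base_learners,
        meta_model=meta,
        oof_matrix=oof,
        fold_assignment=fold_assignment,
        n_folds=n_folds,
        seed=seed,
        n_features=X.shape[1],
    )


def predict_stacking(
    model: StackingModel, features: np.ndarray, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior scores and hard labels at the given threshold."""
    scores = model.predict_scores(features)
    return scores, (scores >= threshold).astype(int)
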
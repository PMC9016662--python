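"""Repeated train/test validation of group classification from gaze features.

The evaluation mirrors a diagnosis scenario: participants are repeatedly
split 80/20 (stratified by group), frame statistics and selection masks are
derived from the training participants only, per-participant features are
built, and four classifiers — logistic regression, k-nearest neighbours,
a cost-complexity-pruned decision tree, and a random forest — are scored by
fivefold cross-validation on the training rows and by accuracy on the
held-out rows.  Permutation variable importance is reported for the random
forest.  Defaults: 18 repetitions, test fraction 0.2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from .io import ConfigurationError, GazeDataset, GroupAssignment
from .framewise import (DEFAULT_ALPHA, DEFAULT_MIN_N, summarize_all,
                        video_framewise_stats)
from .selection import (DEFAULT_THRESHOLD_PCT, FeatureTable, SelectionRegime,
                        build_feature_table, build_selection_mask)

logger = logging.getLogger(__name__)

MODEL_KINDS = ("logistic_regression", "knn", "decision_tree", "random_forest")

#: fixed, fully documented hyperparameters (recorded in every report)
HYPERPARAMETERS: dict[str, dict] = {
    "logistic_regression": {"penalty": "l2", "C": 1.0, "max_iter": 2000,
                            "solver": "lbfgs"},
    "knn": {"n_neighbors": 5},
    "decision_tree": {"criterion": "gini",
                      "pruning": "cost-complexity, alpha by internal 5-fold CV"},
    "random_forest": {"n_estimators": 500, "max_features": "sqrt"},
}


@dataclass(frozen=True)
class SplitSpec:
    """One stratified train/test split of the participants."""

    seed: int
    test_fraction: float
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    stratified: bool = True


@dataclass(frozen=True)
class ModelSpec:
    """A classifier family with its fixed hyperparameters."""

    kind: str
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ConfigurationError(f"unknown model kind {self.kind!r}")

    @property
    def hyperparameters(self) -> dict:
        return dict(HYPERPARAMETERS[self.kind])

    def build(self) -> BaseEstimator:
        if self.kind == "logistic_regression":
            return LogisticRegression(C=1.0, max_iter=2000)
        if self.kind == "knn":
            return KNeighborsClassifier(n_neighbors=5)
        if self.kind == "decision_tree":
            return PrunedDecisionTree(random_state=self.seed)
        return RandomForestClassifier(n_estimators=500, max_features="sqrt",
                                      random_state=self.seed)


class PrunedDecisionTree(BaseEstimator, ClassifierMixin):
    """CART with cost-complexity pruning, alpha chosen by internal 5-fold CV.

    Mimics the classic rpart-style workflow: grow the full tree, compute the
    pruning path, pick the alpha with the best internal cross-validated
    accuracy (ties broken toward the strongest pruning), refit.
    """

    def __init__(self, random_state: int = 0, n_internal_folds: int = 5):
        self.random_state = random_state
        self.n_internal_folds = n_internal_folds

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y)
        base = DecisionTreeClassifier(random_state=self.random_state)
        path = base.cost_complexity_pruning_path(X, y)
        alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))
        if len(alphas) > 1:
            n_folds = min(self.n_internal_folds,
                          int(np.bincount(pd.factorize(y)[0]).min()))
            if n_folds >= 2:
                cv = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                     random_state=self.random_state)
                scores = [
                    cross_val_score(
                        DecisionTreeClassifier(random_state=self.random_state,
                                               ccp_alpha=a), X, y, cv=cv).mean()
                    for a in alphas]
                best = max(range(len(alphas)),
                           key=lambda i: (scores[i], alphas[i]))
                alpha = float(alphas[best])
            else:
                alpha = 0.0
        else:
            alpha = float(alphas[0]) if len(alphas) else 0.0
        self.ccp_alpha_ = alpha
        self.tree_ = DecisionTreeClassifier(random_state=self.random_state,
                                            ccp_alpha=alpha).fit(X, y)
        self.classes_ = self.tree_.classes_
        return self

    def predict(self, X):
        return self.tree_.predict(np.asarray(X, float))


@dataclass
class EvaluationReport:
    """Accuracies per (repetition, regime, model) plus aggregates."""

    rows: pd.DataFrame  # repetition, regime, model, cv_accuracy, test_accuracy
    chance_level: float  # majority-class share, in [0, 1]
    variable_importance: pd.Series | None
    model_hyperparameters: dict[str, dict]
    settings: dict

    @property
    def chance_level_pct(self) -> float:
        """Chance level on the percent scale (e.g. 52 for 23 of 44)."""
        return 100.0 * self.chance_level

    def aggregates(self) -> pd.DataFrame:
        """Mean and sd of accuracies over repetitions per (regime, model)."""
        return (self.rows
                .groupby(["regime", "model"], sort=False)[["cv_accuracy",
                                                           "test_accuracy"]]
                .agg(["mean", "std"]))

    def to_dict(self) -> dict:
        agg = self.aggregates()
        agg.columns = ["_".join(c) for c in agg.columns]
        return {
            "chance_level": self.chance_level,
            "chance_level_pct": self.chance_level_pct,
            "rows": self.rows.to_dict(orient="records"),
            "aggregates": agg.reset_index().to_dict(orient="records"),
            "variable_importance": (
                None if self.variable_importance is None
                else self.variable_importance.to_dict()),
            "model_hyperparameters": self.model_hyperparameters,
            "settings": self.settings,
        }


def split_participants(groups: GroupAssignment, test_fraction: float = 0.2,
                       seed: int = 0) -> SplitSpec:
    """Stratified random split; per group, round-half-up of
    ``test_fraction × n`` participants go to test.  Deterministic given seed."""
    if not 0.0 < test_fraction < 1.0:
        raise ConfigurationError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for label in (GroupAssignment.GROUP_A, GroupAssignment.GROUP_B):
        members = sorted(groups.members(label))
        if len(members) < 5:
            raise ConfigurationError(
                f"{label} too small to stratify ({len(members)} participants)")
        n_test = int(np.floor(test_fraction * len(members) + 0.5))
        n_test = max(1, min(n_test, len(members) - 2))
        perm = rng.permutation(len(members))
        test += [members[i] for i in perm[:n_test]]
        train += [members[i] for i in perm[n_test:]]
    return SplitSpec(seed=seed, test_fraction=test_fraction,
                     train_ids=tuple(sorted(train)), test_ids=tuple(sorted(test)))


def _labels(groups: GroupAssignment, ids: Sequence[str]) -> np.ndarray:
    return np.array([groups.labels[p] for p in ids])


def evaluate_once(features: FeatureTable, groups: GroupAssignment,
                  split: SplitSpec, model: ModelSpec) -> tuple[float, float]:
    """Fivefold CV accuracy on the training rows and accuracy on test rows.

    The model is refit per CV fold and finally on all training rows; test rows
    never influence fitting (the feature table must already be training-derived).
    """
    X_train = features.matrix(split.train_ids)
    y_train = _labels(groups, split.train_ids)
    if len(set(y_train)) < 2:
        raise ConfigurationError("single-class training set")
    est = model.build()
    # fivefold whenever the data permit; tiny training sets fall back to the
    # largest stratifiable fold count
    n_splits = int(min(5, np.bincount(pd.factorize(y_train)[0]).min()))
    if n_splits < 2:
        raise ConfigurationError("training set too small for cross-validation")
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True,
                         random_state=split.seed)
    cv_accuracy = float(cross_val_score(clone(est), X_train, y_train, cv=cv,
                                        scoring="accuracy").mean())
    est.fit(X_train, y_train)
    X_test = features.matrix(split.test_ids)
    y_test = _labels(groups, split.test_ids)
    test_accuracy = float((est.predict(X_test) == y_test).mean())
    return cv_accuracy, test_accuracy


def variable_importance(features: FeatureTable, groups: GroupAssignment,
                        train_ids: Sequence[str], rf_spec: ModelSpec | None = None,
                        n_shuffles: int = 5, n_folds: int = 5,
                        seed: int = 0) -> pd.Series:
    """Permutation importance of each feature column for the random forest.

    Mean decrease in held-fold accuracy when the column is permuted, averaged
    over ``n_shuffles`` permutations and ``n_folds`` stratified folds of the
    training rows.  Returned in decreasing rank order.
    """
    rf_spec = rf_spec or ModelSpec("random_forest", seed=seed)
    if rf_spec.kind != "random_forest":
        raise ConfigurationError("variable importance is defined for the "
                                 "random forest model")
    X = features.matrix(train_ids)
    y = _labels(groups, train_ids)
    rng = np.random.default_rng(seed)
    drops = np.zeros(X.shape[1])
    n_eval = 0
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for fit_idx, held_idx in cv.split(X, y):
        est = rf_spec.build().fit(X[fit_idx], y[fit_idx])
        base = (est.predict(X[held_idx]) == y[held_idx]).mean()
        for j in range(X.shape[1]):
            for _ in range(n_shuffles):
                Xp = X[held_idx].copy()
                Xp[:, j] = Xp[rng.permutation(len(held_idx)), j]
                drops[j] += base - (est.predict(Xp) == y[held_idx]).mean()
        n_eval += n_shuffles
    imp = pd.Series(drops / n_eval, index=features.columns,
                    name="permutation_importance")
    return imp.sort_values(ascending=False)


def repeat_experiment(dataset: GazeDataset, groups: GroupAssignment,
                      regimes: Sequence[SelectionRegime | str] | None = None,
                      models: Sequence[str] | None = None,
                      n_repetitions: int = 18, base_seed: int = 0,
                      method: str = "distance", alpha: float = DEFAULT_ALPHA,
                      min_n: int = DEFAULT_MIN_N,
                      threshold_pct: float = DEFAULT_THRESHOLD_PCT,
                      test_fraction: float = 0.2,
                      feature_mode: str = "leak_free_two_centres",
                      compute_importance: bool = True,
                      importance_regime: SelectionRegime | str =
                      SelectionRegime.SELECTED_FRAMES_ALL_VIDEOS
                      ) -> EvaluationReport:
    """Repeated stratified 80/20 evaluation over regimes and models.

    For every repetition ``r`` (seed ``base_seed + r``): split participants;
    compute frame statistics, summaries and selection masks from the training
    participants only; build features for all participants under each regime;
    evaluate every model.  Variable importance (random forest) is averaged
    over repetitions under ``importance_regime``.
    """
    regimes = [SelectionRegime(r) for r in (regimes or list(SelectionRegime))]
    models = list(models or MODEL_KINDS)
    for m in models:
        if m not in MODEL_KINDS:
            raise ConfigurationError(f"unknown model kind {m!r}")
    importance_regime = SelectionRegime(importance_regime)

    records: list[dict] = []
    importances: list[pd.Series] = []

    for r in range(n_repetitions):
        seed = base_seed + r
        split = split_participants(groups, test_fraction, seed=seed)
        groups_train = groups.restrict(split.train_ids)
        train_ds = dataset.subset_participants(list(split.train_ids))
        try:
            stats = video_framewise_stats(train_ds, groups_train, method=method,
                                          min_n=min_n, alpha=alpha)
            summaries = summarize_all(stats, alpha)
            for regime in regimes:
                mask = build_selection_mask(stats, summaries, regime,
                                            split.train_ids, threshold_pct, alpha)
                features = build_feature_table(
                    dataset, groups_train, dataset.participant_ids, mask,
                    mode=feature_mode, min_n=min_n,
                    groups_all=groups if feature_mode ==
                    "paper_faithful_own_centre" else None)
                for kind in models:
                    spec = ModelSpec(kind, seed=seed)
                    cv_acc, test_acc = evaluate_once(features, groups, split, spec)
                    records.append({
                        "repetition": r, "regime": regime.value, "model": kind,
                        "cv_accuracy": cv_acc, "test_accuracy": test_acc,
                        "n_features": len(features.columns),
                        "n_videos_included": len(mask.included_videos()),
                    })
                if compute_importance and regime == importance_regime \
                        and "random_forest" in models:
                    importances.append(variable_importance(
                        features, groups, split.train_ids, seed=seed))
        except ConfigurationError as exc:
            raise ConfigurationError(
                f"repetition {r} (seed {seed}): {exc}") from exc

    rows = pd.DataFrame.from_records(records)
    imp = None
    if importances:
        imp = (pd.concat(importances, axis=1).mean(axis=1)
               .sort_values(ascending=False))
        imp.name = "permutation_importance"

    settings = {
        "n_repetitions": n_repetitions, "base_seed": base_seed,
        "method": method, "alpha": alpha, "min_n": min_n,
        "threshold_pct": threshold_pct, "test_fraction": test_fraction,
        "feature_mode": feature_mode,
        "regimes": [r.value for r in regimes], "models": models,
        "importance_regime": importance_regime.value,
        "split_stratified": True,
        "t_test": "pooled two-sided Student, df = n_a + n_b - 2",
    }
    return EvaluationReport(
        rows=rows, chance_level=groups.majority_share(),
        variable_importance=imp,
        model_hyperparameters={m: HYPERPARAMETERS[m] for m in models},
        settings=settings)
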
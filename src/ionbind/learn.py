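"""Gradient-boosting classification and shadow-feature (Boruta-style)
selection.

The classifier is a stage-wise additive ensemble of shallow regression
trees, F_m(x) = F_{m-1}(x) + rho_m h_m(x); we use scikit-learn's
``GradientBoostingClassifier`` with the number of boosting iterations,
learning rate (shrinkage), tree depth and minimum node size tuned over a
grid by inner cross-validation on the training data only.

Feature selection follows the shadow-feature idea: each iteration appends a
row-shuffled copy of every feature, fits a random forest on the augmented
matrix, and scores a "hit" for every real feature whose importance exceeds
the best shadow importance.  A two-sided binomial test on the hit count (at
level ``alpha``, null p = 0.5) confirms or rejects each feature; unresolved
features stay tentative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold

logger = logging.getLogger(__name__)

_RANGES = {
    "n_trees": (1, 500),
    "min_node": (10, 50),
    "depth": (3, 9),
    "shrinkage": (0.01, 0.1),
}


@dataclass
class GBMConfig:
    """Hyperparameter grid for the boosting classifier.

    The default grid spans the tuning ranges n_trees 1..500, minimum node
    size 10..50, interaction depth 3..9, shrinkage 0.01..0.1.
    :meth:`fast` returns a single sensible grid point for pipeline runs
    where a full sweep is not warranted.
    """

    n_trees: tuple[int, ...] = (50, 100, 200, 500)
    min_node: tuple[int, ...] = (10, 30, 50)
    depth: tuple[int, ...] = (3, 5, 7, 9)
    shrinkage: tuple[float, ...] = (0.01, 0.05, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_trees", "min_node", "depth", "shrinkage"):
            values = getattr(self, name)
            if not values:
                raise ValueError(f"{name} grid is empty")
            lo, hi = _RANGES[name]
            bad = [v for v in values if not lo <= v <= hi]
            if bad:
                raise ValueError(f"{name} values {bad} outside [{lo}, {hi}]")

    @classmethod
    def fast(cls, seed: int = 0) -> "GBMConfig":
        return cls(n_trees=(200,), min_node=(10,), depth=(3,), shrinkage=(0.1,), seed=seed)

    def grid(self) -> list[dict]:
        return [
            {
                "n_estimators": n,
                "min_samples_leaf": m,
                "max_depth": d,
                "learning_rate": s,
            }
            for n, m, d, s in product(self.n_trees, self.min_node, self.depth, self.shrinkage)
        ]


@dataclass
class FittedGBM:
    estimator: GradientBoostingClassifier
    params: dict
    feature_names: list[str]


def train_gbm(
    features: pd.DataFrame,
    labels,
    config: GBMConfig | None = None,
    tuning_folds: int = 3,
) -> FittedGBM:
    """Grid-search (inner CV on the training data only) then refit on all
    training data.  Deterministic given ``config.seed``."""
    config = config or GBMConfig()
    y = np.asarray(labels)
    if features.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    grid = config.grid()
    if len(grid) == 1:
        best = grid[0]
    else:
        cv = StratifiedKFold(
            n_splits=tuning_folds, shuffle=True, random_state=config.seed
        )
        search = GridSearchCV(
            GradientBoostingClassifier(random_state=config.seed),
            param_grid={
                "n_estimators": list(config.n_trees),
                "min_samples_leaf": list(config.min_node),
                "max_depth": list(config.depth),
                "learning_rate": list(config.shrinkage),
            },
            cv=cv,
            scoring="accuracy",
            n_jobs=1,
        )
        search.fit(features.values, y)
        best = search.best_params_
    model = GradientBoostingClassifier(random_state=config.seed, **best)
    model.fit(features.values, y)
    return FittedGBM(estimator=model, params=best, feature_names=list(features.columns))


def predict(model: FittedGBM, features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Binary predictions and positive-class scores; a score of exactly 0.5
    is classified positive."""
    if list(features.columns) != model.feature_names:
        raise ValueError("feature names do not match the trained model")
    scores = model.estimator.predict_proba(features.values)[:, 1]
    return (scores >= 0.5).astype(int), scores


@dataclass
class SelectionReport:
    """Outcome of shadow-feature selection: the three lists partition the
    input feature names."""

    confirmed: list[str]
    rejected: list[str]
    tentative: list[str]
    hits: dict[str, int] = field(default_factory=dict)
    n_iterations: int = 0
    importance_history: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        union = set(self.confirmed) | set(self.rejected) | set(self.tentative)
        total = len(self.confirmed) + len(self.rejected) + len(self.tentative)
        if len(union) != total:
            raise ValueError("confirmed/rejected/tentative lists overlap")


def select_features_shadow(
    features: pd.DataFrame,
    labels,
    max_iter: int = 30,
    alpha: float = 0.01,
    seed: int = 0,
    n_estimators: int = 100,
) -> SelectionReport:
    """Shadow-feature selection against random probes.

    Constant (zero-variance) features cannot beat any probe and are
    auto-rejected with a warning before the iterations start.
    """
    if len(features) < 30:
        raise ValueError("shadow selection needs at least 30 samples")
    if max_iter < 10:
        raise ValueError("max_iter must be at least 10")
    y = np.asarray(labels)
    names = list(features.columns)

    constant = [n for n in names if features[n].nunique() <= 1]
    if constant:
        logger.warning("auto-rejecting %d constant feature(s): %s", len(constant), constant)
    active = [n for n in names if n not in constant]
    X = features[active].values
    n_feat = len(active)

    rng = np.random.default_rng(seed)
    hits = np.zeros(n_feat, dtype=int)
    history = np.zeros((max_iter, n_feat))
    for it in range(max_iter):
        shadow = X.copy()
        for j in range(n_feat):
            rng.shuffle(shadow[:, j])
        forest = RandomForestClassifier(
            n_estimators=n_estimators,
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        )
        forest.fit(np.hstack([X, shadow]), y)
        imp = forest.feature_importances_
        real, probes = imp[:n_feat], imp[n_feat:]
        threshold = probes.max() if n_feat else 0.0
        hits += real > threshold
        history[it] = real

    confirmed, rejected, tentative = [], list(constant), []
    for j, name in enumerate(active):
        p = binomtest(int(hits[j]), max_iter, 0.5, alternative="two-sided").pvalue
        if p < alpha and hits[j] > max_iter / 2:
            confirmed.append(name)
        elif p < alpha and hits[j] < max_iter / 2:
            rejected.append(name)
        else:
            tentative.append(name)
    return SelectionReport(
        confirmed=confirmed,
        rejected=rejected,
        tentative=tentative,
        hits={n: int(h) for n, h in zip(active, hits)},
        n_iterations=max_iter,
        importance_history=pd.DataFrame(history, columns=active),
    )
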
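"""The five base regression families under one interface: year-ahead split,
Bayesian tuning with cross-validated MSE, and prediction-matrix assembly.

Family names:

* ``linear`` — ordinary least squares (untunable)
* ``lasso`` — L1-penalized linear regression
* ``random_forest`` — bagged trees
* ``gb_a`` / ``gb_b`` — two gradient-boosting implementations
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import (
    GradientBoostingRegressor,
    HistGradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.linear_model import Lasso, LinearRegression
from sklearn.model_selection import KFold, cross_val_score

from .preprocess import TARGET
from .tuning import Integer, Real, bayes_search

FAMILIES = ("linear", "lasso", "random_forest", "gb_a", "gb_b")

DEFAULT_SPACES: dict[str, dict] = {
    "linear": {},
    "lasso": {"alpha": Real(1e-4, 10.0, log=True)},
    "random_forest": {
        "n_estimators": Integer(100, 500),
        "max_depth": Integer(3, 20),
        "max_features": Real(0.2, 1.0),
    },
    "gb_a": {
        "n_estimators": Integer(100, 1000),
        "learning_rate": Real(0.005, 0.3, log=True),
        "max_depth": Integer(3, 10),
        "subsample": Real(0.5, 1.0),
    },
    "gb_b": {
        "max_iter": Integer(100, 1000),
        "learning_rate": Real(0.005, 0.3, log=True),
        "max_depth": Integer(3, 10),
    },
}


class EmptyTrainError(ValueError):
    pass


class FoldSizeError(ValueError):
    pass


@dataclass
class ModelSpec:
    """One base learner: family, search space, and tuning budget."""

    family: str
    space: dict = None  # None -> family default
    n_iter: int = 40
    cv: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.n_iter < 1 or self.cv < 2:
            raise ValueError("tuning budget must have n_iter >= 1 and cv >= 2")
        if self.space is None:
            self.space = dict(DEFAULT_SPACES[self.family])

    def make_estimator(self, params: dict[str, Any]):
        seed = self.seed
        if self.family == "linear":
            return LinearRegression()
        if self.family == "lasso":
            return Lasso(max_iter=50_000, random_state=seed, **params)
        if self.family == "random_forest":
            return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
        if self.family == "gb_a":
            return GradientBoostingRegressor(random_state=seed, **params)
        return HistGradientBoostingRegressor(random_state=seed, **params)


@dataclass
class FittedModel:
    name: str
    spec: ModelSpec
    estimator: Any
    best_params: dict
    cv_mse: float | None
    history: list = field(default_factory=list, repr=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(X)


def temporal_split(
    panel: pd.DataFrame, test_year: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Train on all years strictly before ``test_year``; test on it alone."""
    years = panel["year"]
    if test_year not in set(years):
        raise ValueError(f"test year {test_year} not present in panel")
    train = panel[years < test_year]
    if train.empty:
        raise EmptyTrainError(f"no training rows before {test_year}")
    return train, panel[years == test_year]


def tune_and_fit(
    spec: ModelSpec,
    train: pd.DataFrame,
    features: list[str],
    target: str = TARGET,
) -> FittedModel:
    """Bayesian-search the spec's space by cross-validated MSE on the
    training partition, then refit the winner on all of it.  The plain
    linear family (empty space) skips tuning."""
    missing = [f for f in features if f not in train.columns]
    if missing:
        raise KeyError(f"features absent from training partition: {missing[:5]}")
    X = train[list(features)].to_numpy()
    y = train[target].to_numpy()

    if not spec.space:
        est = spec.make_estimator({})
        est.fit(X, y)
        return FittedModel(spec.family, spec, est, {}, None)

    cv = KFold(n_splits=spec.cv, shuffle=True, random_state=spec.seed)

    def objective(params: dict) -> float:
        est = spec.make_estimator(params)
        scores = cross_val_score(
            est, X, y, cv=cv, scoring="neg_mean_squared_error", n_jobs=1
        )
        return -float(scores.mean())

    best_params, best_mse, history = bayes_search(
        objective, spec.space, n_iter=spec.n_iter, seed=spec.seed
    )
    est = spec.make_estimator(best_params)
    est.fit(X, y)
    return FittedModel(spec.family, spec, est, best_params, best_mse, history)


def _fold_assignment(n: int, n_folds: int, seed: int) -> np.ndarray:
    """Deterministic pseudo-random fold labels derived from the run seed."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF01D]))
    return rng.permutation(np.arange(n) % n_folds)


def collect_predictions(
    models: list[FittedModel],
    train: pd.DataFrame,
    test: pd.DataFrame,
    features: list[str],
    target: str = TARGET,
    mode: str = "out_of_fold",
    n_folds: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the (train, test) prediction matrices.

    The train matrix holds, per model, either 10-fold out-of-fold predictions
    (each fold predicted by a clone refit without it) or in-sample
    predictions.  The test matrix always holds the fitted models'
    predictions on the held-out rows.
    """
    if mode not in ("out_of_fold", "in_sample"):
        raise ValueError("mode must be 'out_of_fold' or 'in_sample'")
    cols = list(features)
    X_tr = train[cols].to_numpy()
    y_tr = train[target].to_numpy()
    X_te = test[cols].to_numpy()

    pm_train = train[["geoid", "year"]].copy().reset_index(drop=True)
    pm_train["y_true"] = y_tr
    pm_test = test[["geoid", "year"]].copy().reset_index(drop=True)
    pm_test["y_true"] = test[target].to_numpy()

    folds = _fold_assignment(len(train), n_folds, seed)
    for f in range(n_folds):
        if (folds == f).sum() < 2 or (folds != f).sum() < 2:
            raise FoldSizeError(f"fold {f} too small for out-of-fold prediction")

    for model in models:
        if mode == "in_sample":
            pm_train[model.name] = model.predict(X_tr)
        else:
            oof = np.full(len(train), np.nan)
            for f in range(n_folds):
                hold = folds == f
                est = clone(model.estimator)
                est.fit(X_tr[~hold], y_tr[~hold])
                oof[hold] = est.predict(X_tr[hold])
            assert not np.isnan(oof).any()
            pm_train[model.name] = oof
        pm_test[model.name] = model.predict(X_te)

    pm_train.attrs["role"] = f"train-{mode.replace('_', '-')}"
    pm_test.attrs["role"] = "test"
    pm_train.attrs["models"] = [m.name for m in models]
    pm_test.attrs["models"] = [m.name for m in models]
    return pm_train, pm_test
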
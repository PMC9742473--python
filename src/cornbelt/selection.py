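"""Two-stage feature selection: expert week-window filter, then permutation
importance under a tuned random forest, keeping the top k (default 100)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import GridSearchCV

from .preprocess import TARGET

#: inclusive week windows retained by the expert filter
WEATHER_WEEK_WINDOW = (16, 43)
PLANTING_WEEK_WINDOW = (12, 29)

#: tree-count grid for forest tuning; 300 is the documented default when
#: tuning is disabled
FOREST_TREE_GRID = (100, 200, 300, 500)
DEFAULT_FOREST_TREES = 300
DEFAULT_TOP_K = 100


class SchemaError(KeyError):
    """A column lacks the manifest annotation the filter needs."""


@dataclass
class FeatureSet:
    """Ordered feature names with a provenance tag per name."""

    names: list[str]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"names": self.names, "provenance": self.provenance}, indent=1)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureSet":
        raw = json.loads(Path(path).read_text())
        return cls(names=raw["names"], provenance=raw["provenance"])


def expert_filter(
    manifest: dict,
    weather_window: tuple[int, int] = WEATHER_WEEK_WINDOW,
    planting_window: tuple[int, int] = PLANTING_WEEK_WINDOW,
) -> FeatureSet:
    """Drop weekly weather columns outside ``weather_window`` and planting
    columns outside ``planting_window``; keep everything else (soil, crop
    model, quarterly, trend).  Purely manifest-driven."""
    names, prov = [], {}
    for col, meta in manifest.items():
        src = meta.get("source")
        week = meta.get("week")
        if src in ("weather", "planting"):
            if week is None:
                raise SchemaError(f"weekly column {col!r} lacks a week annotation")
            lo, hi = weather_window if src == "weather" else planting_window
            if not lo <= week <= hi:
                continue
        names.append(col)
        prov[col] = "expert-retained"
    return FeatureSet(names=names, provenance=prov)


def _tune_forest(
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    tree_grid: tuple[int, ...],
    cv: int,
) -> RandomForestRegressor:
    base = RandomForestRegressor(random_state=seed, n_jobs=1)
    search = GridSearchCV(
        base,
        {"n_estimators": list(tree_grid)},
        cv=cv,
        scoring="neg_mean_squared_error",
    )
    search.fit(X, y)
    return search.best_estimator_


def rank_features_permutation(
    panel: pd.DataFrame,
    featureset: FeatureSet,
    *,
    target: str = TARGET,
    seed: int = 0,
    n_repeats: int = 10,
    tune: bool = True,
    tree_grid: tuple[int, ...] = FOREST_TREE_GRID,
    cv: int = 10,
    n_trees: int = DEFAULT_FOREST_TREES,
) -> pd.DataFrame:
    """Rank features by mean validation-MSE increase under shuffling.

    The validation split is the most recent year present in the panel; the
    forest is fit on all earlier years.  With ``tune=True`` the tree count is
    grid-searched with cross-validation on the training split; otherwise
    ``n_trees`` is used directly.  Importance for a feature is the mean, over
    ``n_repeats`` independent shuffles of that column in the validation set,
    of the increase in validation MSE.  Returns a frame with columns
    name, importance, impurity_importance, rank (rank 1 = most important).
    """
    years = panel["year"].unique()
    if len(years) < 2:
        raise ValueError("need at least two years to form a validation split")
    val_year = years.max()
    train = panel[panel["year"] < val_year]
    val = panel[panel["year"] == val_year]
    if val.empty or train.empty:
        raise ValueError("empty train or validation split")

    cols = list(featureset.names)
    X_tr, y_tr = train[cols].to_numpy(), train[target].to_numpy()
    X_val, y_val = val[cols].to_numpy(), val[target].to_numpy()

    if tune:
        forest = _tune_forest(X_tr, y_tr, seed, tree_grid, cv)
    else:
        forest = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
        forest.fit(X_tr, y_tr)

    perm = permutation_importance(
        forest,
        X_val,
        y_val,
        scoring="neg_mean_squared_error",
        n_repeats=n_repeats,
        random_state=seed,
        n_jobs=1,
    )
    ranking = pd.DataFrame(
        {
            "name": cols,
            "importance": perm.importances_mean,  # mean MSE increase
            "impurity_importance": forest.feature_importances_,  # diagnostic only
        }
    )
    ranking = ranking.sort_values(
        ["importance", "name"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    return ranking


def select_top_k(ranking: pd.DataFrame, k: int = DEFAULT_TOP_K) -> FeatureSet:
    """Keep the k best-ranked features; ties already broken lexicographically
    by the stable sort in the ranking."""
    if k > len(ranking):
        raise ValueError(f"k={k} exceeds the {len(ranking)} ranked features")
    if k < 1:
        raise ValueError("k must be >= 1")
    top = ranking.nsmallest(k, "rank").sort_values("rank")
    names = top["name"].tolist()
    return FeatureSet(names=names, provenance={n: "permutation-rank" for n in names})
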
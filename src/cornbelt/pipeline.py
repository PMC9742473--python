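"""Experiment runner: chains generation, preprocessing, selection, base
learners, both ensembles, and evaluation per test year, with a paired
with/without-crop-model comparison."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, preprocess, selection
from .ensemble import (
    fit_average_weights,
    fit_optimized_weights,
    predict_ensemble,
)
from .learners import (
    FAMILIES,
    FittedModel,
    ModelSpec,
    collect_predictions,
    temporal_split,
    tune_and_fit,
)
from .preprocess import TARGET
from .synth import ScenarioConfig, generate_scenario

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""


@dataclass
class RunConfig:
    """Everything one experiment run needs.  ``seed`` is the root seed: the
    scenario, fold assignment, selection, and every learner derive their
    seeds from it."""

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    test_years: tuple[int, ...] = (2018, 2019, 2020)
    k: int = selection.DEFAULT_TOP_K
    ensemble_mode: str = "out_of_fold"
    include_apsim: bool = True
    families: tuple[str, ...] = FAMILIES
    tune_iterations: int = 40
    tune_cv: int = 10
    stack_folds: int = 10
    selection_tune: bool = True
    selection_cv: int = 10
    selection_repeats: int = 10
    selection_trees: int = selection.DEFAULT_FOREST_TREES
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be positive")
        for y in self.test_years:
            if not self.scenario.year_start < y <= self.scenario.year_end:
                raise ValueError(f"test year {y} outside the panel's usable range")

    def derived_seed(self, offset: int) -> int:
        return int(
            np.random.SeedSequence([self.seed, offset]).generate_state(1)[0] % 2**31
        )


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def prepare_panel(config: RunConfig):
    """Generate the scenario and build the merged, imputed panel with
    quarterly features (trend is added per test year, train-only)."""
    scenario = config.scenario.replace(seed=config.derived_seed(0))
    data = generate_scenario(scenario)
    panel, manifest = preprocess.merge_sources(
        data.yields,
        data.weather,
        data.soil,
        data.planting,
        data.apsim,
        data.geography,
    )
    panel = preprocess.impute_missing(panel, manifest)
    panel, manifest = preprocess.add_quarterly_features(panel, manifest)
    return data, panel, manifest


def run_test_year(
    config: RunConfig,
    panel: pd.DataFrame,
    manifest: dict,
    geography: pd.DataFrame,
    test_year: int,
) -> dict:
    """One rolling-origin evaluation: trend fit, selection, five learners,
    both ensembles, metrics.  Returns all per-year artifacts in a dict."""
    panel = panel[panel["year"] <= test_year]
    manifest = dict(manifest)
    if not config.include_apsim:
        manifest = {c: m for c, m in manifest.items() if m["source"] != "apsim"}

    train_years = {y for y in panel["year"].unique() if y < test_year}
    trend_models = preprocess.fit_trend_models(
        panel[["geoid", "year", TARGET]], train_years, geography
    )
    panel, manifest = preprocess.add_trend_feature(panel, trend_models, manifest)

    train, test = temporal_split(panel, test_year)

    retained = selection.expert_filter(manifest)
    ranking = selection.rank_features_permutation(
        train,
        retained,
        seed=config.derived_seed(1),
        n_repeats=config.selection_repeats,
        tune=config.selection_tune,
        cv=config.selection_cv,
        n_trees=config.selection_trees,
    )
    k = min(config.k, len(ranking))
    selected = selection.select_top_k(ranking, k)

    models: list[FittedModel] = []
    for i, family in enumerate(config.families):
        spec = ModelSpec(
            family=family,
            n_iter=config.tune_iterations,
            cv=config.tune_cv,
            seed=config.derived_seed(10 + i),
        )
        models.append(tune_and_fit(spec, train, selected.names))

    pm_train, pm_test = collect_predictions(
        models,
        train,
        test,
        selected.names,
        mode=config.ensemble_mode,
        n_folds=config.stack_folds,
        seed=config.derived_seed(2),
    )

    w_opt = fit_optimized_weights(pm_train)
    w_avg = fit_average_weights(len(models), [m.name for m in models])
    pm_test = pm_test.copy()
    pm_test["optimized_ensemble"] = predict_ensemble(w_opt, pm_test)
    pm_test["average_ensemble"] = predict_ensemble(w_avg, pm_test)

    return {
        "test_year": test_year,
        "trend_models": trend_models,
        "ranking": ranking,
        "selected": selected,
        "models": models,
        "pm_train": pm_train,
        "pm_test": pm_test,
        "weights_optimized": w_opt,
        "weights_average": w_avg,
    }


def evaluate_test_year(
    year_result: dict, yields: pd.DataFrame, geography: pd.DataFrame
) -> dict:
    """Shock-county exclusion, per-model overall metrics, and the optimized
    ensemble's regional error tables for one test year."""
    pm_test = year_result["pm_test"]
    flags = yields[["geoid", "year", "shock_flag"]]
    n_before = len(pm_test)
    pm_eval = evaluation.apply_exclusions(pm_test, flags)
    n_excluded = n_before - len(pm_eval)

    model_cols = pm_test.attrs.get("models", []) + [
        "optimized_ensemble",
        "average_ensemble",
    ]
    rows = []
    for col in model_cols:
        row = evaluation.metrics_row(pm_eval["y_true"], pm_eval[col])
        rows.append({"model": col, "year": year_result["test_year"], **row})
    metrics = pd.DataFrame(rows)

    opt = pm_eval.rename(columns={"optimized_ensemble": "y_pred"})[
        ["geoid", "year", "y_true", "y_pred"]
    ]
    regional = {
        level: evaluation.error_by_region(opt, geography, level=level)
        for level in ("county", "crd", "state")
    }
    return {
        "metrics": metrics,
        "regional": regional,
        "n_excluded": n_excluded,
        "eval_predictions": opt,
    }


@_stage("run-experiment")
def run_experiment(config: RunConfig) -> dict:
    """Full rolling-origin experiment over ``config.test_years``.

    Returns a manifest dict with per-year weights and metrics, the pooled
    county error table, and the error-covariate correlation screen.  When
    ``config.output_dir`` is set, all tabular artifacts are written there.
    """
    data, panel, manifest = prepare_panel(config)
    year_results, metric_frames, eval_preds, excluded = [], [], [], {}
    for test_year in config.test_years:
        yr = run_test_year(config, panel, manifest, data.geography, test_year)
        ev = evaluate_test_year(yr, data.yields, data.geography)
        logger.info(
            "test year %d: excluded %d shocked rows", test_year, ev["n_excluded"]
        )
        year_results.append((yr, ev))
        metric_frames.append(ev["metrics"])
        eval_preds.append(ev["eval_predictions"])
        excluded[test_year] = ev["n_excluded"]

    metrics = pd.concat(metric_frames, ignore_index=True)
    pooled = pd.concat(eval_preds, ignore_index=True)
    county_metrics = evaluation.compute_metrics(
        pooled, "y_true", "y_pred", group_cols=["geoid"]
    )
    covariates = evaluation.county_covariate_summaries(panel)
    correlations = evaluation.correlate_error_features(
        county_metrics, covariates, data.geography
    )

    result = {
        "config": config,
        "metrics": metrics,
        "county_metrics": county_metrics,
        "correlations": correlations,
        "excluded_by_year": excluded,
        "years": {
            yr["test_year"]: {
                "weights_optimized": yr["weights_optimized"],
                "weights_average": yr["weights_average"],
                "pm_train": yr["pm_train"],
                "pm_test": yr["pm_test"],
                "selected": yr["selected"],
                "ranking": yr["ranking"],
                "regional": ev["regional"],
            }
            for yr, ev in year_results
        },
    }
    if config.output_dir:
        _write_artifacts(result, panel, manifest, Path(config.output_dir))
    return result


def _jsonable_config(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def _write_artifacts(result: dict, panel: pd.DataFrame, manifest: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    preprocess.write_features(panel, manifest, outdir)
    result["metrics"].to_csv(outdir / "metrics.csv", index=False)
    result["county_metrics"].to_csv(outdir / "county_metrics.csv", index=False)
    result["correlations"].to_csv(outdir / "correlations.csv", index=False)
    weights = {}
    for year, yr in result["years"].items():
        ydir = outdir / f"year_{year}"
        ydir.mkdir(exist_ok=True)
        yr["ranking"].to_csv(ydir / "ranking.csv", index=False)
        yr["selected"].to_json(ydir / "selected_features.json")
        yr["pm_train"].to_csv(ydir / "predictions_train.csv", index=False)
        yr["pm_test"].to_csv(ydir / "predictions_test.csv", index=False)
        for level, table in yr["regional"].items():
            table.to_csv(ydir / f"region_errors_{level}.csv", index=False)
        weights[str(year)] = {
            "optimized": yr["weights_optimized"].as_dict(),
            "average": yr["weights_average"].as_dict(),
        }
    (outdir / "weights.json").write_text(json.dumps(weights, indent=1))
    run_manifest = {
        "config": _jsonable_config(result["config"]),
        "excluded_by_year": {str(k): v for k, v in result["excluded_by_year"].items()},
        "n_rows": int(len(panel)),
    }
    (outdir / "run_manifest.json").write_text(json.dumps(run_manifest, indent=1))


@_stage("compare-apsim")
def compare_with_without_apsim(config: RunConfig, n_seeds: int = 10) -> pd.DataFrame:
    """Paired per-seed overall test RMSE of the optimized ensemble with and
    without the crop-model feature block.  Returns 2 x n_seeds rows plus
    summary attrs (mean difference, paired sign count)."""
    if n_seeds < 2:
        raise ValueError("need n_seeds >= 2 for a paired comparison")
    rows = []
    for s in range(n_seeds):
        for include in (True, False):
            cfg = dataclasses.replace(
                config,
                include_apsim=include,
                seed=config.seed + 1000 * s,
                output_dir=None,
            )
            res = run_experiment(cfg)
            m = res["metrics"]
            opt = m[m["model"] == "optimized_ensemble"]
            rmse = float(
                np.sqrt(np.average(opt["rmse"] ** 2, weights=opt["n"]))
            )  # pooled over test years
            rows.append({"seed_index": s, "include_apsim": include, "rmse": rmse})
    table = pd.DataFrame(rows)
    wide = table.pivot(index="seed_index", columns="include_apsim", values="rmse")
    diff = wide[False] - wide[True]  # positive -> crop-model block helps
    table.attrs["mean_rmse_difference"] = float(diff.mean())
    table.attrs["n_seeds_apsim_wins"] = int((diff > 0).sum())
    return table
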
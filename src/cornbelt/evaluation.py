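"""Error metrics (RMSE, RRMSE, MBE, R^2), shock-county exclusion, regional
aggregation with cropland ratio, and the error-vs-covariate Pearson screen."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def metrics_row(y: np.ndarray, yhat: np.ndarray) -> dict:
    """RMSE, RRMSE (percent of mean observed), MBE (signed, predicted minus
    observed), and R^2 (1 - RSS/TSS, unclamped) for one scope."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size == 0 or y.size != yhat.size:
        raise ValueError("need aligned, nonempty vectors")
    resid = y - yhat
    rmse = float(np.sqrt(np.mean(resid**2)))
    mbe = float(np.mean(yhat - y))
    mean_y = float(np.mean(y))
    if mean_y == 0.0:
        logger.warning("zero-mean observations: RRMSE undefined")
        rrmse = np.nan
    else:
        rrmse = 100.0 * rmse / mean_y
    tss = float(np.sum((y - mean_y) ** 2))
    if tss == 0.0:
        logger.warning("zero-variance observations: R^2 undefined")
        r2 = np.nan
    else:
        r2 = 1.0 - float(np.sum(resid**2)) / tss
    return {"rmse": rmse, "rrmse": rrmse, "mbe": mbe, "r2": r2, "n": int(y.size)}


def compute_metrics(
    frame: pd.DataFrame,
    truth_col: str = "y_true",
    pred_col: str = "y_pred",
    group_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Metric report per scope; ``group_cols=None`` gives one overall row."""
    if group_cols:
        rows = []
        for key, grp in frame.groupby(group_cols, sort=True):
            key = key if isinstance(key, tuple) else (key,)
            row = dict(zip(group_cols, key))
            row.update(metrics_row(grp[truth_col].to_numpy(), grp[pred_col].to_numpy()))
            rows.append(row)
        return pd.DataFrame(rows)
    return pd.DataFrame([{"scope": "overall", **metrics_row(
        frame[truth_col].to_numpy(), frame[pred_col].to_numpy())}])


def apply_exclusions(test_panel: pd.DataFrame, shock_flags: pd.DataFrame) -> pd.DataFrame:
    """Drop flagged (geoid, year) rows from the evaluation set only.

    ``shock_flags`` needs columns geoid, year, shock_flag.  Training
    artifacts are never touched by this step.
    """
    if shock_flags.empty or not shock_flags["shock_flag"].any():
        return test_panel
    flagged = shock_flags.loc[shock_flags["shock_flag"], ["geoid", "year"]]
    keys = test_panel[["geoid", "year"]].merge(flagged, on=["geoid", "year"], how="left", indicator=True)
    keep = (keys["_merge"] == "left_only").to_numpy()
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("exclusion filter removed %d county-year rows", n_removed)
    return test_panel[keep]


def error_by_region(
    predictions: pd.DataFrame,
    geography: pd.DataFrame,
    level: str = "county",
    truth_col: str = "y_true",
    pred_col: str = "y_pred",
) -> pd.DataFrame:
    """Metrics within each region at ``level`` in {county, crd, state},
    joined with the region's mean cropland ratio."""
    level_col = {"county": "geoid", "crd": "crd", "state": "state"}.get(level)
    if level_col is None:
        raise ValueError("level must be 'county', 'crd', or 'state'")
    geo = geography[["geoid", "state", "crd", "cropland_ratio"]]
    merged = predictions.merge(geo, on="geoid", how="left", suffixes=("", "_geo"))
    if merged["cropland_ratio"].isna().any():
        missing = merged.loc[merged["cropland_ratio"].isna(), "geoid"].unique()
        raise KeyError(f"unmapped geoids: {missing[:5]}")
    report = compute_metrics(merged, truth_col, pred_col, group_cols=[level_col])
    cropland = merged.groupby(level_col)["cropland_ratio"].mean().rename("cropland_ratio")
    return report.merge(cropland, left_on=level_col, right_index=True)


def county_covariate_summaries(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-county covariates for the error screen: annual and summer
    (weeks 27-39) precipitation and temperature summaries, topsoil
    properties, and mean water-table depth."""
    summer = range(27, 40)
    annual = range(1, 53)

    def weekly(var, weeks):
        return [f"{var}_wk{w}" for w in weeks if f"{var}_wk{w}" in panel.columns]

    per_row = pd.DataFrame({"geoid": panel["geoid"]})
    per_row["annual_prcp"] = panel[weekly("prcp", annual)].sum(axis=1)
    per_row["summer_prcp"] = panel[weekly("prcp", summer)].sum(axis=1)
    per_row["annual_tmax"] = panel[weekly("tmax", annual)].mean(axis=1)
    per_row["summer_tmax"] = panel[weekly("tmax", summer)].mean(axis=1)
    per_row["annual_tmin"] = panel[weekly("tmin", annual)].mean(axis=1)
    per_row["summer_tmin"] = panel[weekly("tmin", summer)].mean(axis=1)
    for soil_col, name in [
        ("clay_d1", "clay_pct"),
        ("sand_d1", "sand_pct"),
        ("om_d1", "organic_matter"),
        ("ph_d1", "soil_ph"),
        ("paw_d1", "plant_available_water"),
    ]:
        if soil_col in panel.columns:
            per_row[name] = panel[soil_col]
    if "AnnualAvgWT" in panel.columns:
        per_row["water_table_depth"] = panel["AnnualAvgWT"]
    return per_row.groupby("geoid").mean().reset_index()


def correlate_error_features(
    county_metrics: pd.DataFrame,
    covariates: pd.DataFrame,
    geography: pd.DataFrame,
    min_counties: int = 3,
) -> pd.DataFrame:
    """Pearson r (with two-sided p) between county RMSE and each covariate,
    per state and pooled over all states."""
    merged = county_metrics[["geoid", "rmse"]].merge(covariates, on="geoid")
    merged = merged.merge(geography[["geoid", "state"]], on="geoid")
    cov_cols = [c for c in covariates.columns if c != "geoid"]

    rows = []
    groups = [("all", merged)] + [(s, g) for s, g in merged.groupby("state")]
    for state, grp in groups:
        if len(grp) < min_counties:
            continue
        for cov in cov_cols:
            x = grp[cov].to_numpy()
            if np.std(x) == 0 or np.std(grp["rmse"]) == 0:
                rows.append({"state": state, "covariate": cov,
                             "pearson_r": np.nan, "p_value": np.nan, "n": len(grp)})
                continue
            r, p = stats.pearsonr(grp["rmse"], x)
            rows.append({"state": state, "covariate": cov,
                         "pearson_r": float(r), "p_value": float(p), "n": len(grp)})
    return pd.DataFrame(rows)
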
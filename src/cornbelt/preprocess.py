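"""Panel assembly: merge the five sources onto the yield reference, impute,
and construct quarterly-weather and per-county yield-trend features.

The merged panel carries key columns (geoid, year, state, crd,
cropland_ratio), the target ``yield_mg_ha`` plus ``shock_flag``, and named
feature columns.  A column manifest (dict keyed by column name) records each
feature's source and, for weekly columns, its week number; the expert filter
downstream is driven entirely by this manifest.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import schema

logger = logging.getLogger(__name__)

KEY_COLUMNS = ("geoid", "year", "state", "crd", "cropland_ratio")
TARGET = "yield_mg_ha"
TREND_COLUMN = "yield_trend"

#: quarters as inclusive week ranges
QUARTERS = {1: range(1, 14), 2: range(14, 27), 3: range(27, 40), 4: range(40, 53)}
#: weekly variables summed (totals) vs averaged (temperatures) per quarter
QUARTER_SUM_VARS = ("prcp", "rad", "gdd")
QUARTER_MEAN_VARS = ("tmin", "tmax")


class IntegrityError(ValueError):
    """A source table violates the merge preconditions."""


class PanelJoinError(KeyError):
    """A county cannot be mapped through the geography table."""


def _check_unique(df: pd.DataFrame, keys: list[str], name: str) -> None:
    if df.duplicated(subset=keys).any():
        raise IntegrityError(f"duplicate {keys} rows in {name}")


def merge_sources(
    yields: pd.DataFrame,
    weather: pd.DataFrame,
    soil: pd.DataFrame,
    planting: pd.DataFrame,
    apsim: pd.DataFrame,
    geography: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Left-join all sources onto the yield table; returns (panel, manifest).

    Soil (keyed by geoid) is replicated across years; planting (keyed by
    state and year) is broadcast to each county of the state through the
    geography table.  Every yield row is preserved.
    """
    if yields.empty:
        raise IntegrityError("yield reference table is empty")
    _check_unique(yields, ["geoid", "year"], "yields")
    _check_unique(weather, ["geoid", "year"], "weather")
    _check_unique(apsim, ["geoid", "year"], "apsim")
    _check_unique(soil, ["geoid"], "soil")
    _check_unique(planting, ["state", "year"], "planting")
    _check_unique(geography, ["geoid"], "geography")

    unmapped = set(yields["geoid"]) - set(geography["geoid"])
    if unmapped:
        raise PanelJoinError(f"counties with no geography mapping: {sorted(unmapped)[:5]}")

    panel = yields.merge(
        geography[["geoid", "state", "crd", "cropland_ratio"]], on="geoid", how="left"
    )
    panel = panel.merge(weather, on=["geoid", "year"], how="left")
    panel = panel.merge(soil, on="geoid", how="left")
    panel = panel.merge(planting, on=["state", "year"], how="left")
    panel = panel.merge(apsim, on=["geoid", "year"], how="left")
    assert len(panel) == len(yields), "merge must be row-conservative"

    manifest: dict[str, dict] = {}
    for col in schema.weather_columns():
        manifest[col] = {"source": "weather", "week": schema.week_of(col)}
    for col in schema.soil_columns():
        manifest[col] = {"source": "soil", "week": None}
    for col in schema.planting_columns():
        manifest[col] = {"source": "planting", "week": schema.week_of(col)}
    for col in schema.APSIM_VARS:
        manifest[col] = {"source": "apsim", "week": None}
    return panel, manifest


def impute_missing(panel: pd.DataFrame, manifest: dict) -> pd.DataFrame:
    """Fill missing planting and crop-model values.

    Planting week-n gaps take the mean of the same state's week-n values over
    the years where they are observed.  Crop-model gaps take the county-level
    median of the variable; counties with no observed value fall back to the
    state median, then the global median (logged).
    """
    panel = panel.copy()
    plant_cols = [c for c, m in manifest.items() if m["source"] == "planting" and c in panel]
    apsim_cols = [c for c, m in manifest.items() if m["source"] == "apsim" and c in panel]

    for col in plant_cols:
        if panel[col].isna().any():
            state_mean = panel.groupby("state")[col].transform("mean")
            panel[col] = panel[col].fillna(state_mean)
            if panel[col].isna().any():
                logger.warning("planting column %s: falling back to global mean", col)
                panel[col] = panel[col].fillna(panel[col].mean())

    for col in apsim_cols:
        if panel[col].isna().any():
            county_med = panel.groupby("geoid")[col].transform("median")
            state_med = panel.groupby("state")[col].transform("median")
            n_state_fallback = int((panel[col].isna() & county_med.isna()).sum())
            if n_state_fallback:
                logger.info(
                    "apsim column %s: %d values imputed from state median",
                    col, n_state_fallback,
                )
            panel[col] = panel[col].fillna(county_med).fillna(state_med)
            if panel[col].isna().any():
                logger.warning("apsim column %s: falling back to global median", col)
                panel[col] = panel[col].fillna(panel[col].median())
    return panel


def add_quarterly_features(
    panel: pd.DataFrame, manifest: dict
) -> tuple[pd.DataFrame, dict]:
    """Append the 20 quarterly weather columns (sums for totals, means for
    temperatures) and extend the manifest."""
    manifest = dict(manifest)
    new_cols = {}
    for q, weeks in QUARTERS.items():
        for var in QUARTER_SUM_VARS + QUARTER_MEAN_VARS:
            weekly = [f"{var}_wk{w}" for w in weeks]
            missing = [c for c in weekly if c not in panel.columns]
            if missing:
                raise IntegrityError(f"weekly columns missing for quarter {q}: {missing[:3]}")
            name = f"{var}_q{q}"
            if var in QUARTER_SUM_VARS:
                new_cols[name] = panel[weekly].sum(axis=1)
            else:
                new_cols[name] = panel[weekly].mean(axis=1)
            manifest[name] = {"source": "quarterly", "week": None}
    out = pd.concat([panel, pd.DataFrame(new_cols, index=panel.index)], axis=1)
    return out, manifest


def fit_trend_models(
    yields: pd.DataFrame, train_years: set[int], geography: pd.DataFrame
) -> pd.DataFrame:
    """Per-county OLS of yield on calendar year over the training years only.

    Counties with fewer than 2 training observations (or a degenerate year
    axis) inherit their state's pooled fit.  Returns a frame with columns
    geoid, b0, b1, n_train, source.
    """
    train = yields[yields["year"].isin(train_years)]
    geo = geography.set_index("geoid")["state"]

    state_fits: dict[str, tuple[float, float]] = {}
    by_state = train.assign(state=train["geoid"].map(geo)).groupby("state")
    for state, grp in by_state:
        if len(grp) >= 2 and grp["year"].nunique() >= 2:
            b1, b0 = np.polyfit(grp["year"], grp[TARGET], 1)
            state_fits[state] = (b0, b1)

    rows = []
    for geoid in geography["geoid"]:
        grp = train[train["geoid"] == geoid]
        if len(grp) >= 2 and grp["year"].nunique() >= 2:
            b1, b0 = np.polyfit(grp["year"], grp[TARGET], 1)
            rows.append({"geoid": geoid, "b0": b0, "b1": b1,
                         "n_train": len(grp), "source": "county"})
        else:
            state = geo.get(geoid)
            if state not in state_fits:
                raise IntegrityError(
                    f"cannot fit trend for county {geoid}: "
                    "insufficient county and state training data"
                )
            logger.info("county %s inherits state %s trend", geoid, state)
            b0, b1 = state_fits[state]
            rows.append({"geoid": geoid, "b0": b0, "b1": b1,
                         "n_train": len(grp), "source": "state"})
    return pd.DataFrame(rows)


def add_trend_feature(
    panel: pd.DataFrame, trend_models: pd.DataFrame, manifest: dict
) -> tuple[pd.DataFrame, dict]:
    """Attach ``yield_trend = b0 + b1 * year`` for every row (any year)."""
    manifest = dict(manifest)
    tm = trend_models.set_index("geoid")
    b0 = panel["geoid"].map(tm["b0"])
    b1 = panel["geoid"].map(tm["b1"])
    if b0.isna().any():
        missing = panel.loc[b0.isna(), "geoid"].unique()
        raise PanelJoinError(f"no trend model for counties: {missing[:5]}")
    out = panel.assign(**{TREND_COLUMN: b0 + b1 * panel["year"]})
    manifest[TREND_COLUMN] = {"source": "trend", "week": None}
    return out, manifest


def compute_trend_feature(
    yields: pd.DataFrame, train_years: set[int], geography: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Convenience wrapper: fit trend models and evaluate the trend for every
    (geoid, year) row of the yield table (including non-training years)."""
    models = fit_trend_models(yields, train_years, geography)
    tm = models.set_index("geoid")
    trend = yields["geoid"].map(tm["b0"]) + yields["geoid"].map(tm["b1"]) * yields["year"]
    return models, trend.rename(TREND_COLUMN)


def feature_columns(panel: pd.DataFrame, manifest: dict) -> list[str]:
    """Manifest-listed columns present in the panel, in panel order."""
    return [c for c in panel.columns if c in manifest]


def write_features(
    panel: pd.DataFrame, manifest: dict, outdir: str | Path
) -> tuple[Path, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fpath = outdir / "features.csv"
    mpath = outdir / "column_manifest.json"
    panel.to_csv(fpath, index=False)
    mpath.write_text(json.dumps(manifest, indent=1))
    return fpath, mpath
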
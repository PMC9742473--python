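"""True-yield model and the correlated crop-simulation output block."""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from . import schema
from .config import ScenarioConfig

#: weeks entering the growing-season weather index
SEASON_WEEKS = range(16, 44)


class JoinError(KeyError):
    """Raised when input tables do not share keys."""


class CropResult(NamedTuple):
    apsim: pd.DataFrame
    yields: pd.DataFrame
    truth: pd.DataFrame  # per-county generative b0, b1, noise sd


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def simulate_crop(
    weather: pd.DataFrame,
    soil: pd.DataFrame,
    planting: pd.DataFrame,
    geography: pd.DataFrame,
    config: ScenarioConfig,
) -> CropResult:
    """Simulate county-year yields and the 37-variable crop-model block.

    yield = b0 + b1*year + weather_effect*z_weather + soil_effect*z_soil
            + N(0, sd) - shock, clipped at 0.  The crop-model AnnualYield
    column (kg/ha) is built to correlate with the final yield at
    ``config.apsim_fidelity``; the remaining 36 variables are plausible
    correlated noise within their documented ranges.
    """
    geo_ids = set(geography["geoid"])
    if set(weather["geoid"]) != geo_ids or set(soil["geoid"]) != geo_ids:
        raise JoinError("weather/soil geoids do not match geography")
    if not set(geography["state"]) <= set(planting["state"]):
        raise JoinError("planting table missing states present in geography")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0B]))
    panel = weather[["geoid", "year"]].copy()
    n = len(panel)

    # per-county generative truth
    counties = geography["geoid"].to_numpy()
    b1 = rng.normal(config.b1_mean, config.b1_sd, size=len(counties))
    level = rng.normal(config.level_mean, config.level_sd, size=len(counties))
    b0 = level - b1 * config.level_ref_year
    noise_mult = np.where(
        geography["cropland_ratio"].to_numpy() < config.cropland_noise_threshold,
        config.cropland_noise_multiplier,
        1.0,
    )
    truth = pd.DataFrame(
        {"geoid": counties, "b0": b0, "b1": b1,
         "noise_sd": config.noise_sd * noise_mult}
    )

    # growing-season weather index: standardized precip + thermal time
    prcp_cols = [f"prcp_wk{w}" for w in SEASON_WEEKS]
    gdd_cols = [f"gdd_wk{w}" for w in SEASON_WEEKS]
    z_weather = 0.5 * (
        _zscore(weather[prcp_cols].sum(axis=1).to_numpy())
        + _zscore(weather[gdd_cols].sum(axis=1).to_numpy())
    )
    z_soil = _zscore(soil.set_index("geoid").loc[panel["geoid"], "om_d1"].to_numpy())

    per_row = truth.set_index("geoid").loc[panel["geoid"]]
    y = (
        per_row["b0"].to_numpy()
        + per_row["b1"].to_numpy() * panel["year"].to_numpy()
        + config.weather_effect * z_weather
        + config.soil_effect * z_soil
        + rng.normal(0.0, 1.0, size=n) * per_row["noise_sd"].to_numpy()
    )

    shock_flag = np.zeros(n, dtype=bool)
    if config.shock_year is not None and config.n_shock_counties > 0:
        if config.n_shock_counties > len(counties):
            raise JoinError("n_shock_counties exceeds county count")
        shocked = rng.choice(counties, size=config.n_shock_counties, replace=False)
        hit = panel["geoid"].isin(shocked).to_numpy() & (
            panel["year"].to_numpy() == config.shock_year
        )
        y = np.where(hit, y - config.shock_magnitude, y)
        shock_flag = hit
    y = np.maximum(y, 0.0)

    yields = panel.assign(yield_mg_ha=y, shock_flag=shock_flag)
    apsim = _simulate_apsim_block(panel, y, config, rng)
    return CropResult(apsim=apsim, yields=yields, truth=truth)


def _simulate_apsim_block(
    panel: pd.DataFrame, y: np.ndarray, config: ScenarioConfig, rng: np.random.Generator
) -> pd.DataFrame:
    n = len(panel)
    fid = config.apsim_fidelity
    mu, sd = y.mean(), y.std()
    eps = rng.normal(0.0, 1.0, size=n)
    z = (y - mu) / sd if sd > 0 else np.zeros(n)
    az = fid * z + np.sqrt(max(1.0 - fid**2, 0.0)) * eps
    annual_yield = np.maximum((mu + sd * az) * 1000.0, 0.0)  # kg/ha

    def beta01(a, b, size=n):
        return rng.beta(a, b, size=size)

    out = {"geoid": panel["geoid"].to_numpy(), "year": panel["year"].to_numpy()}
    out["AnnualYield"] = annual_yield
    out["AnnualBiomass"] = np.maximum(
        2.1 * annual_yield + rng.normal(0, 800, n), 0.0
    )
    out["AnnualRootD"] = np.clip(rng.normal(1500, 150, n), 500, 2500)

    sow = np.clip(rng.normal(120, 7, n), 80, 170)
    flower = np.clip(sow + rng.normal(70, 5, n), None, 330)
    mature = np.clip(flower + rng.normal(55, 5, n), None, 350)
    harvest = np.clip(mature + rng.normal(25, 6, n), None, 366)
    out["DOY_Sowing"] = np.round(sow)
    out["DOY_Flowering"] = np.round(flower)
    out["DOY_Maturity"] = np.round(mature)
    out["DOY_Harvest"] = np.round(harvest)

    out["AnnualLaiMax"] = np.maximum(rng.normal(5.0, 0.7, n) + 0.2 * az, 0.1)
    et = np.maximum(rng.normal(520, 50, n), 100)
    out["AnnualET"] = et
    out["MaizeTranspiration"] = np.clip(0.55 * et + rng.normal(0, 20, n), 0, et)
    nupt = np.maximum(rng.normal(220, 30, n) + 8.0 * az, 20)
    out["AnnualNupt"] = nupt
    out["AnnualGrainlNupt"] = np.clip(0.6 * nupt + rng.normal(0, 10, n), 0, nupt)

    out["AvgDroughtStress"] = beta01(2, 8)
    out["AvgExcessWStress"] = beta01(2, 10)
    out["AvgNStress"] = beta01(2, 12)

    out["AnnualAvgWT"] = np.maximum(rng.normal(1800, 400, n), 0)
    out["AnnualRunoff"] = rng.gamma(2.0, 30.0, n)
    out["AnnualDrainage"] = rng.gamma(2.0, 60.0, n)
    out["AnnualGrossMiner"] = np.maximum(rng.normal(90, 15, n), 0)
    out["AnnualNlossTotal"] = rng.gamma(2.0, 15.0, n)
    out["WTatPlanting"] = np.maximum(rng.normal(1500, 400, n), 0)

    sw_base = beta01(6, 4)
    for var in schema.APSIM_VARS:
        if var.startswith(("SW1m_", "SW15cm_")):
            out[var] = np.clip(sw_base + rng.normal(0, 0.08, n), 0.0, 1.0)
    out["SW45_excess"] = beta01(2, 10)
    out["SW45_deficit"] = beta01(2, 8)

    return pd.DataFrame(out)[["geoid", "year", *schema.APSIM_VARS]]
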
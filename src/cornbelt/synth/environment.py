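"""Weekly weather, layered soil, and state-level planting-progress generators."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from . import schema
from .config import ConfigurationError, ScenarioConfig


def simulate_environment(
    geography: pd.DataFrame, years: range, config: ScenarioConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (weather, soil, planting) tables for the given geography.

    weather: one row per (geoid, year), 293 feature columns.
    soil: one row per geoid, 100 feature columns, static across years.
    planting: one row per (state, year), 52 nondecreasing cumulative columns.
    """
    if geography.empty:
        raise ConfigurationError("geography is empty")
    if len(years) == 0:
        raise ConfigurationError("empty year range")
    weather = _simulate_weather(geography, years, config)
    soil = _simulate_soil(geography, config)
    planting = _simulate_planting(geography, years, config)
    return weather, soil, planting


def _simulate_weather(
    geography: pd.DataFrame, years: range, config: ScenarioConfig
) -> pd.DataFrame:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x3EA]))
    geoids = geography["geoid"].to_numpy()
    n_c, n_y, n_w = len(geoids), len(years), schema.N_WEEKS
    weeks = np.arange(1, n_w + 1)

    # seasonal temperature cycle peaking near week 29 (mid-July)
    season = np.sin(2 * np.pi * (weeks - 16) / n_w)  # (n_w,)
    county_off = rng.normal(0.0, 1.5, size=n_c)[:, None, None]
    year_off = rng.normal(0.0, 1.0, size=(n_c, n_y))[:, :, None]

    tmax = (
        config.tmax_mean
        + config.temp_seasonal_amp * season[None, None, :]
        + county_off
        + year_off
        + rng.normal(0.0, config.temp_sd, size=(n_c, n_y, n_w))
    )
    gap = np.abs(rng.normal(config.tmin_gap_mean, 2.0, size=(n_c, n_y, n_w)))
    tmin = tmax - gap

    # weekly totals, nonnegative by construction
    prcp = rng.gamma(2.0, config.prcp_mean / 2.0, size=(n_c, n_y, n_w))
    rad = np.maximum(
        config.rad_mean
        + 40.0 * season[None, None, :]
        + rng.normal(0.0, 10.0, size=(n_c, n_y, n_w)),
        0.0,
    )
    gdd = np.maximum((tmax + tmin) / 2.0 - config.gdd_base, 0.0) * 7.0
    wet = rng.binomial(7, 0.45, size=(n_c, n_y, len(schema.AUX_WEEKS)))

    blocks = {"rad": rad, "prcp": prcp, "tmin": tmin, "tmax": tmax, "gdd": gdd}
    data = {
        "geoid": np.repeat(geoids, n_y),
        "year": np.tile(np.asarray(years), n_c),
    }
    for var in schema.WEATHER_VARS:
        arr = blocks[var].reshape(n_c * n_y, n_w)
        for w in weeks:
            data[f"{var}_wk{w}"] = arr[:, w - 1]
    wet2 = wet.reshape(n_c * n_y, -1).astype(float)
    for j, w in enumerate(schema.AUX_WEEKS):
        data[f"{schema.AUX_VAR}_wk{w}"] = wet2[:, j]
    return pd.DataFrame(data)


def _simulate_soil(geography: pd.DataFrame, config: ScenarioConfig) -> pd.DataFrame:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5011]))
    n_c = len(geography)
    n_d = schema.N_SOIL_LAYERS
    depth_decay = np.exp(-0.15 * np.arange(n_d))  # properties attenuate with depth

    sand = np.clip(rng.normal(35, 12, (n_c, 1)) + rng.normal(0, 3, (n_c, n_d)), 2, 90)
    clay = np.clip(rng.normal(25, 8, (n_c, 1)) + rng.normal(0, 2, (n_c, n_d)), 2, 60)
    over = sand + clay
    scale = np.where(over > 98.0, 98.0 / over, 1.0)  # texture closure
    sand, clay = sand * scale, clay * scale

    om = np.clip(rng.normal(3.5, 1.0, (n_c, 1)) * depth_decay + rng.normal(0, 0.2, (n_c, n_d)), 0.05, None)
    ph = np.clip(rng.normal(6.3, 0.5, (n_c, 1)) + rng.normal(0, 0.1, (n_c, n_d)), 4.5, 8.5)
    bd = np.clip(rng.normal(1.35, 0.1, (n_c, 1)) + 0.02 * np.arange(n_d), 1.0, 1.8)

    # water retention ordering: wp <= fc <= sat
    sat = np.clip(rng.normal(0.48, 0.03, (n_c, n_d)), 0.35, 0.60)
    fc = sat * np.clip(rng.beta(8, 3, (n_c, n_d)), 0.4, 0.95)
    wp = fc * np.clip(rng.beta(5, 5, (n_c, n_d)), 0.1, 0.9)
    paw = fc - wp
    ksat = np.clip(rng.lognormal(2.5, 0.6, (n_c, n_d)), 0.1, None)

    arrays = {
        "om": om, "sand": sand, "clay": clay, "ph": ph, "bd": bd,
        "wp": wp, "fc": fc, "sat": sat, "ksat": ksat, "paw": paw,
    }
    data = {"geoid": geography["geoid"].to_numpy()}
    for prop in schema.SOIL_PROPS:
        for d in range(1, n_d + 1):
            data[f"{prop}_d{d}"] = arrays[prop][:, d - 1]
    return pd.DataFrame(data)


def _simulate_planting(
    geography: pd.DataFrame, years: range, config: ScenarioConfig
) -> pd.DataFrame:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x91A]))
    states = geography["state"].drop_duplicates().to_numpy()
    n_s, n_y = len(states), len(years)
    weeks = np.arange(1, schema.N_WEEKS + 1)

    # logistic ramp: planting mostly happens weeks ~15-25
    midpoint = rng.normal(19.0, 1.5, size=(n_s, n_y, 1))
    steep = np.abs(rng.normal(0.9, 0.15, size=(n_s, n_y, 1))) + 0.2
    curve = 100.0 * expit(steep * (weeks[None, None, :] - midpoint))
    curve = np.maximum.accumulate(curve, axis=2)  # guard against float wiggle
    curve = np.clip(curve, 0.0, 100.0)

    data = {
        "state": np.repeat(states, n_y),
        "year": np.tile(np.asarray(years), n_s),
    }
    flat = curve.reshape(n_s * n_y, -1)
    for w in weeks:
        data[f"plant_wk{w}"] = flat[:, w - 1]
    return pd.DataFrame(data)
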
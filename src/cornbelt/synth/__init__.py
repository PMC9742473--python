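"""Synthetic county x year panel generator emulating the Corn Belt data stack."""

from __future__ import annotations

from typing import NamedTuple

import pandas as pd

from . import schema
from .config import ConfigurationError, ScenarioConfig
from .crop import CropResult, JoinError, simulate_crop
from .environment import simulate_environment
from .geography import build_geography
from .io import read_tables, write_tables
from .missingness import inject_missingness

__all__ = [
    "ScenarioConfig",
    "ConfigurationError",
    "JoinError",
    "ScenarioData",
    "build_geography",
    "simulate_environment",
    "simulate_crop",
    "inject_missingness",
    "generate_scenario",
    "read_tables",
    "write_tables",
    "schema",
]


class ScenarioData(NamedTuple):
    """The six tables of a generated scenario plus the generative truth."""

    geography: pd.DataFrame
    weather: pd.DataFrame
    soil: pd.DataFrame
    planting: pd.DataFrame
    apsim: pd.DataFrame
    yields: pd.DataFrame
    truth: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "geography": self.geography,
            "weather": self.weather,
            "soil": self.soil,
            "planting": self.planting,
            "apsim": self.apsim,
            "yields": self.yields,
        }


def generate_scenario(config: ScenarioConfig, missingness: bool = True) -> ScenarioData:
    """Run the full generator chain under the scenario seed."""
    geography = build_geography(config)
    weather, soil, planting = simulate_environment(geography, config.years, config)
    result: CropResult = simulate_crop(weather, soil, planting, geography, config)
    apsim, yields = result.apsim, result.yields
    if missingness:
        planting, apsim = inject_missingness(planting, apsim, config, geography)
    return ScenarioData(
        geography=geography,
        weather=weather,
        soil=soil,
        planting=planting,
        apsim=apsim,
        yields=yields,
        truth=result.truth,
    )
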
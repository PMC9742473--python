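"""Structured missingness: pre-cutoff planting gaps and random crop-model gaps."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import schema
from .config import ConfigurationError, ScenarioConfig


def inject_missingness(
    planting: pd.DataFrame,
    apsim: pd.DataFrame,
    config: ScenarioConfig,
    geography: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Blank the designated state's planting rows before the cutoff year and
    a random fraction of crop-model rows.  Yields are never blanked.

    Returns new (planting, apsim) frames; inputs are not mutated.
    """
    if not 0.0 <= config.apsim_missing_rate <= 1.0:
        raise ConfigurationError("apsim_missing_rate must lie in [0, 1]")

    planting = planting.copy()
    states = geography["state"].drop_duplicates().to_numpy()
    if not 0 <= config.planting_missing_state_index < len(states):
        raise ConfigurationError("planting_missing_state_index out of range")
    target_state = states[config.planting_missing_state_index]
    mask = (planting["state"] == target_state) & (
        planting["year"] < config.planting_missing_cutoff_year
    )
    planting.loc[mask, schema.planting_columns()] = np.nan

    apsim = apsim.copy()
    if config.apsim_missing_rate > 0:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x315]))
        blank = rng.random(len(apsim)) < config.apsim_missing_rate
        apsim.loc[blank, list(schema.APSIM_VARS)] = np.nan

    return planting, apsim
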
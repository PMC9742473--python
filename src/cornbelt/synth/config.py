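"""Scenario configuration for the synthetic Corn Belt panel generator."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


class ConfigurationError(ValueError):
    """Raised when a scenario configuration violates its invariants."""


@dataclass
class ScenarioConfig:
    """All knobs of the synthetic scenario; ``seed`` fixes every draw.

    The yield model is
    ``yield = b0 + b1 * year + weather_effect * z_weather
      + soil_effect * z_soil + noise - shock``
    with ``b0`` parameterized through the county's expected level at
    ``level_ref_year`` (``b0 = level - b1 * level_ref_year``) so that draws
    stay on a realistic Mg/ha scale for any year range.
    """

    # geography
    n_states: int = 12
    n_crds_per_state: int = 2
    n_counties_per_crd: int = 3
    cropland_beta_a: float = 4.0
    cropland_beta_b: float = 2.0

    # panel years
    year_start: int = 1984
    year_end: int = 2020

    # yield trend (Mg/ha and Mg/ha/year)
    b1_mean: float = 0.10
    b1_sd: float = 0.02
    level_mean: float = 8.0
    level_sd: float = 1.0
    level_ref_year: int = 2000

    # climate (deg C, mm/week, MJ/m2/week); weekly values follow a seasonal
    # sinusoid around these annual means with county and year offsets
    tmax_mean: float = 16.0
    tmin_gap_mean: float = 10.0
    temp_seasonal_amp: float = 14.0
    temp_sd: float = 2.0
    prcp_mean: float = 18.0
    rad_mean: float = 90.0
    gdd_base: float = 10.0

    # effect sizes and noise
    weather_effect: float = 0.4
    soil_effect: float = 0.2
    noise_sd: float = 0.5

    # heteroscedasticity hook: counties with cropland_ratio below the
    # threshold get their noise SD multiplied (1.0 disables)
    cropland_noise_threshold: float = 0.0
    cropland_noise_multiplier: float = 1.0

    # crop-simulation block
    apsim_fidelity: float = 0.8

    # structured missingness
    planting_missing_state_index: int = 0
    planting_missing_cutoff_year: int = 2000
    apsim_missing_rate: float = 0.05

    # shock (windstorm-style yield loss in a county subset)
    shock_year: int | None = 2020
    n_shock_counties: int = 27
    shock_magnitude: float = 3.0

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if min(self.n_states, self.n_crds_per_state, self.n_counties_per_crd) < 1:
            raise ConfigurationError("geography counts must all be >= 1")
        if self.year_end < self.year_start:
            raise ConfigurationError("empty year range")
        for name in ("b1_sd", "level_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.apsim_fidelity <= 1.0:
            raise ConfigurationError("apsim_fidelity must lie in [0, 1]")
        if not 0.0 <= self.apsim_missing_rate <= 1.0:
            raise ConfigurationError("apsim_missing_rate must lie in [0, 1]")
        if self.cropland_noise_multiplier < 0:
            raise ConfigurationError("cropland_noise_multiplier must be >= 0")
        if self.n_shock_counties < 0:
            raise ConfigurationError("n_shock_counties must be >= 0")

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)

    @property
    def n_counties(self) -> int:
        return self.n_states * self.n_crds_per_state * self.n_counties_per_crd

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown scenario fields: {sorted(unknown)}")
        return cls(**raw)

    def replace(self, **kwargs) -> "ScenarioConfig":
        d = asdict(self)
        d.update(kwargs)
        return ScenarioConfig(**d)
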
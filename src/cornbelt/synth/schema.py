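"""Column-name schemas shared by the generators and the preprocessing layer.

All panel tables are keyed by ``geoid`` (5-character, zero-padded county
identifier, stored as text) and, where applicable, ``year``.
"""

from __future__ import annotations

N_WEEKS = 52

#: Base weekly weather variables (one column per variable per week).
WEATHER_VARS = ("rad", "prcp", "tmin", "tmax", "gdd")

#: Auxiliary weekly variable covering the tail of the season only
#: (weeks 20..52 -> 33 columns, bringing the weather block to 293).
AUX_VAR = "wetdays"
AUX_WEEKS = tuple(range(20, N_WEEKS + 1))

#: Ten soil properties reported at ten profile depths (10 x 10 = 100 columns).
SOIL_PROPS = (
    "om",  # organic matter, %
    "sand",  # sand content, %
    "clay",  # clay content, %
    "ph",
    "bd",  # bulk density, g/cm3
    "wp",  # wilting point, volumetric
    "fc",  # field capacity, volumetric
    "sat",  # saturation point, volumetric
    "ksat",  # saturated hydraulic conductivity, mm/h
    "paw",  # plant-available water capacity, volumetric
)
N_SOIL_LAYERS = 10

#: The 37 crop-simulation output variables, with their unit conventions.
APSIM_VARS = (
    "AnnualYield",  # kg/ha
    "AnnualBiomass",  # kg/ha
    "AnnualRootD",  # mm
    "DOY_Flowering",
    "DOY_Maturity",
    "AnnualLaiMax",  # m2/m2
    "AnnualET",  # mm
    "MaizeTranspiration",  # mm
    "AnnualNupt",  # kg N/ha
    "AnnualGrainlNupt",  # kg N/ha
    "AvgDroughtStress",  # 0-1
    "AvgExcessWStress",  # 0-1
    "AvgNStress",  # 0-1
    "AnnualAvgWT",  # mm
    "AnnualRunoff",  # mm
    "AnnualDrainage",  # mm
    "AnnualGrossMiner",  # kg N/ha
    "AnnualNlossTotal",  # kg N/ha
    "DOY_Sowing",
    "DOY_Harvest",
    "SW1m_Apr",
    "SW1m_May",
    "SW1m_Jun",
    "SW1m_Jul",
    "SW1m_Aug",
    "SW1m_Sep",
    "SW1m_Oct",
    "SW15cm_Apr",
    "SW15cm_May",
    "SW15cm_Jun",
    "SW15cm_Jul",
    "SW15cm_Aug",
    "SW15cm_Sep",
    "SW15cm_Oct",
    "WTatPlanting",  # mm
    "SW45_excess",  # 0-1
    "SW45_deficit",  # 0-1
)

#: Subsets of APSIM_VARS constrained to [0, 1].
APSIM_UNIT_INTERVAL = tuple(
    v
    for v in APSIM_VARS
    if v.startswith(("Avg", "SW1m_", "SW15cm_", "SW45_"))
)

#: Subsets of APSIM_VARS constrained to day-of-year range [1, 366].
APSIM_DOY = tuple(v for v in APSIM_VARS if v.startswith("DOY_"))


def weather_columns() -> list[str]:
    """Names of the 293 weekly weather feature columns, in schema order."""
    cols = [f"{v}_wk{w}" for v in WEATHER_VARS for w in range(1, N_WEEKS + 1)]
    cols += [f"{AUX_VAR}_wk{w}" for w in AUX_WEEKS]
    return cols


def soil_columns() -> list[str]:
    """Names of the 100 soil feature columns (property x depth layer)."""
    return [f"{p}_d{d}" for p in SOIL_PROPS for d in range(1, N_SOIL_LAYERS + 1)]


def planting_columns() -> list[str]:
    """Names of the 52 weekly cumulative planting-progress columns."""
    return [f"plant_wk{w}" for w in range(1, N_WEEKS + 1)]


def week_of(column: str) -> int | None:
    """Extract the 1-based week number from a weekly column name, else None."""
    if "_wk" not in column:
        return None
    tail = column.rsplit("_wk", 1)[1]
    return int(tail) if tail.isdigit() else None


N_WEATHER_COLUMNS = len(weather_columns())
N_SOIL_COLUMNS = len(soil_columns())
N_PLANTING_COLUMNS = len(planting_columns())
N_APSIM_COLUMNS = len(APSIM_VARS)
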
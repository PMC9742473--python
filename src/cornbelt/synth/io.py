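"""CSV writers/readers for the six scenario tables.

geoid is always written and re-read as text so leading zeros survive the
round trip.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

TABLE_FILES = {
    "geography": "geography.csv",
    "weather": "weather.csv",
    "soil": "soil.csv",
    "planting": "planting.csv",
    "apsim": "apsim.csv",
    "yields": "yield.csv",
}

_STR_COLS = {"geoid": str, "state": str, "crd": str}


def write_tables(tables: dict[str, pd.DataFrame], outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, fname in TABLE_FILES.items():
        if name not in tables:
            continue
        path = outdir / fname
        tables[name].to_csv(path, index=False)
        paths[name] = path
    return paths


def read_tables(indir: str | Path) -> dict[str, pd.DataFrame]:
    indir = Path(indir)
    tables = {}
    for name, fname in TABLE_FILES.items():
        path = indir / fname
        if path.exists():
            tables[name] = pd.read_csv(path, dtype=_STR_COLS)
    return tables
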
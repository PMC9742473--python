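"""State -> CRD -> county hierarchy with cropland ratios."""

from __future__ import annotations

import itertools
import string

import numpy as np
import pandas as pd

from .config import ScenarioConfig


def _state_codes(n: int) -> list[str]:
    """Deterministic 2-letter state codes: AA, AB, AC, ..."""
    letters = string.ascii_uppercase
    codes = ["".join(p) for p in itertools.product(letters, repeat=2)]
    if n > len(codes):
        raise ValueError("too many states for 2-letter codes")
    return codes[:n]


def build_geography(config: ScenarioConfig) -> pd.DataFrame:
    """Build the county table: geoid, state, crd, cropland_ratio.

    geoids are 5-character zero-padded strings (2-digit state prefix +
    3-digit county counter), unique by construction. cropland_ratio is
    drawn from Beta(a, b), independently per county, under the scenario seed.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x6E0]))
    states = _state_codes(config.n_states)

    rows = []
    for si, state in enumerate(states):
        county_no = 0
        for ci in range(config.n_crds_per_state):
            crd = f"{state}-{ci + 1:02d}"
            for _ in range(config.n_counties_per_crd):
                county_no += 1
                rows.append(
                    {
                        "geoid": f"{si + 1:02d}{county_no:03d}",
                        "state": state,
                        "crd": crd,
                    }
                )
    geo = pd.DataFrame(rows)
    geo["cropland_ratio"] = rng.beta(
        config.cropland_beta_a, config.cropland_beta_b, size=len(geo)
    )
    return geo
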
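import pandas as pd
import pytest

from cornbelt import preprocess
from cornbelt.synth import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def small_config() -> ScenarioConfig:
    """3 states x 2 CRDs x 2 counties, 21 years: fast but structurally full."""
    return ScenarioConfig(
        n_states=3,
        n_crds_per_state=2,
        n_counties_per_crd=2,
        year_start=2000,
        year_end=2020,
        n_shock_counties=4,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_data(small_config):
    return generate_scenario(small_config)


@pytest.fixture(scope="session")
def default_config() -> ScenarioConfig:
    """The documented default panel: 12 states x 2 CRDs x 3 counties, 1984-2020."""
    return ScenarioConfig()


@pytest.fixture(scope="session")
def default_data(default_config):
    return generate_scenario(default_config)


@pytest.fixture(scope="session")
def small_panel(small_data):
    """Merged + imputed + quarterly panel for the small scenario."""
    panel, manifest = preprocess.merge_sources(
        small_data.yields,
        small_data.weather,
        small_data.soil,
        small_data.planting,
        small_data.apsim,
        small_data.geography,
    )
    panel = preprocess.impute_missing(panel, manifest)
    panel, manifest = preprocess.add_quarterly_features(panel, manifest)
    return panel, manifest


@pytest.fixture(scope="session")
def default_panel(default_data):
    panel, manifest = preprocess.merge_sources(
        default_data.yields,
        default_data.weather,
        default_data.soil,
        default_data.planting,
        default_data.apsim,
        default_data.geography,
    )
    panel = preprocess.impute_missing(panel, manifest)
    panel, manifest = preprocess.add_quarterly_features(panel, manifest)
    return panel, manifest


def tiny_prediction_frame(P, y):
    """Wrap raw arrays as a prediction-matrix frame."""
    df = pd.DataFrame(P, columns=[f"m{j + 1}" for j in range(P.shape[1])])
    df.insert(0, "y_true", y)
    df.insert(0, "year", 2020)
    df.insert(0, "geoid", [f"{i:05d}" for i in range(len(y))])
    df.attrs["models"] = [f"m{j + 1}" for j in range(P.shape[1])]
    return df
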
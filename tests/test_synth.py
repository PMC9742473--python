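import numpy as np
import pandas as pd
import pytest

from cornbelt.synth import (
    ConfigurationError,
    ScenarioConfig,
    build_geography,
    generate_scenario,
    inject_missingness,
    read_tables,
    schema,
    simulate_crop,
    simulate_environment,
    write_tables,
)


class TestGeography:
    def test_row_count_is_product_of_counts(self):
        cfg = ScenarioConfig(n_states=2, n_crds_per_state=2, n_counties_per_crd=3)
        geo = build_geography(cfg)
        assert len(geo) == 12
        assert geo["geoid"].nunique() == 12

    def test_hierarchy_membership(self, small_data):
        geo = small_data.geography
        # every county belongs to exactly one CRD and one state
        assert geo.groupby("geoid")[["state", "crd"]].nunique().eq(1).all().all()
        # CRD ids nest inside their state
        assert (geo["crd"].str.split("-").str[0] == geo["state"]).all()

    def test_determinism(self, small_config):
        a = build_geography(small_config)
        b = build_geography(small_config)
        pd.testing.assert_frame_equal(a, b)

    def test_cropland_ratio_bounds(self, small_data):
        r = small_data.geography["cropland_ratio"]
        assert ((r >= 0) & (r <= 1)).all()

    def test_cropland_mean_matches_beta(self):
        # Monte-Carlo check against the configured Beta(a, b) distribution
        a, b = 4.0, 2.0
        cfg = ScenarioConfig(
            n_states=10, n_crds_per_state=10, n_counties_per_crd=100,
            cropland_beta_a=a, cropland_beta_b=b, seed=7,
        )
        geo = build_geography(cfg)
        n = len(geo)
        assert n == 10_000
        mean = a / (a + b)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        se = np.sqrt(var / n)
        assert abs(geo["cropland_ratio"].mean() - mean) < 3 * se

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            ScenarioConfig(n_states=0)


class TestEnvironment:
    def test_weather_has_293_feature_columns(self, small_data):
        feats = [c for c in small_data.weather.columns if c not in ("geoid", "year")]
        assert len(feats) == 293

    def test_weather_row_per_county_year(self, small_config, small_data):
        assert len(small_data.weather) == small_config.n_counties * len(small_config.years)

    def test_physical_invariants(self, small_data):
        w = small_data.weather
        for week in range(1, 53):
            assert (w[f"tmax_wk{week}"] >= w[f"tmin_wk{week}"]).all()
            for var in ("prcp", "rad", "gdd"):
                assert (w[f"{var}_wk{week}"] >= 0).all()

    def test_tmax_mean_matches_climate_config(self):
        cfg = ScenarioConfig(n_states=6, n_crds_per_state=2, n_counties_per_crd=5,
                             tmax_mean=16.0, seed=3)
        geo = build_geography(cfg)
        weather, _, _ = simulate_environment(geo, cfg.years, cfg)
        cols = [f"tmax_wk{w}" for w in range(1, 53)]
        county_means = weather.groupby("geoid")[cols].mean().mean(axis=1)
        se = county_means.std(ddof=1) / np.sqrt(len(county_means))
        assert abs(county_means.mean() - cfg.tmax_mean) < 3 * se

    def test_soil_schema_and_invariants(self, small_config, small_data):
        soil = small_data.soil
        assert len(soil) == small_config.n_counties
        assert len([c for c in soil.columns if c != "geoid"]) == 100
        for d in range(1, 11):
            assert (soil[f"sand_d{d}"] + soil[f"clay_d{d}"] <= 100).all()
            assert (soil[f"wp_d{d}"] <= soil[f"fc_d{d}"]).all()
            assert (soil[f"fc_d{d}"] <= soil[f"sat_d{d}"]).all()

    def test_planting_monotone_and_bounded(self, small_data):
        p = small_data.planting
        cols = schema.planting_columns()
        assert len(cols) == 52
        vals = p[cols].to_numpy()
        finite = ~np.isnan(vals).any(axis=1)
        assert (np.diff(vals[finite], axis=1) >= 0).all()
        assert (vals[finite] >= 0).all() and (vals[finite] <= 100).all()
        assert (p[cols[51]].dropna() >= p[cols[11]].dropna()).all()

    def test_empty_year_range_rejected(self, small_config):
        geo = build_geography(small_config)
        with pytest.raises(ConfigurationError):
            simulate_environment(geo, range(2020, 2020), small_config)

    def test_empty_geography_rejected(self, small_config):
        empty = build_geography(small_config).iloc[:0]
        with pytest.raises(ConfigurationError):
            simulate_environment(empty, small_config.years, small_config)


class TestCrop:
    def test_apsim_schema(self, small_data):
        apsim = small_data.apsim
        feats = [c for c in apsim.columns if c not in ("geoid", "year")]
        assert feats == list(schema.APSIM_VARS)
        assert len(feats) == 37

    def test_apsim_range_invariants(self, small_data):
        ap = small_data.apsim.dropna()
        for var in schema.APSIM_UNIT_INTERVAL:
            assert ap[var].between(0, 1).all(), var
        for var in schema.APSIM_DOY:
            assert ap[var].between(1, 366).all(), var
        assert (ap["AnnualYield"] >= 0).all()

    def test_yield_nonnegative(self, small_data):
        assert (small_data.yields["yield_mg_ha"] >= 0).all()

    def test_perfect_fidelity_zero_noise_gives_unit_correlation(self):
        cfg = ScenarioConfig(
            n_states=2, n_crds_per_state=2, n_counties_per_crd=3,
            apsim_fidelity=1.0, noise_sd=0.0, n_shock_counties=0,
            apsim_missing_rate=0.0,
        )
        data = generate_scenario(cfg)
        r = np.corrcoef(data.apsim["AnnualYield"] / 1000.0,
                        data.yields["yield_mg_ha"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_default_shock_count_is_27(self, default_data, default_config):
        y = default_data.yields
        shocked = y[y["shock_flag"]]
        assert len(shocked) == 27
        assert (shocked["year"] == default_config.shock_year).all()

    def test_trend_slope_recovery_within_3_se(self):
        # OLS sampling-distribution oracle: se(b1) = sd / sqrt(sum (x-xbar)^2)
        cfg = ScenarioConfig(
            n_states=2, n_crds_per_state=1, n_counties_per_crd=2,
            noise_sd=0.5, weather_effect=0.0, soil_effect=0.0,
            n_shock_counties=0, seed=11,
        )
        data = generate_scenario(cfg)
        years = np.asarray(list(cfg.years), dtype=float)
        se_b1 = cfg.noise_sd / np.sqrt(np.sum((years - years.mean()) ** 2))
        truth = data.truth.set_index("geoid")
        for geoid, grp in data.yields.groupby("geoid"):
            b1_hat, _ = np.polyfit(grp["year"], grp["yield_mg_ha"], 1)
            assert abs(b1_hat - truth.loc[geoid, "b1"]) < 3 * se_b1

    def test_noise_free_trend_recovery_exact(self):
        cfg = ScenarioConfig(
            n_states=2, n_crds_per_state=1, n_counties_per_crd=2,
            noise_sd=0.0, weather_effect=0.0, soil_effect=0.0,
            n_shock_counties=0,
        )
        data = generate_scenario(cfg)
        truth = data.truth.set_index("geoid")
        for geoid, grp in data.yields.groupby("geoid"):
            b1_hat, b0_hat = np.polyfit(grp["year"], grp["yield_mg_ha"], 1)
            assert b0_hat == pytest.approx(truth.loc[geoid, "b0"], abs=1e-6)
            assert b1_hat == pytest.approx(truth.loc[geoid, "b1"], abs=1e-9)


class TestMissingness:
    def test_designated_state_missing_years(self, small_config, small_data):
        # cutoff 2000 on years 2000-2020 leaves nothing missing; use 2005
        cfg = small_config.replace(planting_missing_cutoff_year=2005, seed=1)
        data = generate_scenario(cfg)
        states = data.geography["state"].drop_duplicates().to_numpy()
        target = states[cfg.planting_missing_state_index]
        rows = data.planting[data.planting["state"] == target]
        missing_years = rows[rows["plant_wk20"].isna()]["year"]
        assert sorted(missing_years) == list(range(2000, 2005))

    def test_cutoff_2000_gives_16_missing_years_on_default_panel(self, default_data):
        states = default_data.geography["state"].drop_duplicates().to_numpy()
        target = states[0]
        rows = default_data.planting[default_data.planting["state"] == target]
        assert rows["plant_wk1"].isna().sum() == 16  # 1984..1999 inclusive

    def test_rate_zero_is_identity(self, small_config, small_data):
        cfg = small_config.replace(apsim_missing_rate=0.0)
        _, apsim = inject_missingness(
            small_data.planting, small_data.apsim, cfg, small_data.geography
        )
        clean = small_data.apsim
        pd.testing.assert_frame_equal(apsim, clean)

    def test_blank_fraction_binomial_interval(self):
        cfg = ScenarioConfig(
            n_states=12, n_crds_per_state=3, n_counties_per_crd=8,
            apsim_missing_rate=0.1, seed=5,
        )
        data = generate_scenario(cfg)
        n = len(data.apsim)
        assert n >= 10_000
        frac = data.apsim["AnnualYield"].isna().mean()
        assert 0.08 <= frac <= 0.12

    def test_yields_never_blanked(self, small_data):
        assert not small_data.yields["yield_mg_ha"].isna().any()

    def test_rate_out_of_range_rejected(self, small_config):
        with pytest.raises(ConfigurationError):
            small_config.replace(apsim_missing_rate=1.5)


class TestDeterminismAndIO:
    def test_full_scenario_bit_identical(self, small_config):
        a = generate_scenario(small_config)
        b = generate_scenario(small_config)
        for ta, tb in zip(a, b):
            pd.testing.assert_frame_equal(ta, tb)

    def test_csv_round_trip_preserves_geoid_text(self, small_data, tmp_path):
        write_tables(small_data.tables(), tmp_path)
        back = read_tables(tmp_path)
        assert back["geography"]["geoid"].tolist() == small_data.geography["geoid"].tolist()
        assert back["geography"]["geoid"].str.len().eq(5).all()
        pd.testing.assert_frame_equal(
            back["weather"], small_data.weather, check_exact=False, rtol=1e-12
        )

    def test_scenario_yaml_round_trip(self, small_config, tmp_path):
        path = tmp_path / "scenario.yaml"
        small_config.to_yaml(path)
        assert ScenarioConfig.from_yaml(path) == small_config
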
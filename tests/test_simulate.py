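import numpy as np
import pandas as pd
import pytest

import heatlag as hl
from heatlag.simulate import (
    SimulationConfig,
    simulate_encounters,
    simulate_study,
    simulate_temperature,
    true_cumulative_log_or,
    write_station_csv,
)


ONE_YEAR = SimulationConfig(years=(2005,), baseline_daily={"18-25": 30.0})


class TestTemperature:
    def test_same_seed_identical_series(self):
        a = simulate_temperature(ONE_YEAR, 7)
        b = simulate_temperature(ONE_YEAR, 7)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_no_noise_limit_is_deterministic_sinusoid(self):
        # a target SD at (or below) the sinusoid's own spread leaves no
        # room for noise: repeated seeds give the same smooth series
        cfg = ONE_YEAR.replace(season_sd_f=1e-6, seasonal_amplitude_f=4.0)
        a = simulate_temperature(cfg, 1).frame["tmin_f"].dropna()
        b = simulate_temperature(cfg, 2).frame["tmin_f"].dropna()
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())
        # smoothness: day-to-day changes bounded by the sinusoid slope
        assert np.abs(np.diff(a.to_numpy())).max() < 0.1

    def test_warm_season_moments_match_config(self):
        # 200 simulated seasons pooled (as the multi-year observed summary
        # would be computed); pooled mean/SD within 3 Monte-Carlo standard
        # errors of the configured 67.9 / 5.4.  Pooling across independent
        # seasons avoids the short-window downward bias of the sample SD
        # under strong day-to-day autocorrelation.
        season_vals = []
        for seed in range(200):
            s = simulate_temperature(ONE_YEAR, seed)
            jja = s.frame.loc[s.frame.index.month.isin([6, 7, 8]), "tmin_f"]
            season_vals.append(jja.to_numpy())
        means = np.array([v.mean() for v in season_vals])
        pooled_mean = means.mean()
        se_mean = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(pooled_mean - 67.9) < 3 * se_mean
        # per-season mean squared deviation from the pooled mean
        d = np.array([((v - pooled_mean) ** 2).mean() for v in season_vals])
        pooled_sd = np.sqrt(d.mean())
        se_sd = d.std(ddof=1) / np.sqrt(len(d)) / (2 * pooled_sd)
        assert abs(pooled_sd - 5.4) < 3 * se_sd

    def test_range_within_physical_clip(self):
        s = simulate_temperature(ONE_YEAR.replace(physical_range_f=(50.0, 83.0)), 3)
        t = s.frame["tmin_f"].dropna()
        assert t.min() >= 50.0 and t.max() <= 83.0

    def test_invalid_ar_coefficient(self):
        with pytest.raises(ValueError):
            SimulationConfig(ar1_rho=1.0)


class TestEncounters:
    def test_same_seed_identical_line_list(self):
        exp = simulate_temperature(ONE_YEAR, 5)
        a = simulate_encounters(ONE_YEAR, exp, 6)
        b = simulate_encounters(ONE_YEAR, exp, 6)
        assert a == b

    def test_null_effect_counts_independent_of_temperature(self):
        # ~10,000 days of null-effect counts: sample correlation with Tmin
        # within +-3/sqrt(n) of zero
        cfg = SimulationConfig(
            years=tuple(range(1900, 2009)), baseline_daily={"18-25": 10.0},
            lag_weights=(0.0,) * 6, dow_log_effects=(0.0,) * 7,
            month_log_effects={6: 0.0, 7: 0.0, 8: 0.0}, year_log_slope=0.0,
        )
        exp = simulate_temperature(cfg, 11)
        recs = simulate_encounters(cfg, exp, 12)
        days = exp.frame.index[exp.frame.index.month.isin([6, 7, 8])]
        counts = pd.Series(0, index=days, dtype=float)
        vc = pd.Series([r.admit_date for r in recs]).value_counts()
        vc.index = pd.DatetimeIndex(vc.index)
        counts.loc[vc.index] = vc.to_numpy(dtype=float)
        r = np.corrcoef(counts.to_numpy(), exp.frame.loc[days, "tmin_f"])[0, 1]
        assert abs(r) < 3 / np.sqrt(len(days))

    def test_null_mean_count_matches_baseline(self):
        cfg = SimulationConfig(
            years=(2005, 2006), baseline_daily={"18-25": 20.0},
            lag_weights=(0.0,) * 6, dow_log_effects=(0.0,) * 7,
            month_log_effects={6: 0.0, 7: 0.0, 8: 0.0}, year_log_slope=0.0,
        )
        exp = simulate_temperature(cfg, 21)
        recs = simulate_encounters(cfg, exp, 22)
        n_days = 2 * 92
        mean = len(recs) / n_days
        se = np.sqrt(20.0 / n_days)
        assert abs(mean - 20.0) < 3 * se

    def test_all_encounters_are_cases_in_window(self):
        study = simulate_study(ONE_YEAR, 31)
        kept, att = hl.apply_cohort_filters(study.encounters, years=(2005, 2005))
        assert sum(att.values()) == 0
        assert len(kept) == len(study.encounters)

    def test_mixture_proportions_validated(self):
        with pytest.raises(ValueError):
            SimulationConfig(sex_mix={"male": 0.7, "female": 0.4})


class TestTruth:
    def test_null_contrast_at_reference(self):
        assert true_cumulative_log_or(ONE_YEAR, 72.0, 72.0) == 0.0

    def test_quadratic_minimized_at_vertex(self):
        cfg = ONE_YEAR
        v = cfg.response_vertex_f
        vals = [true_cumulative_log_or(cfg, t, v) for t in (v - 5, v - 1, v, v + 1, v + 5)]
        assert vals[2] == 0.0 and min(vals) == vals[2]

    def test_hand_polynomial_value(self):
        cfg = ONE_YEAR.replace(
            response_curvature=0.004, response_vertex_f=69.0,
            lag_weights=(1.0,) * 6,
        )
        assert true_cumulative_log_or(cfg, 76.0, 69.0) == pytest.approx(
            6 * 0.004 * (76 - 69) ** 2
        )


class TestStudyAndExport:
    def test_study_reproducible_from_seed(self):
        a = simulate_study(ONE_YEAR, 9)
        b = simulate_study(ONE_YEAR, 9)
        assert a.encounters == b.encounters
        pd.testing.assert_frame_equal(a.exposure.frame, b.exposure.frame)

    def test_station_export_averages_back_to_city_series(self, tmp_path):
        study = simulate_study(ONE_YEAR, 13)
        path = tmp_path / "stations.csv"
        write_station_csv(study.exposure, path, seed=13)
        stations = hl.StationSeries.read_csv(path)
        assert len(stations) == 4
        city = hl.average_stations(stations)
        orig = study.exposure.frame["tmin_f"].dropna()
        np.testing.assert_allclose(
            city.frame.loc[orig.index, "tmin_f"], orig, atol=5e-4
        )

    def test_truth_json_round_trip(self, tmp_path):
        import json

        study = simulate_study(ONE_YEAR, 17)
        study.write_truth(tmp_path / "truth.json")
        doc = json.loads((tmp_path / "truth.json").read_text())
        assert doc["seed"] == 17
        assert doc["config"]["season_mean_f"] == pytest.approx(67.9)
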
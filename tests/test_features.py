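import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from volleymine.features import (
    POSITION_COLUMNS,
    build_feature_matrix,
    daily_series,
    feature_columns,
    feature_families,
    monotony,
    predictor_columns,
    session_load,
    strain,
    window_aggregate,
)
from volleymine.scoring import match_performance

from conftest import make_tiny_season, make_uniform_score_map


class TestLoadMetrics:
    @pytest.mark.parametrize("rpe,dur,expected", [(5, 60, 300), (0, 90, 0), (7.5, 48, 360)])
    def test_session_load_is_rpe_times_duration(self, rpe, dur, expected):
        assert session_load(rpe, dur) == pytest.approx(expected)

    def test_session_load_rejects_out_of_scale_rpe(self):
        with pytest.raises(ValueError):
            session_load(11, 60)

    def test_monotony_golden(self):
        # mean 100, SD (n-1) = sqrt(2)*100 -> ratio 1/sqrt(2)
        assert monotony([0, 200]) == pytest.approx(1 / np.sqrt(2))

    def test_monotony_constant_series_is_missing(self):
        assert np.isnan(monotony([100] * 10))

    def test_monotony_single_day_is_missing(self):
        assert np.isnan(monotony([150]))

    @given(st.floats(0.01, 100), st.integers(0, 2**31))
    @settings(max_examples=30, deadline=None)
    def test_monotony_scale_invariant(self, c, seed):
        loads = np.random.default_rng(seed).uniform(0, 500, size=7)
        if np.isnan(monotony(loads)):
            return
        assert monotony(c * loads) == pytest.approx(monotony(loads), rel=1e-9)

    def test_strain_is_load_times_monotony(self):
        assert strain(1000, 1.5) == pytest.approx(1500)
        assert strain(0, 1.2) == 0
        assert np.isnan(strain(1000, float("nan")))  # degenerate monotony propagates


class TestWindowAggregate:
    def _series(self, vals, start="2018-06-01"):
        idx = pd.date_range(start, periods=len(vals), freq="D")
        return pd.Series(vals, index=idx, dtype=float)

    def test_zero_filled_mean_counts_inactive_days(self):
        # 3 active days (3,5,7 jumps) + 4 zero days in a 7-day window
        s = self._series([3, 0, 5, 0, 7, 0, 0])
        val = window_aggregate(s, 7, "avg", pd.Timestamp("2018-06-08"))
        assert val == pytest.approx(15 / 7)

    def test_sd_of_constant_series_is_zero(self):
        s = self._series([4, 4, 4, 4])
        assert window_aggregate(s, 7, "std", pd.Timestamp("2018-06-05")) == 0.0

    def test_quartiles_collapse_for_single_point(self):
        s = self._series([9.0])
        d = pd.Timestamp("2018-06-02")
        assert (window_aggregate(s, 7, "firstquantile", d)
                == window_aggregate(s, 7, "thirdquantile", d)
                == window_aggregate(s, 7, "avg", d) == 9.0)

    def test_window_excludes_match_day(self):
        s = self._series([1, 1, 1, 100])  # day 4 is the match day
        assert window_aggregate(s, 3, "sum", pd.Timestamp("2018-06-04")) == 3.0

    def test_all_missing_window_is_missing(self):
        s = self._series([np.nan, np.nan])
        assert np.isnan(window_aggregate(s, 7, "avg", pd.Timestamp("2018-06-03")))


class TestDailySeries:
    def test_jump_counts_per_category(self, tiny_season):
        s = daily_series(tiny_season, "jumps_high", "A")
        day = tiny_season.jumps["date"].min()
        assert s.loc[day] == 1.0  # the 70 cm jump
        assert daily_series(tiny_season, "jumps_all", "A").loc[day] == 3.0

    def test_no_strength_day_contributes_no_set_observations(self, tiny_season):
        s = daily_series(tiny_season, "strength_kg_lower_body", "A")
        assert len(s) == 1  # exactly one lower-body set logged

    def test_holiday_days_missing_for_every_variable(self, tiny_season):
        holiday = tiny_season.calendar.loc[tiny_season.calendar.phase == "holiday", "date"].iloc[0]
        for var in ("jumps_all", "load_all", "wellness_mood", "sessions_volleyball"):
            assert np.isnan(daily_series(tiny_season, var, "A").loc[holiday])

    def test_unknown_variable_rejected(self, tiny_season):
        with pytest.raises(KeyError):
            daily_series(tiny_season, "nonexistent", "A")


class TestFeatureMatrix:
    def test_predictor_count_identity(self):
        fam = feature_families()
        counts = {k: len(v) for k, v in fam.items()}
        assert counts == {"jumps": 72, "strength": 81, "wellness": 48,
                          "load_metrics": 27, "session_counts": 9}
        assert len(feature_columns()) == 237

    def test_table_style_feature_names_present(self):
        cols = feature_columns()
        for name in ("Jumps_above65_std7", "LowerWeight_firstquantile28",
                     "WeightPrct_Upperbody_avg28", "JumpHeight_thirdquantile28",
                     "FullbodyWeight_std28"):
            assert name in cols

    def test_matrix_shape_and_positions(self, season_and_matrix):
        _, _, _, targets, matrix = season_and_matrix
        assert len(matrix) == len(targets)
        preds = predictor_columns(matrix)
        assert len(preds) == 237 + 5
        pos = matrix[list(POSITION_COLUMNS)].to_numpy()
        assert (pos.sum(axis=1) == 1).all()  # one-hot

    def test_jump_categories_partition_counts(self, season_and_matrix):
        _, _, _, _, matrix = season_and_matrix
        for w in (7, 14, 28):
            total = matrix[f"Jumps_all_sum{w}"]
            parts = (matrix[f"Jumps_below50_sum{w}"] + matrix[f"Jumps_50to65_sum{w}"]
                     + matrix[f"Jumps_above65_sum{w}"])
            np.testing.assert_allclose(total.to_numpy(), parts.to_numpy(), rtol=1e-12)

    def test_translation_invariance(self):
        sm = make_uniform_score_map()
        mats = []
        for shift in (0, 13):
            ds = make_tiny_season(shift_days=shift)
            targets = match_performance(ds.actions, sm, ds.roster)
            mats.append(build_feature_matrix(ds, targets))
        a, b = mats
        pd.testing.assert_frame_equal(a.drop(columns=["match_date"]),
                                      b.drop(columns=["match_date"]))

    def test_locality_events_outside_windows_ignored(self):
        sm = make_uniform_score_map()
        ds = make_tiny_season()
        base = build_feature_matrix(ds, match_performance(ds.actions, sm, ds.roster))
        # add a jump on a day > 28 days before the match: no window reaches it
        early = ds.calendar["date"].iloc[2]
        ds2 = ds.copy()
        ds2.jumps = pd.concat([ds2.jumps, pd.DataFrame([
            {"player_id": "A", "date": early, "height_cm": 80.0, "source": "training"}
        ])], ignore_index=True)
        mod = build_feature_matrix(ds2, match_performance(ds2.actions, sm, ds2.roster))
        pd.testing.assert_frame_equal(base, mod)

    def test_match_day_activity_excluded_from_own_features(self):
        sm = make_uniform_score_map()
        ds = make_tiny_season()
        base = build_feature_matrix(ds, match_performance(ds.actions, sm, ds.roster))
        mdate = ds.actions["match_date"].iloc[0]
        ds2 = ds.copy()
        ds2.jumps = pd.concat([ds2.jumps, pd.DataFrame([
            {"player_id": "A", "date": mdate, "height_cm": 99.0, "source": "match"}
        ])], ignore_index=True)
        mod = build_feature_matrix(ds2, match_performance(ds2.actions, sm, ds2.roster))
        pd.testing.assert_frame_equal(base, mod)

    def test_golden_window_values_in_matrix(self):
        # tiny season, player A, 7-day window before the day-41 match:
        # jumps on days 35 (3 jumps), 38 (1), 40 (1) -> daily counts
        # [3,0,0,1,0,1,0] over days 34..40
        sm = make_uniform_score_map()
        ds = make_tiny_season()
        m = build_feature_matrix(ds, match_performance(ds.actions, sm, ds.roster))
        row = m[(m.player_id == "A") & (m.action_type == "attack")].iloc[0]
        assert row["Jumps_all_sum7"] == pytest.approx(5)
        assert row["Jumps_all_avg7"] == pytest.approx(5 / 7)
        # loads: day 35 session 5*60=300, day 37 6*40=240, day 40 4*100=400
        assert row["Load_All_sum7"] == pytest.approx(940)
        daily = np.array([0, 300.0, 0, 240.0, 0, 0, 400.0])
        assert row["Monotony_All_7"] == pytest.approx(daily.mean() / daily.std(ddof=1))
        assert row["Strain_All_7"] == pytest.approx(940 * daily.mean() / daily.std(ddof=1))
        assert row["Sessions_Strength_sum7"] == pytest.approx(1)
        # strength kg sets in window: one lower-body set of 120 kg
        assert row["LowerWeight_sum7"] == pytest.approx(120)
        assert np.isnan(row["LowerWeight_std7"])  # single observation
        # wellness mood on days 39, 40: mean of {8, 7}
        assert row["Mood_avg7"] == pytest.approx(7.5)

    def test_non_default_config_warns_about_parity(self, tiny_season):
        from volleymine.features import FeatureConfig
        sm = make_uniform_score_map()
        targets = match_performance(tiny_season.actions, sm, tiny_season.roster)
        with pytest.warns(UserWarning, match="parity"):
            build_feature_matrix(tiny_season, targets, FeatureConfig(windows=(7, 14)))
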
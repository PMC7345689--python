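"""Daily exposure metrics: monitor averaging, 8-h ozone, AQHI, lags, IQR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import aircrossover as ac


def _panel(values_by_monitor, date="2010-06-01", pollutant="no2"):
    rows = []
    for monitor, values in values_by_monitor.items():
        for hour, value in enumerate(values):
            if value is not None:
                rows.append((pd.Timestamp(date), hour, monitor, pollutant, value))
    return pd.DataFrame(rows, columns=["date", "hour", "monitor_id", "pollutant", "value"])


class TestDailyMeanAcrossMonitors:
    def test_two_constant_monitors(self):
        panel = _panel({"A": [10.0] * 24, "B": [20.0] * 24})
        daily = ac.daily_mean_across_monitors(panel)
        assert daily.iloc[0] == pytest.approx(15.0)

    def test_single_monitor_hourly_ramp(self):
        panel = _panel({"A": list(range(1, 25))})
        assert ac.daily_mean_across_monitors(panel).iloc[0] == pytest.approx(12.5)

    def test_incomplete_day_is_missing(self):
        values = [5.0] * 10 + [None] * 14
        panel = _panel({"A": values})
        daily = ac.daily_mean_across_monitors(panel, completeness=0.75)
        assert np.isnan(daily.iloc[0])

    def test_empty_panel_raises(self):
        empty = pd.DataFrame(columns=["date", "hour", "monitor_id", "pollutant", "value"])
        with pytest.raises(ValueError):
            ac.daily_mean_across_monitors(empty)

    def test_monitor_first_averaging_is_missingness_robust(self):
        # monitor B reports only the high afternoon hours; averaging monitors
        # per hour first keeps the day's value at the hourly means
        a = [10.0] * 24
        b = [None] * 12 + [30.0] * 12
        daily = ac.daily_mean_across_monitors(_panel({"A": a, "B": b}))
        expected = (12 * 10.0 + 12 * 20.0) / 24
        assert daily.iloc[0] == pytest.approx(expected)


class TestDailyMax8h:
    def test_constant_day(self):
        daily = ac.daily_max_8h(_panel({"A": [30.0] * 24}, pollutant="o3"))
        assert daily.iloc[0] == pytest.approx(30.0)

    def test_ramp_takes_last_window(self):
        daily = ac.daily_max_8h(_panel({"A": list(range(1, 25))}, pollutant="o3"))
        assert daily.iloc[0] == pytest.approx(20.5)  # hours 16..23 -> mean(17..24)

    def test_all_missing_day(self):
        # day 2 reports nothing at all; its metric is missing, neighbours unaffected
        panel = pd.concat(
            [
                _panel({"A": [30.0] * 24}, date="2010-06-01", pollutant="o3"),
                _panel({"A": [40.0] * 24}, date="2010-06-03", pollutant="o3"),
            ]
        )
        daily = ac.daily_max_8h(panel)
        assert np.isnan(daily.loc["2010-06-02"])
        assert daily.loc["2010-06-01"] == pytest.approx(30.0)

    def test_sparse_windows_below_minimum_are_invalid(self):
        values = [None] * 16 + [10.0] * 5 + [None] * 3  # best window has 5 valid hours
        daily = ac.daily_max_8h(_panel({"A": values}, pollutant="o3"), min_hours_in_window=6)
        assert np.isnan(daily.iloc[0])

    def test_constant_series_max8h_equals_daily_mean(self, rng):
        level = float(rng.uniform(5, 50))
        panel = _panel({"A": [level] * 24}, pollutant="o3")
        assert ac.daily_max_8h(panel).iloc[0] == pytest.approx(
            ac.daily_mean_across_monitors(panel).iloc[0]
        )


class TestComputeAqhi:
    def test_zero_inputs_give_zero(self):
        assert ac.compute_aqhi(0.0, 0.0, 0.0) == 0.0

    @pytest.mark.parametrize(
        "no2,o3,pm25,expected",
        [(16.1, 31.5, 6.0, 3.279570698392951), (62.3, 85.9, 44.8, 12.021985699126047)],
    )
    def test_reference_values(self, no2, o3, pm25, expected):
        assert ac.compute_aqhi(no2, o3, pm25) == pytest.approx(expected, rel=1e-12)

    def test_missing_input_propagates(self):
        assert np.isnan(ac.compute_aqhi(np.nan, 10.0, 5.0))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            ac.compute_aqhi(-1.0, 0.0, 0.0)

    @settings(deadline=None, max_examples=100)
    @given(
        base=st.tuples(*[st.floats(0, 100) for _ in range(3)]),
        arg=st.integers(0, 2),
        bump=st.floats(0.1, 50),
    )
    def test_strictly_increasing_in_each_argument(self, base, arg, bump):
        lo = ac.compute_aqhi(*base)
        hi_args = list(base)
        hi_args[arg] += bump
        assert ac.compute_aqhi(*hi_args) > lo

    def test_zero_only_at_origin(self, rng):
        vals = rng.uniform(0.01, 60, size=(50, 3))
        out = ac.compute_aqhi(*vals.T)
        assert (out > 0).all()


class TestLagSeries:
    def _series(self, values, start="2010-01-01"):
        return pd.Series(values, index=pd.date_range(start, periods=len(values), freq="D"))

    def test_lag_zero_is_identity(self):
        s = self._series([3.0, 1.0, 4.0])
        pd.testing.assert_series_equal(ac.lag_series(s, 0), s)

    def test_lag_one_shifts_forward(self):
        out = ac.lag_series(self._series([1.0, 2.0, 3.0]), 1)
        assert np.isnan(out.iloc[0])
        assert list(out.iloc[1:]) == [1.0, 2.0]

    def test_lag_beyond_length_all_missing(self):
        out = ac.lag_series(self._series([1.0, 2.0, 3.0]), 5)
        assert out.isna().all()

    def test_negative_lag_rejected(self):
        with pytest.raises(ValueError):
            ac.lag_series(self._series([1.0]), -1)

    @settings(deadline=None, max_examples=30)
    @given(a=st.integers(0, 4), b=st.integers(0, 4))
    def test_lag_composition(self, a, b):
        s = self._series(list(np.arange(12.0)))
        lhs = ac.lag_series(ac.lag_series(s, a), b)
        rhs = ac.lag_series(s, a + b)
        pd.testing.assert_series_equal(lhs, rhs)


class TestInterquartileRange:
    def test_constant_series_has_zero_iqr(self):
        s = pd.Series([5.0] * 10)
        assert ac.interquartile_range(s).iqr == 0.0

    def test_ozone_quartiles_give_published_scaling(self):
        # five-point series whose type-7 quartiles equal the published
        # ozone Q1 = 24.0 and Q3 = 40.0
        s = pd.Series([8.0, 24.0, 31.5, 40.0, 56.0])
        assert ac.interquartile_range(s, pollutant="o3").iqr == pytest.approx(16.0)

    def test_pm25_quartiles(self):
        s = pd.Series([1.0, 3.8, 6.0, 9.8, 20.0])
        assert ac.interquartile_range(s).iqr == pytest.approx(6.0)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            ac.interquartile_range(pd.Series([np.nan, np.nan]))

    @settings(deadline=None, max_examples=50)
    @given(shift=st.floats(-100, 100), scale=st.floats(0.01, 50))
    def test_shift_invariance_and_positive_scaling(self, shift, scale):
        base = pd.Series([1.0, 4.0, 4.5, 7.0, 11.0, 13.0])
        iqr0 = ac.interquartile_range(base).iqr
        assert ac.interquartile_range(base + shift).iqr == pytest.approx(iqr0, abs=1e-9)
        assert ac.interquartile_range(base * scale).iqr == pytest.approx(scale * iqr0, rel=1e-9)


class TestBuildDailyTable:
    def test_hourly_panel_round_trip(self, rng):
        dates = pd.date_range("2011-07-01", periods=4, freq="D")
        daily_truth = pd.Series([12.0, 18.0, 9.0, 15.0], index=dates)
        panel = ac.simulate_hourly_panel(daily_truth, "no2", n_monitors=3, monitor_sd=0.5, rng=rng)
        recovered = ac.daily_mean_across_monitors(panel)
        assert np.allclose(recovered, daily_truth, rtol=0.05)

    def test_table_includes_aqhi(self, rng):
        dates = pd.date_range("2011-07-01", periods=3, freq="D")
        panels = {
            p: ac.simulate_hourly_panel(
                pd.Series([20.0, 22.0, 18.0], index=dates), p, n_monitors=2, rng=rng
            )
            for p in ("no2", "o3", "pm25")
        }
        table = ac.build_daily_table(panels)
        assert {"no2_ppb", "o3_ppb_max8h", "pm25_ugm3", "aqhi"} <= set(table.columns)
        assert table["aqhi"].notna().all()
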
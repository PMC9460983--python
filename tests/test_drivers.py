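"""Driver ingestion, meteorological conversions and daily reduction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from peatflux import drivers


class TestSapwoodAllometry:
    @pytest.mark.parametrize("dbh_mm, thickness_cm", [
        (129, 3.29), (162, 3.94), (150, 3.70),
        (157, 3.84), (133, 3.37), (175, 4.20),
    ])
    def test_matches_site_measurements(self, dbh_mm, thickness_cm):
        assert round(drivers.sapwood_thickness(dbh_mm) / 10, 2) == thickness_cm

    def test_intercept_limit(self):
        assert drivers.sapwood_thickness(1e-9) == pytest.approx(9.755)

    def test_rejects_nonpositive_dbh(self):
        with pytest.raises(ValueError):
            drivers.sapwood_thickness(0)


class TestVpd:
    def test_saturated_air_has_zero_deficit(self):
        assert drivers.vpd(15.0, 1.0) == 0.0

    def test_reference_saturation_pressure(self):
        assert drivers.vpd(0.0, 0.0) == pytest.approx(611.0)

    def test_hand_evaluated_value(self):
        # frozen independent calculator evaluation at 20 degC, 50% RH
        assert drivers.vpd(20.0, 0.5) == pytest.approx(1168.2397137744122, rel=1e-12)

    def test_rejects_humidity_outside_unit_interval(self):
        with pytest.raises(ValueError):
            drivers.vpd(20.0, 1.2)

    @given(t=st.floats(-30, 40), h1=st.floats(0, 0.99), dh=st.floats(1e-3, 0.5))
    @settings(max_examples=50, derandomize=True)
    def test_strictly_decreasing_in_humidity(self, t, h1, dh):
        h2 = min(h1 + dh, 1.0)
        assert drivers.vpd(t, h2) < drivers.vpd(t, h1)

    @given(t=st.floats(-30, 39), dt=st.floats(0.1, 10), h=st.floats(0, 0.99))
    @settings(max_examples=50, derandomize=True)
    def test_strictly_increasing_in_temperature(self, t, dt, h):
        assert drivers.vpd(t + dt, h) > drivers.vpd(t, h)


class TestVpdMolar:
    def test_zero_maps_to_zero(self):
        assert drivers.vpd_molar(0.0, 25.0) == 0.0

    def test_identity_by_construction(self):
        assert drivers.vpd_molar(8.3145 * 273.15, 0.0) == pytest.approx(1.0)

    def test_hand_evaluated_value(self):
        assert drivers.vpd_molar(1168.0, 20.0) == pytest.approx(
            0.47919999693935617, rel=1e-12)


class TestLeafTemperature:
    def test_dark_leaf_at_air_temperature(self):
        assert drivers.leaf_temperature(12.0, 0.0) == 12.0

    @pytest.mark.parametrize("t, i, expected", [
        (10.0, 1.5e-3, 12.25), (20.0, 1e-3, 21.5),
    ])
    def test_linear_offset(self, t, i, expected):
        assert drivers.leaf_temperature(t, i) == pytest.approx(expected)


class TestTopDecileMedian:
    def test_ten_values_keep_the_single_largest(self):
        assert drivers.daily_top_decile_median(range(1, 11)) == 10.0

    def test_twenty_values_keep_two(self):
        assert drivers.daily_top_decile_median(range(1, 21)) == 19.5

    def test_constant_series(self):
        assert drivers.daily_top_decile_median([4.2] * 7) == 4.2

    def test_empty_day_is_missing(self):
        assert np.isnan(drivers.daily_top_decile_median([]))

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=200))
    @settings(max_examples=100, derandomize=True)
    def test_at_least_the_overall_median(self, values):
        assert drivers.daily_top_decile_median(values) >= np.median(values)


class TestInterpolateWtd:
    def _logger(self, deltas, start="2009-06-01"):
        ts = pd.date_range(start, periods=len(deltas), freq="h")
        return pd.DataFrame({"timestamp": ts, "delta": deltas})

    def test_manual_on_logger_curve_returns_logger(self):
        log = self._logger(np.linspace(10, 30, 48))
        manual = log.iloc[[5, 40]]
        out = drivers.interpolate_wtd(manual, log)
        np.testing.assert_allclose(out["delta"], log["delta"])

    def test_constant_logger_gives_linear_between_manuals(self):
        log = self._logger(np.full(49, 20.0))
        manual = pd.DataFrame({"timestamp": [log["timestamp"].iloc[0],
                                             log["timestamp"].iloc[48]],
                               "delta": [10.0, 34.0]})
        out = drivers.interpolate_wtd(manual, log)
        np.testing.assert_allclose(out["delta"], np.linspace(10.0, 34.0, 49))

    def test_single_manual_point_shifts_by_constant(self):
        log = self._logger(np.linspace(12, 40, 24))
        manual = pd.DataFrame({"timestamp": [log["timestamp"].iloc[6]],
                               "delta": [log["delta"].iloc[6] + 5.0]})
        out = drivers.interpolate_wtd(manual, log)
        np.testing.assert_allclose(out["delta"], log["delta"] + 5.0)

    def test_standing_water_clamped_to_surface(self):
        log = self._logger(np.linspace(2, 10, 12))
        manual = pd.DataFrame({"timestamp": [log["timestamp"].iloc[0]],
                               "delta": [0.0]})
        out = drivers.interpolate_wtd(manual, log)
        assert (out["delta"] >= 0).all()


class TestDailyPipeline:
    def _met(self):
        ts = pd.date_range("2009-06-01", periods=96, freq="h")
        rng = np.random.default_rng(1)
        return pd.DataFrame({
            "timestamp": ts,
            "T": 12 + 6 * np.sin(np.arange(96) / 24 * 2 * np.pi) + rng.normal(0, 1, 96),
            "h_r": np.clip(rng.uniform(0.4, 0.95, 96), 0, 1),
            "I": np.clip(1.2e-3 * np.sin(np.arange(96) / 24 * np.pi), 0, None),
        })

    def test_build_daily_drivers_shape_and_invariants(self):
        met = self._met()
        wtd = pd.DataFrame({"timestamp": met["timestamp"],
                            "delta": np.linspace(20, 40, 96)})
        daily = drivers.build_daily_drivers(met, wtd)
        assert list(daily.columns) == drivers.DAILY_DRIVER_COLUMNS
        assert len(daily) == 4
        assert (daily["D"] >= 0).all()
        assert (daily["T_l"] >= daily["T"]).all()

    def test_multiple_tubes_averaged_per_timestamp(self):
        met = self._met()
        ts = met["timestamp"]
        wtd = pd.concat([
            pd.DataFrame({"timestamp": ts, "delta": 20.0, "tube_id": "a"}),
            pd.DataFrame({"timestamp": ts, "delta": 30.0, "tube_id": "b"}),
        ])
        daily = drivers.build_daily_drivers(met, wtd)
        assert (daily["delta"] == 25.0).all()

    def test_daily_table_roundtrip_is_exact(self, tmp_path):
        met = self._met()
        wtd = pd.DataFrame({"timestamp": met["timestamp"],
                            "delta": np.linspace(20, 40, 96)})
        daily = drivers.build_daily_drivers(met, wtd)
        path = tmp_path / "daily_drivers.csv"
        drivers.write_daily_drivers(daily, path)
        back = drivers.read_daily_drivers(path)
        for col in ["D", "I", "T", "T_l", "delta"]:
            assert np.array_equal(daily[col].to_numpy(), back[col].to_numpy())

    def test_eobs_converts_sap_flow_by_leaf_area(self):
        ts = pd.date_range("2009-06-01", periods=24, freq="h")
        sap = pd.DataFrame({"timestamp": ts, "tree_id": 1,
                            "J": np.full(24, 2.116)})
        out = drivers.build_daily_eobs(sap, rho=2500.0)
        assert out["E_obs"].iloc[0] == pytest.approx(8.464e-4)
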
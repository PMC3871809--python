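"""Synthetic environment generator: anchors, shapes, seasonal claims, CSV I/O."""

import numpy as np
import pandas as pd
import pytest

from kiwisim.environment import (
    EnvironmentConfig,
    EnvironmentConfigError,
    SyntheticEnvironment,
    TabulatedEnvironment,
    stem_water_potential,
)

CFG = EnvironmentConfig()
ENV = SyntheticEnvironment(CFG)


class TestDiurnalTemperature:
    def test_minimum_at_sunrise(self):
        for day in (10.0, 80.0, 150.0):
            env = ENV.envelopes(day)
            assert ENV.diurnal_temperature(day, env["sunrise"]) == pytest.approx(
                env["t_min"], abs=1e-9
            )

    def test_daily_maximum_equals_envelope(self):
        for day in (10.0, 80.0, 150.0):
            env = ENV.envelopes(day)
            hours = np.linspace(0, 24, 2401)
            temps = [ENV.diurnal_temperature(day, h) for h in hours]
            assert max(temps) == pytest.approx(env["t_max"], abs=0.01)

    def test_continuity_across_sunset(self):
        for day in (10.0, 80.0, 150.0):
            ss = ENV.envelopes(day)["sunset"]
            gap = abs(
                ENV.diurnal_temperature(day, ss - 1e-7)
                - ENV.diurnal_temperature(day, ss + 1e-7)
            )
            assert gap < 1e-4


class TestDiurnalHumidity:
    def test_maximum_at_sunrise(self):
        env = ENV.envelopes(60.0)
        assert ENV.diurnal_humidity(60.0, env["sunrise"]) == pytest.approx(
            env["h_max"], abs=1e-9
        )

    def test_antiphase_with_temperature(self):
        """Humidity minimum coincides with the temperature maximum."""
        hours = np.linspace(0, 24, 2401)
        temps = np.array([ENV.diurnal_temperature(60.0, h) for h in hours])
        hums = np.array([ENV.diurnal_humidity(60.0, h) for h in hours])
        assert abs(hours[np.argmax(temps)] - hours[np.argmin(hums)]) < 0.02

    def test_bounds_on_season_grid(self):
        for t in np.linspace(0, 170, 1000):
            h = ENV.sample(t).H_a
            assert 0.0 <= h <= 1.0


class TestTranspirationAndPotential:
    def test_zero_at_midnight(self):
        assert ENV.transpiration(80.0, 0.0) == 0.0
        assert ENV.transpiration(80.0, 23.9) == 0.0

    def test_daily_integral_matches_envelope_total(self):
        for day in (20.0, 90.0, 160.0):
            env = ENV.envelopes(day)
            hours = np.linspace(0, 24, 24001)
            tr = np.array([ENV.transpiration(day, h) for h in hours])  # L/s
            total = np.trapezoid(tr, hours * 3600.0)
            assert total == pytest.approx(env["tr_total"], rel=1e-3)

    def test_summer_exceeds_autumn(self):
        """Mid-summer daily transpiration far exceeds the harvest-season total."""
        summer = ENV.envelopes(55.0)["tr_total"]     # mid-January
        autumn = ENV.envelopes(165.0)["tr_total"]    # early May
        assert autumn < summer
        assert summer / autumn > 2.0

    def test_soil_potential_at_zero_transpiration(self):
        assert stem_water_potential(0.0, CFG) == pytest.approx(-1.0)

    def test_linear_in_transpiration(self):
        assert stem_water_potential(0.001, CFG) == pytest.approx(-2.0)
        slope = (stem_water_potential(0.002, CFG) - stem_water_potential(0.001, CFG)) / 0.001
        assert slope == pytest.approx(-1.0 / CFG.L_soil_stem)

    def test_potential_bounded_by_soil_on_grid(self):
        for t in np.linspace(0, 170, 2000):
            assert ENV.sample(t).psi_x <= -1.0 + 1e-12


class TestPhloemConcentration:
    def test_extrema_anchors(self):
        env = ENV.envelopes(60.0)
        sr = env["sunrise"]
        assert ENV.phloem_concentration(60.0, sr) == pytest.approx(0.09, abs=1e-9)
        hours = np.linspace(0, 24, 2401)
        cs = [ENV.phloem_concentration(60.0, h) for h in hours]
        assert max(cs) == pytest.approx(0.17, abs=1e-4)

    def test_high_crop_offset(self):
        high = SyntheticEnvironment(CFG, crop_offset=0.01)
        hours = np.linspace(0, 24, 2401)
        cs = [high.phloem_concentration(60.0, h) for h in hours]
        assert max(cs) == pytest.approx(0.16, abs=1e-4)


def test_seasonal_envelope_may_january_contrast():
    """Mean temperature in May is about 7 degC below January (within 1 degC)."""

    def month_mean(doy_lo, doy_hi):
        days = [d - CFG.bloom_doy + 365 for d in range(doy_lo, doy_hi)]
        temps = []
        for d in days:
            temps.extend(ENV.diurnal_temperature(d, h) for h in range(24))
        return float(np.mean(temps))

    january = month_mean(1, 32)
    may = month_mean(121, 152)
    assert january - may == pytest.approx(7.0, abs=1.0)


def test_determinism():
    a = ENV.to_frame(10.0, 12.0, 1.0)
    b = SyntheticEnvironment(EnvironmentConfig()).to_frame(10.0, 12.0, 1.0)
    pd.testing.assert_frame_equal(a, b)


class TestTabulatedEnvironment:
    def test_round_trip_matches_generator(self, tmp_path):
        frame = ENV.to_frame(40.0, 42.0, 0.5)
        path = tmp_path / "weather.csv"
        frame.to_csv(path, index=False)
        tab = TabulatedEnvironment.from_csv(path)
        for t in (40.25, 41.0, 41.75):
            a, b = tab.sample(t), ENV.sample(t)
            assert a.T == pytest.approx(b.T, abs=1e-9)
            assert a.C_p == pytest.approx(b.C_p, abs=1e-12)

    def test_non_monotone_time_rejected_with_row(self):
        frame = pd.DataFrame({
            "t": [0.0, 1.0, 0.5], "T": [20.0] * 3, "H_a": [0.8] * 3,
            "Tr": [0.0] * 3, "psi_x": [-1.0] * 3, "C_p": [0.1] * 3,
        })
        with pytest.raises(EnvironmentConfigError, match="row 3"):
            TabulatedEnvironment(frame)

    def test_out_of_range_humidity_rejected(self):
        frame = pd.DataFrame({
            "t": [0.0, 1.0], "T": [20.0] * 2, "H_a": [0.8, 1.4],
            "Tr": [0.0] * 2, "psi_x": [-1.0] * 2, "C_p": [0.1] * 2,
        })
        with pytest.raises(EnvironmentConfigError, match="humidity"):
            TabulatedEnvironment(frame)

    def test_missing_column_rejected(self):
        with pytest.raises(EnvironmentConfigError, match="missing"):
            TabulatedEnvironment(pd.DataFrame({"t": [0, 1], "T": [20, 21]}))


def test_config_validation():
    with pytest.raises(ValueError):
        EnvironmentConfig(C_min=0.2, C_max=0.1)
    with pytest.raises(ValueError):
        EnvironmentConfig(L_soil_stem=0.0)
    with pytest.raises(ValueError):
        EnvironmentConfig(tmax_fourier=(1.0, 2.0))
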
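import numpy as np
import pytest
from scipy import stats

from voyage_eb.body_model import BodyType
from voyage_eb.energy_balance import HHL, adjust_wind
from voyage_eb.errors import ConfigurationError
from voyage_eb.synthetic_env import EnvSample
from voyage_eb.trip_energetics import (DepartureEnvSeries, EBSeries,
                                       W_TO_KCAL_PER_DAY, aeb_ratio,
                                       departure_day_stats, departure_env,
                                       destination_contrast, eb_series,
                                       mean_ci, seasonal_means, trip_hourly_env,
                                       welch_contrast)
from voyage_eb.voyage_sim import SimConfig, Trip, TrajectoryPoint, VesselPolar, simulate_trip

from conftest import make_uniform_fieldset

BODY = BodyType(sex="female", h_cm=166.0, bm_kg=70.0, scf_m=0.005, label="B1")


def stationary_trip(lat, lon, fieldset, hours=24, departure_day=0, dest="hawaii"):
    """A trip whose vessel never moves; env re-sampled from the fieldset."""
    pts = []
    for t in np.arange(0.0, hours + 1e-9, 6.0):
        env = fieldset.sample(lat, lon, float(t))
        pts.append(TrajectoryPoint(t=float(t), lat=lat, lon=lon, env=env,
                                   sail_vec=(0.0, 0.0), drift_vec=(0.0, 0.0)))
    return Trip(departure_day=departure_day, destination=dest, vessel_index=0,
                points=pts)


class TestDepartureEnv:
    def test_identical_trips_mean_is_member(self, uniform_fieldset):
        trips = [stationary_trip(0.0, 200.0, uniform_fieldset) for _ in range(8)]
        env = departure_env(trips, uniform_fieldset)
        assert np.allclose(env.ta_c, 25.0)
        assert env.n_vessels == 8

    def test_two_vessel_arithmetic_mean(self):
        # SAT linear in latitude: 20 degC at one vessel, 24 at the other
        fs = make_uniform_fieldset(ta_c=22.0, sat_lat_gradient=0.4)
        t1 = stationary_trip(-5.0, 200.0, fs)   # 22 - 2 = 20
        t2 = stationary_trip(5.0, 200.0, fs)    # 22 + 2 = 24
        env = departure_env([t1, t2], fs)
        assert np.allclose(env.ta_c, 22.0, atol=1e-6)

    def test_wind_adjusted_to_person_height(self):
        fs = make_uniform_fieldset(wind=(8.0, 0.0))
        env = departure_env([stationary_trip(0.0, 200.0, fs)], fs)
        assert np.allclose(env.ws15, float(adjust_wind(8.0)), atol=1e-6)

    def test_brute_force_vessel_mean_oracle(self):
        # [DERIVED] explicit per-hour loop over vessels still en route
        from voyage_eb.config import RunConfig
        from voyage_eb.synthetic_env import ClimateConfig, GridSpec, generate_fields

        grid = GridSpec(lat_min=-40, lat_max=20, lon_min=180, lon_max=230,
                        resolution=5.0, time_end=60 * 24.0, atmos_step=6.0)
        fs = generate_fields(ClimateConfig(seed=6), grid)
        cfg = RunConfig.for_profile("demo", seed=6)
        sim = SimConfig(seed=6, max_duration_days=10.0)
        trips = [simulate_trip(0, "hawaii", fs, cfg.polar, sim, vessel_index=v,
                               start=(-17.0, 210.0), target=(15.0, 205.0))
                 for v in range(4)]
        env = departure_env(trips, fs)
        members = [trip_hourly_env(t, fs) for t in trips]
        n = max(m["ta_c"].size for m in members)
        for h in range(0, n, 7):
            vals = [m["ta_c"][h] for m in members if m["ta_c"].size > h]
            assert env.ta_c[h] == pytest.approx(float(np.mean(vals)), abs=1e-9)

    def test_truncate_at_shortest(self, uniform_fieldset):
        t1 = stationary_trip(0.0, 200.0, uniform_fieldset, hours=24)
        t2 = stationary_trip(0.0, 200.0, uniform_fieldset, hours=48)
        env = departure_env([t1, t2], uniform_fieldset, truncate_at_shortest=True)
        assert env.ta_c.size == 25
        assert env.truncation_time == pytest.approx(24.0)

    def test_empty_rejected(self, uniform_fieldset):
        with pytest.raises(ConfigurationError):
            departure_env([], uniform_fieldset)

    def test_mixed_departures_rejected(self, uniform_fieldset):
        t1 = stationary_trip(0.0, 200.0, uniform_fieldset, departure_day=0)
        t2 = stationary_trip(0.0, 200.0, uniform_fieldset, departure_day=5)
        with pytest.raises(ConfigurationError):
            departure_env([t1, t2], uniform_fieldset)


def constant_series(eb_w, hours, **kw):
    defaults = dict(departure_day=0, destination="hawaii", body_label="B1",
                    sex="female", exposure_label="Hhl")
    defaults.update(kw)
    return EBSeries(eb_w=np.full(hours, float(eb_w)), **defaults)


class TestEbSeries:
    def test_constant_minus_100w_24h(self):
        # [DERIVED] -100 W for 24 h = -100 * 86400 / 4184 kcal
        s = constant_series(-100.0, 24)
        assert s.aeb_kcal == pytest.approx(-100.0 * 86400.0 / 4184.0, rel=1e-12)
        assert s.aeb_kcal == pytest.approx(-2065.0, abs=0.1)

    def test_zero_eb(self):
        assert constant_series(0.0, 48).aeb_kcal == 0.0

    def test_length_doubling_doubles_aeb(self):
        assert constant_series(-50.0, 96).aeb_kcal == pytest.approx(
            2.0 * constant_series(-50.0, 48).aeb_kcal)

    def test_watt_to_kcal_day_bookkeeping(self):
        # 1 W sustained = 20.65 kcal/day, independent day-level conversion
        s = constant_series(1.0, 240)
        assert W_TO_KCAL_PER_DAY == pytest.approx(20.65, abs=0.01)
        assert s.mean_daily_eb == pytest.approx(W_TO_KCAL_PER_DAY, rel=1e-3)

    def test_applies_model_hourly(self, uniform_fieldset):
        env = DepartureEnvSeries(departure_day=0, destination="hawaii",
                                 hours=np.arange(48.0), ta_c=np.full(48, 37.0),
                                 ws15=np.zeros(48), solar_wm2=np.zeros(48),
                                 n_vessels=8, truncation_time=48.0)
        s = eb_series(env, BODY, HHL)
        assert np.allclose(s.eb_w, BODY.bmr_w, atol=1e-9)


class TestStats:
    def test_identical_values_zero_ci(self):
        g = mean_ci([5.0, 5.0, 5.0])
        assert g.mean == 5.0 and g.ci_half_width == 0.0

    def test_closed_form_t_interval(self):
        # [DERIVED] t(0.975, 2) * 20 / sqrt(3) = 49.68
        g = mean_ci([-100.0, -120.0, -140.0])
        assert g.mean == pytest.approx(-120.0)
        expected = stats.t.ppf(0.975, 2) * 20.0 / np.sqrt(3.0)
        assert g.ci_half_width == pytest.approx(expected, rel=1e-12)
        assert g.ci_half_width == pytest.approx(49.68, abs=0.01)

    def test_departure_day_grouping(self):
        series = [constant_series(-100.0, 24, departure_day=d + 365 * y)
                  for d in (0, 5) for y in (0, 1)]
        df = departure_day_stats(series)
        assert set(df["departure_doy"]) == {0, 5}
        assert (df["n"] == 2).all()
        assert np.allclose(df["ci_half_width"], 0.0)

    def test_seasonal_means_partition(self):
        series = [constant_series(-100.0, 24, departure_day=d)
                  for d in range(0, 365, 5)]
        df = departure_day_stats(series)
        sm = seasonal_means(df)
        assert set(sm["season"]) == {"DJF", "MAM", "JJA", "SON"}
        assert np.allclose(sm[sm.destination == "hawaii"]["mean_daily_eb"], -2065.0, atol=0.1)
        # seasons partition the year: weighted seasonal means recompose the annual mean
        counts = df.groupby("season").size()
        annual = (sm.set_index("season")["mean_daily_eb"] * counts).sum() / counts.sum()
        assert annual == pytest.approx(df["mean_daily_eb"].mean(), rel=1e-9)


class TestContrasts:
    def test_identical_groups_not_significant(self):
        res = destination_contrast({0: [-10.0, -10.0]}, {0: [-10.0, -10.0]})
        assert res[0].mean_difference == 0.0
        assert not res[0].significant

    def test_degenerate_zero_variance_significant(self):
        res = destination_contrast({0: [-20.0, -20.0, -20.0]},
                                   {0: [-10.0, -10.0, -10.0]})
        assert res[0].mean_difference == pytest.approx(-10.0)
        assert res[0].ci_half_width == 0.0
        assert res[0].significant

    def test_welch_against_scipy_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = rng.normal(0.0, 2.0, size=rng.integers(3, 12))
            b = rng.normal(1.0, 3.0, size=rng.integers(3, 12))
            diff, hw = welch_contrast(a, b)
            res = stats.ttest_ind(a, b, equal_var=False)
            lo, hi = res.confidence_interval(0.95)
            assert diff == pytest.approx(a.mean() - b.mean(), rel=1e-12)
            assert diff - hw == pytest.approx(lo, rel=1e-9)
            assert diff + hw == pytest.approx(hi, rel=1e-9)

    def test_season_label(self):
        res = destination_contrast({40: [-5.0, -6.0]}, {40: [-1.0, -2.0]})
        assert res[0].season == "DJF"  # day 40 is in February


class TestAebRatio:
    def test_equal_aggregates(self):
        assert aeb_ratio([-1000.0], [-1000.0]) == pytest.approx(1.0)

    def test_paper_style_arithmetic(self):
        assert aeb_ratio([-3300.0], [-1000.0]) == pytest.approx(3.3)

    def test_scale_invariance(self):
        r1 = aeb_ratio([-3300.0], [-1000.0])
        r2 = aeb_ratio([-6600.0], [-2000.0])
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_zero_rejected(self):
        with pytest.raises(ConfigurationError):
            aeb_ratio([0.0], [-1.0])
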
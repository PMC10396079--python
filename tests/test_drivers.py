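import numpy as np
import pandas as pd
import pytest

from critnc import (
    SimConfig,
    WeatherSeries,
    compute_agdd,
    correlate_drivers,
    default_gem_suite,
    default_truth,
    extract_covariates,
    significance_tier,
    simulate_experiment,
    subseed,
)
from critnc.drivers import CoverageError


def weather_frame(start, n_days, tmax=20.0, tmin=10.0, rain=0.0):
    days = pd.date_range(start, periods=n_days, freq="D")
    return pd.DataFrame(
        {
            "date": days.date.astype(str),
            "tmax_c": np.full(n_days, tmax),
            "tmin_c": np.full(n_days, tmin),
            "rain_mm": np.full(n_days, rain),
        }
    )


class TestWeatherSeries:
    def test_tmax_below_tmin_rejected(self):
        df = weather_frame("2012-11-01", 3)
        df.loc[1, "tmax_c"] = 5.0
        with pytest.raises(ValueError, match="Tmax"):
            WeatherSeries(df)

    def test_gap_in_dates_rejected(self):
        df = weather_frame("2012-11-01", 5).drop(index=2)
        with pytest.raises(ValueError, match="contiguous"):
            WeatherSeries(df)

    def test_csv_roundtrip(self, tmp_path):
        w = WeatherSeries(weather_frame("2012-11-01", 4, rain=2.5))
        p = tmp_path / "w.csv"
        w.to_csv(p)
        w2 = WeatherSeries.from_csv(p)
        pd.testing.assert_frame_equal(w.df, w2.df)


class TestComputeAgdd:
    def test_single_day(self):
        w = WeatherSeries(weather_frame("2013-03-01", 1, tmax=20, tmin=10))
        assert compute_agdd(w, "2013-03-01", "2013-03-01") == pytest.approx(15.0)

    def test_additive_over_days(self):
        w = WeatherSeries(weather_frame("2013-03-01", 3, tmax=15, tmin=5))
        assert compute_agdd(w, "2013-03-01", "2013-03-03") == pytest.approx(30.0)

    def test_subzero_mean_clamped_to_zero(self):
        w = WeatherSeries(weather_frame("2013-01-01", 1, tmax=0.0, tmin=-4.0))
        assert compute_agdd(w, "2013-01-01", "2013-01-01") == 0.0
        # literal unclamped accumulation stays available
        assert compute_agdd(
            w, "2013-01-01", "2013-01-01", clamp_negative=False
        ) == pytest.approx(-2.0)

    def test_split_additivity(self):
        rng = np.random.default_rng(2)
        df = weather_frame("2012-11-01", 60)
        df["tmax_c"] = rng.uniform(2, 25, 60)
        df["tmin_c"] = df["tmax_c"] - rng.uniform(2, 10, 60)
        w = WeatherSeries(df)
        whole = compute_agdd(w, "2012-11-01", "2012-12-30")
        left = compute_agdd(w, "2012-11-01", "2012-12-01")
        right = compute_agdd(w, "2012-12-02", "2012-12-30")
        assert whole == pytest.approx(left + right, abs=1e-9)

    def test_missing_coverage_raises(self):
        w = WeatherSeries(weather_frame("2013-03-01", 5))
        with pytest.raises(CoverageError, match="missing"):
            compute_agdd(w, "2013-02-25", "2013-03-03")


class TestExtractCovariates:
    def test_constant_weather_gdd_identities(self, noise_free_trial):
        ds, _ = noise_free_trial
        vpd = (ds.meta.flowering_date - ds.meta.sowing_date).days
        w = WeatherSeries(
            weather_frame(ds.meta.sowing_date, vpd + 1, tmax=12.0, tmin=4.0, rain=1.5)
        )
        row = extract_covariates(ds, w)
        assert row.VPD == vpd
        assert row.AGDD == pytest.approx(8.0 * (vpd + 1))
        assert row.GDD_daily * row.VPD == pytest.approx(row.AGDD, abs=1e-9)
        assert row.rainfall_total == pytest.approx(1.5 * (vpd + 1))
        assert row.density == ds.meta.sowing_density

    def test_dmmax_nmax_are_observed_maxima(self, noise_free_trial):
        ds, _ = noise_free_trial
        row = extract_covariates(ds)
        shoot = ds.observations("shoot")
        assert row.DMmax == pytest.approx(shoot["W"].max())
        assert row.Nmax == pytest.approx(shoot["N_conc"].max())


class TestCorrelateDrivers:
    def _tables(self, n=6, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"E{i}" for i in range(n)]
        covars = pd.DataFrame(
            {"density": rng.uniform(150, 400, n), "AGDD": rng.uniform(1200, 2000, n)},
            index=idx,
        )
        params = pd.DataFrame(
            {"A1": 2.0 + 0.004 * covars["density"], "A2": rng.uniform(0.2, 0.5, n)},
            index=idx,
        )
        return params, covars

    def test_perfectly_linear_pair(self):
        params, covars = self._tables()
        corr = correlate_drivers(params, covars)
        assert corr.r("A1", "density") == pytest.approx(1.0)
        row = corr.table.query("var1 == 'A1' and var2 == 'density'")
        assert row["tier"].iloc[0] == "***"

    def test_constant_variable_flagged_not_fatal(self):
        params, covars = self._tables()
        covars["AGDD"] = 1500.0
        corr = correlate_drivers(params, covars)
        row = corr.table.query("var1 == 'A1' and var2 == 'AGDD'")
        assert row["tier"].iloc[0] == "undefined"
        assert np.isnan(row["r"].iloc[0])
        assert corr.r("A1", "density") == pytest.approx(1.0)

    def test_too_few_experiments_rejected(self):
        params, covars = self._tables(n=3)
        with pytest.raises(ValueError, match=">= 4"):
            correlate_drivers(params, covars)

    def test_mismatched_ids_rejected(self):
        params, covars = self._tables()
        covars.index = [f"X{i}" for i in range(len(covars))]
        with pytest.raises(ValueError, match="match"):
            correlate_drivers(params, covars)

    def test_symmetry_unit_diagonal_and_order_invariance(self):
        params, covars = self._tables()
        corr = correlate_drivers(params, covars)
        piv = corr.pivot("r")
        np.testing.assert_allclose(np.diag(piv.loc[piv.columns, piv.columns]), 1.0)
        shuffled = correlate_drivers(params.iloc[::-1], covars.iloc[::-1])
        assert corr.r("A1", "AGDD") == pytest.approx(shuffled.r("A1", "AGDD"), abs=1e-12)

    def test_recovers_engineered_density_correlation(self):
        # true A1 affine in sowing density with correlation 0.8: the estimated
        # Pearson r should land near 0.8 for most master seeds
        hits = 0
        for seed in range(10):
            truths, cfgs = default_gem_suite(
                n_experiments=14, master_seed=seed, density_a1_rho=0.8
            )
            params = pd.DataFrame(
                {"A1": [t.A1 for t in truths]},
                index=[c.experiment_id for c in cfgs],
            )
            covars = pd.DataFrame(
                {"density": [c.sowing_density for c in cfgs]},
                index=[c.experiment_id for c in cfgs],
            )
            r = correlate_drivers(params, covars).r("A1", "density")
            hits += abs(r - 0.8) <= 0.2
        assert hits >= 8


def test_significance_tiers_boundaries():
    assert significance_tier(0.0005) == "***"
    assert significance_tier(0.005) == "**"
    assert significance_tier(0.03) == "*"
    assert significance_tier(0.08) == "."
    assert significance_tier(0.5) == ""
    assert significance_tier(float("nan")) == "undefined"
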
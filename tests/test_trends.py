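import numpy as np
import pandas as pd
import pytest

from nutriclines import (
    MonthlyClimatology,
    RegionSpec,
    TrendDistribution,
    annual_average,
    compute_all,
    density_trends,
    deep_anomaly_trend,
    filter_extreme_trends,
    filter_trend_eligible,
    fit_global_regression,
    fit_site_trends,
    generate_archive,
    generate_climatology,
    kruskal_wallis,
    median_with_bootstrap_ci,
    paired_residual_trend,
    regional_medians,
    residual_tpo4,
    seasonal_anomaly,
    sign_test,
)
from nutriclines.nulls import ErrorModel
from nutriclines.simulate import SyntheticWorldConfig


def _series(rows, nutrient="nitrate"):
    df = pd.DataFrame(rows, columns=["lat_bin", "lon_bin", "year", "mean_depth"])
    df["nutrient"] = nutrient
    df["n_casts"] = 1
    return df


class TestGlobalRegression:
    def test_collinear_points_recover_line(self):
        series = _series([(10, 0, 2000, 100.0), (11, 0, 2005, 105.0), (12, 0, 2010, 110.0)])
        fit = fit_global_regression(series)
        assert fit.slope == pytest.approx(1.0)
        assert fit.n_points == 3

    def test_flat_depths_slope_zero_p_one(self):
        series = _series([(10, 0, 2000, 100.0), (11, 0, 2005, 100.0), (12, 0, 2010, 100.0)])
        fit = fit_global_regression(series)
        assert fit.slope == 0.0
        assert fit.p_value == pytest.approx(1.0)

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(ValueError):
            fit_global_regression(_series([(10, 0, 2000, 100.0), (10, 0, 2010, 110.0)]))

    def test_recovers_imposed_global_deepening(self):
        # every site deepens at 0.47 m/y; pooled OLS must recover it within 2 SE
        cfg = SyntheticWorldConfig(
            n_sites=60,
            years=(1990, 2015),
            seed=21,
            casts_per_site_year=1.0,
            trend_dist_no3=TrendDistribution(0.47, 0.0),
            trend_dist_po4=TrendDistribution(0.47, 0.0),
        )
        casts, _ = generate_archive(cfg)
        series = filter_trend_eligible(annual_average(compute_all(casts)))
        fit = fit_global_regression(series[series.nutrient == "phosphate"])
        assert abs(fit.slope - 0.47) <= 2 * fit.slope_se


class TestSiteTrends:
    def test_two_point_slope(self):
        series = _series([(10, 0, 2000, 100.0), (10, 0, 2010, 120.0)])
        out = fit_site_trends(series)
        assert len(out) == 1
        assert out.slope[0] == pytest.approx(2.0)
        assert out.n_years[0] == 2

    def test_single_year_site_skipped_and_counted(self):
        series = _series([(10, 0, 2000, 100.0), (20, 5, 2000, 90.0), (20, 5, 2005, 95.0)])
        out = fit_site_trends(series)
        assert len(out) == 1
        assert out.attrs["n_sites_skipped"] == 1

    def test_exact_line_zero_residuals(self):
        series = _series([(10, 0, 2000, 100.0), (10, 0, 2001, 103.0), (10, 0, 2002, 106.0)])
        out = fit_site_trends(series)
        assert out.slope[0] == pytest.approx(3.0)
        predicted = out.intercept[0] + out.slope[0] * series.year
        np.testing.assert_allclose(predicted, series.mean_depth, rtol=1e-9)


class TestMedianBootstrap:
    def test_degenerate_distribution(self):
        summary = median_with_bootstrap_ci(np.full(10, 0.7), n_bootstrap=200, seed=0)
        assert summary.median == pytest.approx(0.7)
        assert summary.ci_low == summary.ci_high == pytest.approx(0.7)

    def test_order_statistic(self):
        assert median_with_bootstrap_ci([-1.0, 0.0, 1.0], n_bootstrap=100, seed=0).median == 0.0

    def test_ci_contains_median_for_every_seed(self, rng):
        slopes = rng.normal(0.3, 1.0, 80)
        for seed in range(5):
            s = median_with_bootstrap_ci(slopes, n_bootstrap=500, seed=seed)
            assert s.ci_low <= s.median <= s.ci_high

    def test_invariant_under_permutation(self, rng):
        slopes = rng.normal(0, 1, 60)
        a = median_with_bootstrap_ci(slopes, n_bootstrap=500, seed=3)
        b = median_with_bootstrap_ci(slopes[::-1].copy(), n_bootstrap=500, seed=3)
        assert a.median == b.median
        # CI is a function of the multiset only up to resampling noise
        assert a.ci_low == pytest.approx(b.ci_low, abs=0.08)

    def test_ci_width_matches_median_asymptotics(self, rng):
        # SE of a sample median of n normals is ~1.2533 sd/sqrt(n)
        slopes = rng.normal(0.35, 1.0, 1600)
        s = median_with_bootstrap_ci(slopes, n_bootstrap=2000, seed=1)
        expected_width = 2 * 1.96 * 1.2533 / np.sqrt(1600)
        assert expected_width / 1.5 < (s.ci_high - s.ci_low) < expected_width * 1.5


class TestSeasonalAnomaly:
    def _clim(self):
        rows = [
            (10, 20, m, "nitrate", 100.0 + 10 * np.cos(2 * np.pi * (m - 8) / 12))
            for m in range(1, 13)
        ]
        return MonthlyClimatology(
            depths=pd.DataFrame(rows, columns=["lat_bin", "lon_bin", "month", "nutrient", "nutricline_depth_m"])
        )

    def _records(self, depth, month, lat=10.0, lon=20.0, year=2000, cast="a"):
        return pd.DataFrame(
            [(cast, "nitrate", depth, "crossed", lat, lon, year, month)],
            columns=["cast_id", "nutrient", "depth", "status", "latitude", "longitude", "year", "month"],
        )

    def test_subtraction(self):
        clim = self._clim()
        recs = self._records(120.0, 7)
        out, n_dropped = seasonal_anomaly(recs, clim)
        expected = 120.0 - (100.0 + 10 * np.cos(2 * np.pi * (7 - 8) / 12))
        assert out.depth_anomaly[0] == pytest.approx(expected)
        assert out.depth[0] == 120.0  # raw depth preserved for the >50 m filter
        assert n_dropped == 0

    def test_missing_site_dropped_and_counted(self):
        out, n_dropped = seasonal_anomaly(self._records(120.0, 7, lat=55.0), self._clim())
        assert len(out) == 0 and n_dropped == 1

    def test_anomaly_trend_recovers_imposed_slope_exactly(self):
        # observed = climatology + b (year - y0): anomalies are the pure trend
        clim = self._clim()
        b, y0 = 0.8, 2000
        rows = []
        for i, (year, month) in enumerate([(y, m) for y in range(1995, 2006) for m in (2, 7, 11)]):
            z = 100.0 + 10 * np.cos(2 * np.pi * (month - 8) / 12) + b * (year - y0)
            rows.append((f"c{i}", "nitrate", z, "crossed", 10.0, 20.0, year, month))
        recs = pd.DataFrame(rows, columns=["cast_id", "nutrient", "depth", "status", "latitude", "longitude", "year", "month"])
        out, _ = seasonal_anomaly(recs, clim)
        series = annual_average(out, value_cols=("depth", "depth_anomaly"))
        trend = fit_site_trends(series, value_col="mean_depth_anomaly")
        assert trend.slope[0] == pytest.approx(b, abs=1e-9)
        # the seasonal variance is gone from the anomalies
        assert out.depth_anomaly.std() < recs.depth.std()


class TestPairedResidual:
    def test_difference_and_exclusion(self):
        no3 = pd.DataFrame(
            [("a", "nitrate", 130.0, "crossed", 10.0, 20.0, 2000, 6),
             ("b", "nitrate", 140.0, "crossed", 10.0, 20.0, 2010, 6)],
            columns=["cast_id", "nutrient", "depth", "status", "latitude", "longitude", "year", "month"],
        )
        po4 = pd.DataFrame(
            [("a", "phosphate", 100.0, "crossed", 10.0, 20.0, 2000, 6),
             ("b", "phosphate", np.nan, "never_reached", 10.0, 20.0, 2010, 6)],
            columns=["cast_id", "nutrient", "depth", "status", "latitude", "longitude", "year", "month"],
        )
        # cast b lacks Z_PO4: only one paired year remains -> no site trend
        out = paired_residual_trend(no3, po4)
        assert len(out) == 0

    def test_generator_construction_recovers_difference_trend(self):
        cfg = SyntheticWorldConfig(
            n_sites=40,
            years=(1995, 2015),
            seed=9,
            casts_per_site_year=1.0,
            trend_dist_no3=TrendDistribution(0.0, 0.0),
            trend_dist_po4=TrendDistribution(0.5, 0.0),
            noise=ErrorModel(0.0, 0.0),
        )
        casts, _ = generate_archive(cfg)
        records = compute_all(casts)
        no3 = records[records.nutrient == "nitrate"]
        po4 = records[records.nutrient == "phosphate"]
        trends = paired_residual_trend(no3, po4)
        med = median_with_bootstrap_ci(trends, n_bootstrap=500, seed=0)
        assert med.quantity == "" and trends.quantity.unique() == ["ZNO3_minus_ZPO4"]
        assert med.median == pytest.approx(-0.5, abs=0.1)


class TestResidualTpo4:
    def test_unit_geometry(self):
        assert residual_tpo4(0.0, 1.0) == pytest.approx(1 / np.sqrt(2))
        assert residual_tpo4(1.0, 0.0) == pytest.approx(-1 / np.sqrt(2))

    def test_zero_on_diagonal_and_antisymmetric(self, rng):
        for c in rng.normal(0, 2, 20):
            assert residual_tpo4(c, c) == 0.0
        a, b = rng.normal(0, 1, 50), rng.normal(0, 1, 50)
        np.testing.assert_allclose(residual_tpo4(a, b), -residual_tpo4(b, a))


class TestSignTest:
    def test_exact_binomial_examples(self):
        assert sign_test([1.0, 1.0, 1.0, 1.0]) == pytest.approx(2 * 0.5**4)
        assert sign_test([1.0, -1.0]) == pytest.approx(1.0)
        assert sign_test([1.0] * 20) == pytest.approx(2 * 0.5**20, rel=1e-9)

    def test_zeros_dropped(self):
        assert sign_test([0.0, 0.0, 1.0, 1.0]) == pytest.approx(0.5)

    def test_all_zero_undefined(self):
        with pytest.warns(UserWarning):
            assert np.isnan(sign_test([0.0, 0.0]))


class TestKruskalWallis:
    def test_identical_groups_no_effect(self):
        h, p = kruskal_wallis([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert h == 0.0 and p == 1.0

    def test_matches_hand_rank_computation(self):
        g1, g2 = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        # ranks 1..6, no ties: H = 12/(N(N+1)) * sum(R_i^2/n_i) - 3(N+1)
        r1, r2 = 1 + 2 + 3, 4 + 5 + 6
        expected = 12 / (6 * 7) * (r1**2 / 3 + r2**2 / 3) - 3 * 7
        h, p = kruskal_wallis(g1, g2)
        assert h == pytest.approx(expected)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1.0], [2.0, 3.0])

    def test_null_calibration(self, rng):
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            _, p = kruskal_wallis(rng.normal(0, 1, 15), rng.normal(0, 1, 15))
            rejections += p < 0.05
        assert 0.015 <= rejections / n_rep <= 0.10


class TestDensityTrends:
    def _run(self, follows, b=0.6):
        from nutriclines.simulate import TwoLayerTS

        cfg = SyntheticWorldConfig(
            n_sites=30,
            years=(1995, 2015),
            seed=13,
            casts_per_site_year=1.0,
            trend_dist_no3=TrendDistribution(b, 0.0),
            trend_dist_po4=TrendDistribution(b, 0.0),
            redfield_coupled=True,
            noise=ErrorModel(0.0, 0.0),
            seasonal_amplitude=0.0,
            ts=TwoLayerTS(pycnocline_follows_nutricline=follows),
        )
        casts, truth = generate_archive(cfg)
        records = compute_all(casts)
        out = density_trends(casts, records, n_bootstrap=300, seed=1)
        return out["nitrate"][0], casts, truth

    def test_nutricline_locked_to_isopycnal_gives_zero_trend(self):
        summary, _, _ = self._run(follows=True)
        assert abs(summary.median) < 2e-3

    def test_migration_into_denser_water_recovered(self):
        from nutriclines import density_at_depth

        summary, casts, truth = self._run(follows=False)
        # expected rate: vertical density gradient at the crossing x deepening rate
        cast = casts[0]
        z = truth.loc[truth.cast_id == cast.cast_id, "z_no3_true"].iloc[0]
        grad = (density_at_depth(cast, z + 5) - density_at_depth(cast, z - 5)) / 10.0
        expected = 0.6 * grad
        assert summary.median == pytest.approx(expected, rel=0.35)

    def test_all_missing_ts_reports_counts(self):
        from conftest import make_cast

        cast = make_cast([0, 100, 150, 200, 300], nitrate=[0.5, 1.0, 2.0, 5.0, 9.0])
        records = compute_all([cast], qc=None)
        out = density_trends([cast], records)
        summary, n_missing = out["nitrate"]
        assert summary is None and n_missing == 1


class TestRegionalMedians:
    def _trends(self, rng):
        north = pd.DataFrame(
            {"lat_bin": rng.integers(5, 40, 150), "lon_bin": rng.integers(-170, 170, 150),
             "slope": rng.normal(0.1, 0.5, 150)}
        )
        south = pd.DataFrame(
            {"lat_bin": rng.integers(-40, -5, 150), "lon_bin": rng.integers(-170, 170, 150),
             "slope": rng.normal(0.6, 0.5, 150)}
        )
        return pd.concat([north, south], ignore_index=True)

    def test_single_region_equals_global(self, rng):
        trends = self._trends(rng)
        world = RegionSpec("global", ((( -90, 90), (-180, 179)),))
        out = regional_medians(trends, [world], n_bootstrap=300, seed=0)
        assert out["global"].median == pytest.approx(np.median(trends.slope))
        assert out["global"].n_sites == len(trends)

    def test_hemispheric_contrast_recovered(self, rng):
        trends = self._trends(rng)
        regions = [
            RegionSpec("north", (((0, 90), (-180, 179)),)),
            RegionSpec("south", (((-90, 0), (-180, 179)),)),
        ]
        out = regional_medians(trends, regions, n_bootstrap=500, seed=0)
        assert out["north"].ci_low <= 0.1 <= out["north"].ci_high
        assert out["south"].ci_low <= 0.6 <= out["south"].ci_high

    def test_empty_region_flagged(self, rng):
        trends = self._trends(rng)
        arctic = RegionSpec("arctic", (((80, 90), (-180, 179)),))
        out = regional_medians(trends, [arctic], n_bootstrap=100, seed=0)
        assert out["arctic"].insufficient
        assert np.isnan(out["arctic"].median)


class TestFilterExtremeTrends:
    def _trends(self, slopes):
        return pd.DataFrame({"lat_bin": 0, "lon_bin": range(len(slopes)), "slope": slopes})

    def test_out_of_bounds_removed(self):
        kept, n = filter_extreme_trends(self._trends([1.0, 12.0, -2.0]), (-5, 5))
        assert n == 1 and sorted(kept.slope) == [-2.0, 1.0]

    def test_infinite_bounds_identity(self):
        kept, n = filter_extreme_trends(self._trends([1.0, 12.0]), (-np.inf, np.inf))
        assert n == 0 and len(kept) == 2

    def test_median_robust_to_symmetric_outlier_removal(self, rng):
        slopes = np.concatenate([rng.normal(0.3, 0.5, 101), [40.0, -40.0]])
        trends = self._trends(slopes)
        kept, n = filter_extreme_trends(trends, (-10, 10))
        assert n == 2
        assert np.median(kept.slope) == pytest.approx(np.median(slopes))


class TestDeepAnomalyTrend:
    def test_observations_equal_climatology_give_zero_slope(self):
        cfg = SyntheticWorldConfig(
            n_sites=10, years=(2000, 2010), seed=17, casts_per_site_year=1.0,
            trend_dist_no3=TrendDistribution(0.0, 0.0),
            trend_dist_po4=TrendDistribution(0.0, 0.0),
            noise=ErrorModel(0.0, 0.0),
        )
        casts, _ = generate_archive(cfg)
        clim = generate_climatology(cfg)
        out = deep_anomaly_trend(casts, clim)
        assert abs(out["nitrate"].slope) < 1e-8
        assert abs(out["phosphate"].slope) < 1e-8

    def test_shallow_archive_reports_empty(self):
        cfg = SyntheticWorldConfig(
            n_sites=4, years=(2000, 2005), seed=17, casts_per_site_year=2.0,
            bottle_depths=tuple(float(z) for z in range(0, 600, 25)),
        )
        casts, _ = generate_archive(cfg)
        clim = generate_climatology(cfg)
        out = deep_anomaly_trend(casts, clim)
        assert out["nitrate"] is None
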
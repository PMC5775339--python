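import numpy as np
import pandas as pd
import pytest

import dietshift as ds


def annual(name, values, start=1997):
    return ds.AnnualSeries(name, pd.Series(
        values, index=range(start, start + len(values))))


class TestSeaIceIndex:
    @staticmethod
    def _daily(month_values, year=2005, blocks=(1, 2, 3, 4)):
        rows = []
        for month, value in month_values.items():
            days = pd.period_range(f"{year}-{month:02d}", freq="D",
                                   periods=28)
            for day in days:
                for b in blocks:
                    rows.append({"date": str(day), "block_id": b,
                                 "concentration_pct": value})
        return pd.DataFrame(rows)

    def test_full_cover_gives_100(self):
        daily = self._daily({m: 100.0 for m in range(1, 13)})
        s = ds.sea_ice_index(daily)
        assert s.values.loc[2005] == pytest.approx(100.0)

    def test_half_year_at_40_gives_20(self):
        daily = self._daily({m: (40.0 if m <= 6 else 0.0)
                             for m in range(1, 13)})
        assert ds.sea_ice_index(daily).values.loc[2005] == pytest.approx(20.0)

    def test_month_first_averaging_not_pooled_days(self):
        """One 31-day month at 100%, one 28-day month at 0%, ten at 50%:
        month-first averaging gives 50, pooling all days would not."""
        rows = []
        for month, (ndays, value) in {
            1: (31, 100.0), 2: (28, 0.0),
            **{m: (30, 50.0) for m in range(3, 13)},
        }.items():
            for day in range(1, ndays + 1):
                rows.append({"date": f"2005-{month:02d}-{day:02d}",
                             "block_id": 1, "concentration_pct": value})
        daily = pd.DataFrame(rows)
        month_first = (100 + 0 + 10 * 50) / 12
        pooled = daily["concentration_pct"].mean()
        assert month_first != pytest.approx(pooled)
        assert ds.sea_ice_index(daily).values.loc[2005] \
            == pytest.approx(month_first)

    def test_incomplete_year_dropped_with_warning(self):
        daily = self._daily({m: 50.0 for m in range(1, 12)})  # 11 months
        with pytest.warns(UserWarning, match="2005"):
            s = ds.sea_ice_index(daily)
        assert 2005 not in s.values.index

    def test_out_of_range_concentration_rejected(self):
        daily = self._daily({1: 101.0})
        with pytest.raises(ValueError, match="outside"):
            ds.sea_ice_index(daily)


class TestVolumeWeightedTemperature:
    def test_uniform_profile(self):
        assert ds.volume_weighted_temperature(
            [0, 10, 20], [3.0, 3.0, 3.0], [100, 80, 60]) == pytest.approx(3.0)

    def test_equal_volumes_average(self):
        assert ds.volume_weighted_temperature(
            [0, 10], [2.0, 4.0], [50, 50]) == pytest.approx(3.0)

    def test_three_to_one_volume_weighting(self):
        # volumes 3:1 at 4 degC and 0 degC -> (3*4 + 1*0)/4 = 3 degC
        assert ds.volume_weighted_temperature(
            [0, 10], [4.0, 0.0], [75, 25]) == pytest.approx(3.0)

    def test_increasing_area_with_depth_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            ds.volume_weighted_temperature([0, 10], [1.0, 1.0], [10, 20])

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError, match="volume"):
            ds.volume_weighted_temperature([0, 10], [1.0, 1.0], [0, 0])


class TestDetrend:
    def test_linear_series_detrends_to_zero(self):
        resid = ds.detrend(annual("s", 5 + 0.3 * np.arange(10)))
        np.testing.assert_allclose(resid.values, 0.0, atol=1e-10)

    def test_constant_series_detrends_to_zero(self):
        resid = ds.detrend(annual("s", [4.0] * 6))
        np.testing.assert_allclose(resid.values, 0.0, atol=1e-12)

    def test_pattern_orthogonal_to_trend_survives_detrending(self):
        # project an alternating +-1 pattern off {1, t} by hand; what is left
        # is orthogonal to the trend space, so detrending must return it
        n = 10
        t = np.arange(n, dtype=float)
        w = np.resize([1.0, -1.0], n)
        w = w - w.mean()
        tc = t - t.mean()
        w = w - (w @ tc) / (tc @ tc) * tc
        resid = ds.detrend(annual("s", 2 + 0.5 * t + w))
        np.testing.assert_allclose(resid.values, w, atol=1e-10)

    def test_idempotent(self):
        s = annual("s", np.random.default_rng(3).normal(size=12))
        once = ds.detrend(s)
        twice = ds.detrend(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_output_mean_zero(self):
        s = annual("s", np.random.default_rng(4).lognormal(size=15))
        assert ds.detrend(s).values.mean() == pytest.approx(0.0, abs=1e-10)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ds.detrend(annual("s", [1.0, 2.0]))


class TestCorrelate:
    def test_affine_relation_gives_r_one(self):
        x = annual("x", np.arange(10.0))
        y = annual("y", 2 * np.arange(10.0) + 1)
        res = ds.correlate(x, y)
        assert res.r == pytest.approx(1.0)
        assert res.significant

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(5)
        x = annual("x", rng.normal(size=14))
        y = annual("y", rng.normal(size=14))
        assert ds.correlate(x, y).r == pytest.approx(ds.correlate(y, x).r)

    def test_pairwise_complete_overlap(self):
        x = annual("x", [1, 2, 3, 4, 5.0], start=2000)
        y = annual("y", [5, 3, 2, 4, 1.0], start=2002)  # 3-year overlap
        with pytest.raises(ValueError, match="overlapping"):
            ds.correlate(x, y)

    def test_zero_variance_rejected(self):
        x = annual("x", [1.0] * 8)
        y = annual("y", np.arange(8.0))
        with pytest.raises(ValueError, match="variance"):
            ds.correlate(x, y)

    def test_ci_contains_r(self):
        rng = np.random.default_rng(6)
        res = ds.correlate(annual("x", rng.normal(size=19)),
                           annual("y", rng.normal(size=19)))
        lo, hi = res.ci95
        assert lo <= res.r <= hi
        assert -1 <= lo <= hi <= 1

    def test_shared_trend_significant_raw_but_not_detrended(self):
        """Two series that share only a linear trend: the raw correlation is
        trend-driven and significant, the detrended one is not.  Independent
        wiggles are constructed orthogonal so the detrended r is exactly
        their (near-zero) correlation."""
        n = 19
        t = np.arange(n, dtype=float)
        wiggle_x = np.resize([1.0, -1.0], n)               # period 2
        wiggle_y = np.resize([1.0, 1.0, -1.0, -1.0], n)    # period 4
        x = annual("x", 2.0 * t + wiggle_x)
        y = annual("y", -1.5 * t + 0.9 * wiggle_y)
        raw = ds.correlate(x, y)
        det = ds.correlate(x, y, detrended=True)
        assert raw.significant and abs(raw.r) > 0.9
        assert not det.significant

    def test_genuinely_coupled_pair_stays_significant_after_detrending(self):
        rng = np.random.default_rng(8)
        t = np.arange(19, dtype=float)
        shared = rng.normal(size=19)
        x = annual("x", 1.0 * t + shared)
        y = annual("y", -0.5 * t + shared + 0.2 * rng.normal(size=19))
        det = ds.correlate(x, y, detrended=True)
        assert det.significant and det.r > 0.7

    def test_fisher_ci_covers_zero_at_nominal_rate(self):
        """Null coverage check: independent white-noise pairs, n=19."""
        rng = np.random.default_rng(12)
        n_reps, covered = 400, 0
        for _ in range(n_reps):
            x = annual("x", rng.normal(size=19))
            y = annual("y", rng.normal(size=19))
            covered += not ds.correlate(x, y).significant
        assert covered / n_reps == pytest.approx(0.95, abs=0.03)


class TestTrendRegression:
    def test_noiseless_decline_recovered(self):
        fit = ds.trend_regression(annual("ww", 25.0 - 0.7 * np.arange(19)))
        assert fit.slope == pytest.approx(-0.7)
        assert fit.intercept == pytest.approx(25.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_series_flat_with_undefined_f(self):
        fit = ds.trend_regression(annual("s", [3.0] * 10))
        assert fit.slope == 0.0
        assert np.isnan(fit.f_statistic)

    def test_f_equals_squared_t_of_slope(self):
        rng = np.random.default_rng(9)
        fit = ds.trend_regression(annual("s", rng.normal(size=15)))
        t_slope = fit.slope / fit.slope_se
        assert fit.f_statistic == pytest.approx(t_slope ** 2)

    def test_slope_ci_covers_truth_at_nominal_rate(self):
        """Recovery simulation at generator-like noise (slope -0.5, sd 4)."""
        from scipy import stats

        rng = np.random.default_rng(10)
        n_reps, covered = 400, 0
        t = np.arange(20, dtype=float)
        crit = stats.t.ppf(0.975, len(t) - 2)
        for _ in range(n_reps):
            y = 19.9 - 0.5 * t + rng.normal(0, 4, len(t))
            fit = ds.trend_regression(annual("ice", y))
            covered += abs(fit.slope - (-0.5)) <= crit * fit.slope_se
        assert covered / n_reps == pytest.approx(0.95, abs=0.03)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ds.trend_regression(annual("s", [1.0, 2.0]))
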
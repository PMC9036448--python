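import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from spectraits.rue_blues import (
    BLUEModelSpec, WeatherSeries, accumulate_ipar,
    correlate_predictions_with_rue, fit_blues, rue_slope,
)


def _weather(n_days=30, irradiance=20.0, start="2020-01-01"):
    dates = pd.date_range(start, periods=n_days)
    return WeatherSeries(pd.DataFrame({
        "date": dates, "irradiance": np.full(n_days, irradiance)}))


class TestInterceptedPAR:
    def test_constant_case(self):
        wx = _weather()
        total = accumulate_ipar(wx, [("2020-01-01", 1.0)],
                                ("2020-01-01", "2020-01-10"))
        assert total == pytest.approx(20 * 0.45 * 10)

    def test_zero_fapar_zero_ipar(self):
        wx = _weather()
        assert accumulate_ipar(wx, [("2020-01-01", 0.0)],
                               ("2020-01-01", "2020-01-10")) == 0.0

    def test_interpolated_fapar_matches_day_by_day_sum(self):
        wx = _weather(n_days=11)
        readings = [("2020-01-01", 0.5), ("2020-01-11", 1.0)]
        total = accumulate_ipar(wx, readings, ("2020-01-01", "2020-01-11"))
        expected = sum(20 * 0.45 * (0.5 + 0.05 * d) for d in range(11))
        assert total == pytest.approx(expected)

    def test_additive_over_adjacent_windows(self):
        wx = _weather(n_days=20)
        readings = [("2020-01-01", 0.3), ("2020-01-20", 0.9)]
        whole = accumulate_ipar(wx, readings, ("2020-01-01", "2020-01-20"))
        first = accumulate_ipar(wx, readings, ("2020-01-01", "2020-01-10"))
        second = accumulate_ipar(wx, readings, ("2020-01-11", "2020-01-20"))
        assert whole == pytest.approx(first + second)

    def test_fapar_held_constant_beyond_last_reading(self):
        wx = _weather(n_days=10)
        total = accumulate_ipar(wx, [("2020-01-01", 0.5)],
                                ("2020-01-06", "2020-01-10"))
        assert total == pytest.approx(20 * 0.45 * 0.5 * 5)

    def test_no_reading_before_window_rejected(self):
        wx = _weather(n_days=30)
        with pytest.raises(ValueError, match="fAPAR"):
            accumulate_ipar(wx, [("2020-01-25", 0.8)],
                            ("2020-01-01", "2020-01-10"))

    def test_window_outside_weather_rejected(self):
        wx = _weather(n_days=5)
        with pytest.raises(ValueError, match="weather"):
            accumulate_ipar(wx, [("2020-01-01", 1.0)],
                            ("2020-01-01", "2020-02-01"))


class TestRUESlope:
    def test_exact_line(self):
        x = np.array([100.0, 300, 500, 800])
        est = rue_slope(np.c_[x, 1.2 * x + 50])
        assert est.slope == pytest.approx(1.2)
        assert est.intercept == pytest.approx(50.0)
        assert est.r2 == pytest.approx(1.0)

    def test_two_points_is_difference_quotient(self):
        est = rue_slope([(100.0, 250.0), (300.0, 850.0)])
        assert est.slope == pytest.approx((850 - 250) / (300 - 100))
        assert est.n == 2

    def test_intercept_shift_leaves_slope(self, rng):
        x = rng.uniform(100, 900, 10)
        y = 2.5 * x + rng.normal(0, 20, 10)
        s1 = rue_slope(np.c_[x, y]).slope
        s2 = rue_slope(np.c_[x, y + 500.0]).slope
        assert s1 == pytest.approx(s2)

    def test_recovers_true_rue_under_multiplicative_noise(self):
        """Mean slope over 200 noisy 4-stage trajectories within 5% of truth."""
        rng = np.random.default_rng(3)
        cum = np.array([150.0, 400.0, 700.0, 950.0])
        sigma = np.sqrt(np.log1p(0.05 ** 2))
        slopes = [rue_slope(np.c_[cum, 3.0 * cum *
                                  np.exp(rng.normal(-sigma ** 2 / 2, sigma, 4))]
                            ).slope
                  for _ in range(200)]
        assert np.mean(slopes) == pytest.approx(3.0, rel=0.05)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            rue_slope([(100.0, 1.0), (100.0, 2.0)])


def _mixed_model_data(seed, g_sd=2.0, n_geno=11, n_env=3, n_rep=3):
    rng = np.random.default_rng(seed)
    g_eff = rng.normal(0, g_sd, n_geno)
    env = rng.normal(0, 2, n_env)
    rep = rng.normal(0, 1, (n_env, n_rep))
    gxe = rng.normal(0, 1, (n_env, n_geno))
    rows = []
    for e in range(n_env):
        for r in range(n_rep):
            for g in range(n_geno):
                rows.append({
                    "genotype": f"G{g:02d}", "env": f"E{e}", "rep": f"R{r}",
                    "y": 10 + g_eff[g] + env[e] + rep[e, r] + gxe[e, g]
                         + rng.normal(0, 1),
                })
    return pd.DataFrame(rows), g_eff


class TestBLUEs:
    def test_balanced_single_env_equals_raw_means(self):
        rows = [{"genotype": f"G{g}", "env": "E0", "rep": f"R{r}",
                 "y": 5.0 + 2 * g}
                for g in range(4) for r in range(3)]
        table = fit_blues(pd.DataFrame(rows), BLUEModelSpec(response="y"))
        np.testing.assert_allclose(table["blue"], [5.0, 7.0, 9.0, 11.0],
                                   atol=1e-8)

    def test_location_equivariance(self):
        df, _ = _mixed_model_data(0)
        t1 = fit_blues(df, BLUEModelSpec(response="y"))
        df2 = df.assign(y=df["y"] + 100.0)
        t2 = fit_blues(df2, BLUEModelSpec(response="y"))
        np.testing.assert_allclose(t2["blue"], t1["blue"] + 100.0, atol=1e-6)

    def test_recovers_genotype_ranking(self):
        corrs = []
        for seed in range(10):
            df, g_eff = _mixed_model_data(seed)
            table = fit_blues(df, BLUEModelSpec(response="y"))
            order = [f"G{g:02d}" for g in range(len(g_eff))]
            blues = table.set_index("genotype").loc[order, "blue"]
            corrs.append(sps.spearmanr(blues, g_eff).statistic)
        assert np.mean(corrs) >= 0.8

    def test_covariate_adjustment_at_mean(self):
        # response depends linearly on the covariate; BLUEs at the covariate
        # mean must remove that dependence
        rng = np.random.default_rng(1)
        rows = []
        for g in range(5):
            for r in range(4):
                cov = rng.uniform(60, 80)
                rows.append({"genotype": f"G{g}", "env": "E0", "rep": f"R{r}",
                             "days": cov, "y": 3.0 + g + 0.5 * (cov - 70)})
        frame = pd.DataFrame(rows)
        spec = BLUEModelSpec(response="y", covariate="days")
        table = fit_blues(frame, spec)
        shift = 0.5 * (frame["days"].mean() - 70.0)  # means sit at c-bar
        np.testing.assert_allclose(table["blue"],
                                   3.0 + np.arange(5) + shift, atol=0.05)

    def test_single_genotype_rejected(self):
        rows = [{"genotype": "G0", "env": "E0", "rep": f"R{r}", "y": 1.0}
                for r in range(3)]
        with pytest.raises(ValueError, match="genotypes"):
            fit_blues(pd.DataFrame(rows), BLUEModelSpec(response="y"))


class TestRUECorrelation:
    def test_perfect_linear_relation(self):
        pred = pd.DataFrame({"genotype": list("abcde"),
                             "blue": [1.0, 2, 3, 4, 5]})
        rue = pd.DataFrame({"genotype": list("abcde"),
                            "slope": [2.0, 4, 6, 8, 10]})
        report = correlate_predictions_with_rue(pred, rue)
        assert report["r2"] == pytest.approx(1.0)
        assert report["slope"] == pytest.approx(2.0)
        assert report["n"] == 5

    def test_too_few_genotypes_rejected(self):
        pred = pd.DataFrame({"genotype": ["a", "b"], "blue": [1.0, 2.0]})
        rue = pd.DataFrame({"genotype": ["a", "b"], "slope": [1.0, 2.0]})
        with pytest.raises(ValueError, match="at least 3"):
            correlate_predictions_with_rue(pred, rue)

    def test_null_linkage_gives_null_distribution(self):
        """With RUE independent of the trait, R² stays consistent with the
        null: the 75th percentile of R² over replicates is small."""
        rng = np.random.default_rng(9)
        r2s = []
        for _ in range(100):
            pred = pd.DataFrame({"genotype": [f"g{i}" for i in range(11)],
                                 "blue": rng.normal(size=11)})
            rue = pd.DataFrame({"genotype": [f"g{i}" for i in range(11)],
                                "slope": rng.normal(size=11)})
            r2s.append(correlate_predictions_with_rue(pred, rue)["r2"])
        # under H0 with n=11, E[R^2] = 1/(n-1) = 0.1
        assert np.mean(r2s) == pytest.approx(0.1, abs=0.05)
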
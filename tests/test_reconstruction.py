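"""Transfer-function calibration, validation statistics, and reconstruction."""

import numpy as np
import pandas as pd
import pytest

from dendrorecon.reconstruction import (TransferModel, coefficient_of_efficiency,
                                        durbin_watson, fit_transfer, loocv,
                                        product_mean_test, reconstruct,
                                        reduction_of_error, sign_test, split_sample)


def yr_series(vals, start=1965):
    return pd.Series(np.asarray(vals, float), index=np.arange(start, start + len(vals)))


@pytest.fixture(scope="module")
def linear_pair():
    """Noise-free exact linear relation over 54 years."""
    rng = np.random.default_rng(0)
    x = yr_series(1 + 0.2 * rng.normal(0, 1, 54))
    y = 2.0 * x + 1.0
    return x, y


class TestFitTransfer:
    def test_exact_linear_relation(self, linear_pair):
        x, y = linear_pair
        m = fit_transfer(x, y)
        assert m.slope == pytest.approx(2.0, abs=1e-10)
        assert m.intercept == pytest.approx(1.0, abs=1e-10)
        assert m.stats["R2"] == pytest.approx(1.0, abs=1e-12)
        assert m.stats["RMSE"] == pytest.approx(0.0, abs=1e-10)

    def test_r_squared_identity_and_adjusted_below(self):
        rng = np.random.default_rng(1)
        x = yr_series(rng.normal(0, 1, 54))
        y = yr_series(0.5 * x.to_numpy() + rng.normal(0, 1, 54))
        m = fit_transfer(x, y)
        assert m.stats["R2"] == pytest.approx(m.stats["r"] ** 2, abs=1e-12)
        assert m.stats["R2adj"] <= m.stats["R2"]

    def test_published_coefficient_arithmetic(self):
        """A fitted model with slope 430.6 and intercept -107.51 predicts
        107.79 mm at an index value of 0.5 (transfer-function arithmetic)."""
        m = TransferModel(slope=430.6, intercept=-107.51,
                          cal_years=np.arange(1965, 2019), stats={"RMSE": 76.94})
        assert m.predict(0.5) == pytest.approx(430.6 * 0.5 - 107.51, abs=1e-12)
        assert m.predict(0.5) == pytest.approx(107.79, abs=1e-10)

    def test_null_relation_f_p_uniform(self):
        rng = np.random.default_rng(2)
        ps = []
        for _ in range(200):
            x = yr_series(rng.normal(0, 1, 40))
            y = yr_series(rng.normal(0, 1, 40))
            ps.append(fit_transfer(x, y).stats["p"])
        # KS check against uniformity
        from scipy import stats
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_zero_variance_predictor_rejected(self):
        x = yr_series(np.ones(30))
        y = yr_series(np.arange(30.0))
        with pytest.raises(ValueError, match="zero-variance"):
            fit_transfer(x, y)


class TestSignTest:
    def test_identical_series_all_agree(self):
        obs = np.array([1.0, 3, 2, 5, 4, 6])
        a, d, p = sign_test(obs, obs)
        assert (a, d) == (5, 0)

    def test_mirrored_series_all_disagree(self):
        obs = np.array([1.0, 3, 2, 5, 4])
        a, d, _ = sign_test(obs, -obs)
        assert (a, d) == (0, 4)

    def test_hand_enumerated_case(self):
        obs = np.array([1.0, 3, 2, 5, 4])
        pred = np.array([2.0, 4, 1, 6, 5])
        a, d, p = sign_test(obs, pred)
        assert (a, d) == (4, 0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sign_test([1, 2], [1, 2])


class TestProductMeanTest:
    def test_perfect_association_degenerate(self):
        obs = np.array([1.0, 2, 3, 4, 5, 6])
        t, degen = product_mean_test(obs, obs, cal_mean=3.5)
        assert degen and t == np.inf

    def test_hand_computed_case(self):
        # departures obs: (-2,-1,1,2,-1,2,1,-2), pred: (-2,-2,2,1,1,-2,1,1)
        # products: (4,2,2,2,-1,-4,1,-2) -> pos {4,2,2,2,1} neg_abs {1,4,2}
        obs = np.array([1.0, 2, 4, 5, 2, 5, 4, 1])
        pred = np.array([1.0, 1, 5, 4, 4, 1, 4, 4])
        cal_mean = 3.0
        z = (obs - cal_mean) * (pred - cal_mean)
        pos, neg = z[z > 0], np.abs(z[z < 0])
        expected = (pos.mean() - neg.mean()) / np.sqrt(
            pos.std(ddof=1) ** 2 / len(pos) + neg.std(ddof=1) ** 2 / len(neg))
        t, degen = product_mean_test(obs, pred, cal_mean)
        assert not degen
        assert t == pytest.approx(expected, abs=1e-12)

    def test_independent_series_centred_near_zero(self):
        rng = np.random.default_rng(3)
        ts = []
        for _ in range(300):
            obs = rng.normal(0, 1, 30)
            pred = rng.normal(0, 1, 30)
            t, degen = product_mean_test(obs, pred, 0.0)
            if not degen:
                ts.append(t)
        assert abs(np.median(ts)) < 0.3


class TestDurbinWatson:
    def test_white_noise_near_two(self):
        rng = np.random.default_rng(4)
        assert durbin_watson(rng.normal(0, 1, 2000)) == pytest.approx(2.0, abs=0.2)

    def test_alternating_residuals_hand_arithmetic(self):
        # n=6 alternating +1/-1: sum diff^2 = 5*4 = 20, sum e^2 = 6 -> 10/3
        e = np.array([1.0, -1, 1, -1, 1, -1])
        assert durbin_watson(e) == pytest.approx(20 / 6, abs=1e-12)

    def test_constant_residuals_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            durbin_watson(np.zeros(10))


class TestSkillScores:
    def test_re_zero_for_calibration_mean_prediction(self):
        obs = np.array([3.0, 5, 4, 6, 2])
        pred = np.full(5, 4.0)
        assert reduction_of_error(obs, pred, cal_mean=4.0) == pytest.approx(0.0)

    def test_insample_re_equals_r2_identity(self):
        rng = np.random.default_rng(5)
        for seed in range(20):
            x = rng.normal(0, 1, 40)
            y = 1.3 * x + rng.normal(0, 1, 40)
            slope, icept = np.polyfit(x, y, 1)
            pred = slope * x + icept
            r2 = np.corrcoef(x, y)[0, 1] ** 2
            assert reduction_of_error(y, pred, y.mean()) == pytest.approx(r2, abs=1e-10)

    def test_re_geq_ce_on_random_splits(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            obs = rng.normal(0, 1, 25)
            pred = rng.normal(0, 1, 25)
            cal_mean = rng.normal(0, 1)
            re = reduction_of_error(obs, pred, cal_mean)
            ce = coefficient_of_efficiency(obs, pred)
            assert re >= ce - 1e-12

    def test_re_equals_ce_when_means_match(self):
        rng = np.random.default_rng(7)
        obs = rng.normal(0, 1, 30)
        pred = rng.normal(0, 1, 30)
        assert reduction_of_error(obs, pred, obs.mean()) == pytest.approx(
            coefficient_of_efficiency(obs, pred), abs=1e-12)


class TestLoocv:
    def test_perfect_data_perfect_scores(self, linear_pair):
        x, y = linear_pair
        v = loocv(x, y)
        assert v.RE == pytest.approx(1.0, abs=1e-10)
        assert v.RMSE == pytest.approx(0.0, abs=1e-9)
        assert v.PRESS == pytest.approx(0.0, abs=1e-12)
        assert v.sign_disagree == 0

    def test_loocv_r2_below_insample_on_noisy_data(self):
        rng = np.random.default_rng(8)
        diffs = []
        for seed in range(30):
            x = yr_series(rng.normal(0, 1, 54))
            y = yr_series(1.0 * x.to_numpy() + rng.normal(0, 1, 54))
            m = fit_transfer(x, y)
            v = loocv(x, y)
            diffs.append(m.stats["R2"] - v.R2)
        assert np.median(diffs) > 0

    def test_press_is_sum_of_squared_loocv_residuals(self):
        rng = np.random.default_rng(9)
        x = yr_series(rng.normal(0, 1, 30))
        y = yr_series(0.8 * x.to_numpy() + rng.normal(0, 0.5, 30))
        v = loocv(x, y)
        assert v.PRESS == pytest.approx(30 * v.RMSE ** 2, rel=1e-10)


class TestSplitSample:
    def test_noise_free_re_ce_unity_both_directions(self, linear_pair):
        x, y = linear_pair
        out = split_sample(x, y)
        for block in out.values():
            assert block["verification"]["RE"] == pytest.approx(1.0, abs=1e-9)
            assert block["verification"]["CE"] == pytest.approx(1.0, abs=1e-9)

    def test_hand_computed_integer_dataset(self):
        """5/5 split of a 10-point integer dataset: RE and CE on the late
        half verified against explicit arithmetic."""
        x = yr_series([1.0, 2, 3, 4, 5, 1, 2, 3, 4, 5], start=1990)
        y = yr_series([3.0, 5, 7, 9, 11, 4, 5, 8, 9, 12], start=1990)
        out = split_sample(x, y, split_year=1994, min_half=5)
        # calibration 1990-94: y = 2x+1 exactly; predictions on 1995-99:
        # (3,5,7,9,11); obs (4,5,8,9,12); errors (1,0,1,0,1) -> SSE=3
        # cal mean = 7 -> RE = 1 - 3/sum((obs-7)^2)=1-3/(9+4+1+4+25)=1-3/43
        # ver mean = 7.6 -> CE = 1 - 3/sum((obs-7.6)^2) = 1 - 3/40.2... wait:
        # (4-7.6)^2+(5-7.6)^2+(8-7.6)^2+(9-7.6)^2+(12-7.6)^2
        obs = np.array([4.0, 5, 8, 9, 12])
        sse_null_cal = np.sum((obs - 7.0) ** 2)
        sse_null_ver = np.sum((obs - obs.mean()) ** 2)
        v = out["early_cal"]["verification"]
        assert v["RE"] == pytest.approx(1 - 3 / sse_null_cal, abs=1e-10)
        assert v["CE"] == pytest.approx(1 - 3 / sse_null_ver, abs=1e-10)
        assert v["RE"] >= v["CE"]

    def test_short_halves_rejected(self):
        x = yr_series(np.arange(15.0) + np.random.default_rng(0).normal(0, 0.1, 15))
        y = 2 * x
        with pytest.raises(ValueError, match="too short"):
            split_sample(x, y, split_year=int(x.index[4]))


class TestReconstruct:
    def test_mean_index_maps_to_mean_climate(self, linear_pair):
        x, y = linear_pair
        m = fit_transfer(x, y)
        const = pd.Series(np.full(100, x.mean()), index=np.arange(1900, 2000))
        rec = reconstruct(m, const, 1900)
        np.testing.assert_allclose(rec.values, y.mean(), rtol=1e-12)

    def test_truncation_year_respected_and_band_symmetric(self, linear_pair):
        x, y = linear_pair
        m = fit_transfer(x, y)
        rng = np.random.default_rng(10)
        ch = pd.Series(1 + 0.2 * rng.normal(0, 1, 300), index=np.arange(1719, 2019))
        rec = reconstruct(m, ch, 1800)
        assert rec.years[0] == 1800 and rec.years[-1] == 2018
        np.testing.assert_allclose(rec.upper - rec.values, rec.values - rec.lower)

    def test_truncation_outside_span_rejected(self, linear_pair):
        x, y = linear_pair
        m = fit_transfer(x, y)
        ch = pd.Series(np.ones(50), index=np.arange(1900, 1950))
        with pytest.raises(ValueError, match="outside"):
            reconstruct(m, ch, 1700)

    def test_negative_predictions_flagged(self):
        m = TransferModel(slope=400.0, intercept=-350.0,
                          cal_years=np.arange(1965, 2019), stats={"RMSE": 40.0})
        ch = pd.Series([0.5, 1.0, 2.0], index=[1900, 1901, 1902])
        rec = reconstruct(m, ch, 1900)
        assert list(rec.negative_years) == [1900]


class TestSlopeRecoveryCoverage:
    def test_ci_covers_true_slope_at_nominal_rate(self):
        """95% CI of the calibration slope covers the true effective slope
        in ~95% of seeds (linear forcing with AR(1) predictor noise)."""
        import statsmodels.api as sm
        rng = np.random.default_rng(11)
        true_slope, true_icept = 300.0, -50.0
        hits = 0
        n_seeds = 200
        for _ in range(n_seeds):
            x = 1 + 0.2 * rng.normal(0, 1, 54)
            y = true_slope * x + true_icept + rng.normal(0, 40, 54)
            res = sm.OLS(y, sm.add_constant(x)).fit()
            lo, hi = res.conf_int()[1]
            hits += lo <= true_slope <= hi
        assert hits / n_seeds == pytest.approx(0.95, abs=0.05)
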
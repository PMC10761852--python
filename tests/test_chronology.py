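"""Detrending, prewhitening, robust averaging and signal-strength statistics."""

import numpy as np
import pandas as pd
import pytest

from dendrorecon.chronology import (biweight_mean, build_chronology, detrend_negexp,
                                    eps_from_rbar, mean_sensitivity, pca_sites,
                                    prewhiten, running_rbar_eps, truncate_by_eps)
from dendrorecon.synthetic import ForestSimConfig, simulate_forest
from dendrorecon.types import RingSeries, SiteCollection

from conftest import ar1_series


def biweight_oracle(x, c=9.0, tol=1e-12, iters=500):
    """Independent brute-force fixed-point iteration for the Tukey biweight
    location (median start, MAD scale, explicit loop)."""
    x = np.asarray(x, float)
    m = np.median(x)
    for _ in range(iters):
        s = np.median(np.abs(x - m))
        if s == 0:
            return m
        u = (x - m) / (c * s)
        w = np.clip(1 - u ** 2, 0, None) ** 2
        m_new = np.sum(w * x) / np.sum(w)
        if abs(m_new - m) < tol:
            return m_new
        m = m_new
    return m


class TestDetrend:
    def test_model_true_negexp_gives_unit_index(self):
        t = np.arange(1, 201)
        w = 2.0 * np.exp(-0.05 * t) + 0.5
        d = detrend_negexp(RingSeries("A", 1800, w))
        assert d.curve == "negexp"
        np.testing.assert_allclose(d.index, 1.0, atol=1e-6)

    def test_constant_series_falls_back_to_mean(self):
        d = detrend_negexp(RingSeries("A", 1900, np.full(60, 1.50)))
        assert d.curve == "mean"
        np.testing.assert_allclose(d.index, 1.0, atol=1e-12)

    def test_increasing_series_uses_fallback_with_mean_one_index(self):
        w = np.linspace(0.5, 3.0, 80)
        d = detrend_negexp(RingSeries("A", 1900, w))
        assert d.curve in ("mean", "line")
        assert d.index.mean() == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_series_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            detrend_negexp(RingSeries("A", 1900, np.zeros(20)))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            detrend_negexp(RingSeries("A", 1900, np.ones(5)))

    def test_mean_fallback_index_mean_is_one_property(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            w = rng.uniform(0.2, 3.0, size=rng.integers(15, 120))
            d = detrend_negexp(RingSeries("A", 1900, w))
            if d.curve == "mean":
                assert d.index.mean() == pytest.approx(1.0, abs=1e-9)
            else:  # ratio detrending carries a small bias only
                assert d.index.mean() == pytest.approx(1.0, abs=0.05)


class TestPrewhiten:
    def test_ar1_coefficient_recovered_and_residual_white(self):
        rng = np.random.default_rng(3)
        x = 1.0 + ar1_series(rng, 500, 0.7, sd=0.2)
        d = prewhiten(
            detrend_negexp(RingSeries("A", 1500, np.maximum(x, 0.01))), max_order=3)
        assert d.ar_order >= 1
        r1 = np.corrcoef(d.index[:-1], d.index[1:])[0, 1]
        assert abs(r1) < 0.1

    def test_white_noise_mostly_selects_order_zero(self):
        rng = np.random.default_rng(1)
        orders = []
        for _ in range(60):
            idx = 1.0 + rng.normal(0, 0.2, 300)
            from dendrorecon.chronology import DetrendedSeries
            d = DetrendedSeries("A", 1700, idx, "mean")
            orders.append(prewhiten(d, max_order=3).ar_order)
        assert np.mean(np.array(orders) == 0) > 0.5

    def test_constant_series_unchanged_order_zero(self):
        from dendrorecon.chronology import DetrendedSeries
        d = DetrendedSeries("A", 1900, np.full(100, 1.0), "mean")
        out = prewhiten(d, max_order=3)
        assert out.ar_order == 0
        np.testing.assert_array_equal(out.index, d.index)

    def test_residual_autocorrelation_below_standard(self):
        rng = np.random.default_rng(5)
        x = 1.0 + ar1_series(rng, 400, 0.6, sd=0.15)
        from dendrorecon.chronology import DetrendedSeries
        d = DetrendedSeries("A", 1600, x, "mean")
        res = prewhiten(d, max_order=3)
        ac_std = abs(np.corrcoef(x[:-1], x[1:])[0, 1])
        ac_res = abs(np.corrcoef(res.index[:-1], res.index[1:])[0, 1])
        assert ac_res < ac_std


class TestBiweight:
    def test_symmetric_sample(self):
        assert biweight_mean([0.8, 1.0, 1.2]) == pytest.approx(1.0, abs=1e-12)

    def test_singleton_and_pairs_are_arithmetic(self):
        assert biweight_mean([3.7]) == 3.7
        assert biweight_mean([1.0, 2.0]) == 1.5

    def test_outlier_downweighted_and_matches_oracle(self):
        x = np.array([1.0] * 9 + [10.0])
        m = biweight_mean(x)
        assert 1.0 <= m < 1.9
        assert m == pytest.approx(biweight_oracle(x), abs=1e-8)

    def test_matches_oracle_on_contaminated_samples(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = rng.integers(5, 40)
            x = rng.normal(1.0, 0.2, n)
            x[rng.integers(0, n)] += rng.choice([-5, 5]) * rng.uniform(1, 3)
            assert biweight_mean(x) == pytest.approx(biweight_oracle(x), abs=1e-8)

    def test_matches_arithmetic_mean_on_clean_symmetric_samples(self):
        x = np.concatenate([np.linspace(0.9, 1.1, 11)])
        assert biweight_mean(x) == pytest.approx(x.mean(), abs=1e-9)

    def test_outlier_influence_bounded(self):
        base = list(np.linspace(0.8, 1.2, 9))
        far = biweight_mean(base + [1e3])
        farther = biweight_mean(base + [1e9])
        assert far == pytest.approx(farther, abs=1e-6)


class TestRbarEps:
    def test_identical_series_give_unit_rbar_eps(self):
        years = np.arange(1800, 1900)
        rng = np.random.default_rng(0)
        base = pd.Series(1 + rng.normal(0, 0.2, 100), index=years)
        frame = pd.DataFrame({f"S{i}": base for i in range(5)})
        for (_, _, rbar, eps, _) in running_rbar_eps(frame, window=50, overlap=25):
            assert rbar == pytest.approx(1.0, abs=1e-12)
            assert eps == pytest.approx(1.0, abs=1e-12)

    def test_equicorrelated_series_match_closed_form(self):
        # signal:noise variance 1:1 -> rbar ~ 0.5, EPS ~ 10*0.5/(10*0.5+0.5)
        rng = np.random.default_rng(8)
        n, k = 500, 10
        years = np.arange(1300, 1300 + n)
        signal = rng.normal(0, 1, n)
        frame = pd.DataFrame(
            {f"S{i}": pd.Series(signal + rng.normal(0, 1, n), index=years)
             for i in range(k)})
        wins = running_rbar_eps(frame, window=n, overlap=0)
        assert len(wins) == 1
        _, _, rbar, eps, depth = wins[0]
        assert rbar == pytest.approx(0.5, abs=0.05)
        assert eps == pytest.approx(10 * 0.5 / (10 * 0.5 + 0.5), abs=0.05)
        assert depth == k

    def test_independent_noise_gives_near_zero(self):
        rng = np.random.default_rng(9)
        years = np.arange(1500, 2000)
        frame = pd.DataFrame({f"S{i}": pd.Series(rng.normal(0, 1, 500), index=years)
                              for i in range(8)})
        _, _, rbar, eps, _ = running_rbar_eps(frame, window=500, overlap=0)[0]
        assert abs(rbar) < 0.05
        assert eps < 0.35  # EPS inflates small rbar by N; stays far from 1

    def test_eps_monotone_in_n_and_rbar(self):
        grid_r = np.linspace(0.05, 0.95, 10)
        grid_n = np.arange(2, 40, 4)
        for r in grid_r:
            eps_n = [eps_from_rbar(r, n) for n in grid_n]
            assert np.all(np.diff(eps_n) >= -1e-12)
        for n in grid_n:
            eps_r = [eps_from_rbar(r, n) for r in grid_r]
            assert np.all(np.diff(eps_r) >= -1e-12)


def _flat_eps_chronology(eps_values, start=1300, window=50, overlap=25):
    """Build a Chronology shell with prescribed running EPS values."""
    from dendrorecon.chronology import Chronology
    step = window - overlap
    wins = []
    y = start
    for e in eps_values:
        wins.append((y, y + window - 1, 0.5, e, 10))
        y += step
    years = np.arange(start, wins[-1][1] + 1)
    return Chronology(years=years, standard=np.ones(len(years)), residual=None,
                      sample_depth=np.full(len(years), 10), rbar_windows=wins)


class TestTruncation:
    def test_all_windows_good_returns_first_year(self):
        ch = _flat_eps_chronology([0.9] * 8)
        assert truncate_by_eps(ch, 0.85) == ch.years[0]

    def test_step_eps_returns_step_year(self):
        # below threshold for the first 4 windows, above thereafter
        ch = _flat_eps_chronology([0.80] * 4 + [0.95] * 6, start=1300)
        assert truncate_by_eps(ch, 0.85) == 1300 + 4 * 25

    def test_flicker_ignored_before_final_crossing(self):
        ch = _flat_eps_chronology([0.9, 0.7, 0.9, 0.9, 0.9])
        assert truncate_by_eps(ch, 0.85) == 1300 + 2 * 25

    def test_never_reaching_threshold_reports_max(self):
        ch = _flat_eps_chronology([0.5, 0.6, 0.7])
        with pytest.raises(ValueError, match="0.700"):
            truncate_by_eps(ch, 0.85)

    def test_depth_driven_truncation_matches_closed_form(self, small_forest):
        # with known rbar, EPS >= 0.85 requires N >= 0.85(1-rbar)/(0.15*rbar);
        # the returned year must lie within one window of where depth crosses it
        sites, _ = small_forest
        from dendrorecon.types import pool
        ch = build_chronology(pool(sites), prewhiten_series=False)
        year = truncate_by_eps(ch, 0.85)
        wins = [w for w in ch.rbar_windows if np.isfinite(w[3])]
        rbar = np.median([w[2] for w in wins])
        n_req = 0.85 * (1 - rbar) / (0.15 * rbar)
        depth = pd.Series(ch.sample_depth, index=ch.years)
        crossing = depth[depth >= n_req].index.min()
        assert abs(year - crossing) <= 50


class TestBuildChronology:
    def test_noise_free_uncoupled_forest_gives_unit_chronology(self, small_climate):
        mc, _ = small_climate
        cfg = ForestSimConfig(n_sites=1, trees_per_site=4, beta=0.0, gamma=0.0,
                              phi_b=0.0, tree_sd=0.0, core_sd=0.0,
                              min_tree_age=100, max_tree_age=250, seed=0)
        sites, _ = simulate_forest(cfg, mc)
        ch = build_chronology(sites[0], prewhiten_series=False)
        # widths follow the age trend exactly (up to 0.01 mm recording)
        assert np.nanstd(ch.standard) < 0.02
        np.testing.assert_allclose(ch.standard, 1.0, atol=0.06)

    def test_pooling_identical_collections_is_idempotent(self, small_forest):
        sites, _ = small_forest
        one = build_chronology(sites[0], prewhiten_series=False)
        # pooling the same collection twice under distinct ids
        import copy
        dup = copy.deepcopy(sites[0])
        dup2 = copy.deepcopy(sites[0])
        for s in dup2.series:
            s.series_id = s.series_id.replace("S1", "S9")
        both = build_chronology(
            SiteCollection("P", dup.series + dup2.series), prewhiten_series=False)
        joint = pd.concat([one.series("standard"), both.series("standard")],
                          axis=1).dropna()
        np.testing.assert_allclose(joint.iloc[:, 0], joint.iloc[:, 1], atol=1e-9)

    def test_composite_correlates_with_sites_under_common_forcing(self, small_forest):
        sites, _ = small_forest
        chron_sites = [build_chronology(s) for s in sites]
        from dendrorecon.types import pool
        comp = build_chronology(pool(sites))
        pair = pd.concat([c.series("residual") for c in chron_sites], axis=1,
                         keys=["a", "b"]).dropna()
        site_pair_r = pair.corr().iloc[0, 1]
        for c in chron_sites:
            j = pd.concat([comp.series("residual"), c.series("residual")], axis=1).dropna()
            assert j.corr().iloc[0, 1] > site_pair_r - 0.05

    def test_residual_variance_not_above_standard_for_persistent_input(self, small_forest):
        sites, _ = small_forest
        ch = build_chronology(pool_sites := sites[0], prewhiten_series=True)
        span = slice(50, None)  # skip low-depth early years
        assert np.nanvar(ch.residual[span]) <= np.nanvar(ch.standard[span]) * 1.15

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_chronology([])

    def test_mean_sensitivity_hand_case(self):
        # |2(x2-x1)/(x2+x1)| terms: (2*1/3, 2*1/3) -> mean 2/3
        assert mean_sensitivity(np.array([1.0, 2.0, 1.0])) == pytest.approx(2 / 3)


class TestPcaSites:
    def _chron_from(self, values, start=1800):
        from dendrorecon.chronology import Chronology
        years = np.arange(start, start + len(values))
        return Chronology(years=years, standard=np.asarray(values, float),
                          residual=None, sample_depth=np.ones(len(values)))

    def test_identical_chronologies_pc1_explains_all(self):
        rng = np.random.default_rng(2)
        x = 1 + rng.normal(0, 0.2, 120)
        fr, _, _ = pca_sites([self._chron_from(x) for _ in range(3)])
        assert fr[0] == pytest.approx(1.0, abs=1e-12)

    def test_equicorrelated_pc1_fraction_closed_form(self):
        # top eigenvalue of 3x3 equicorrelation matrix with r=0.6: (1+2r)/3
        rng = np.random.default_rng(4)
        n = 20000
        common = rng.normal(0, 1, n)
        chs = []
        for _ in range(3):
            # var mix chosen so pairwise corr = 0.6 exactly in population
            x = np.sqrt(0.6) * common + np.sqrt(0.4) * rng.normal(0, 1, n)
            chs.append(self._chron_from(x, start=0))
        fr, _, _ = pca_sites(chs)
        assert fr[0] == pytest.approx((1 + 2 * 0.6) / 3, abs=0.02)
        assert fr.sum() == pytest.approx(1.0, abs=1e-12)

    def test_uncorrelated_fractions_near_third(self):
        rng = np.random.default_rng(6)
        chs = [self._chron_from(rng.normal(0, 1, 5000), start=0) for _ in range(3)]
        fr, _, _ = pca_sites(chs)
        np.testing.assert_allclose(fr, 1 / 3, atol=0.05)

    def test_short_common_span_rejected(self):
        rng = np.random.default_rng(0)
        a = self._chron_from(rng.normal(0, 1, 25))
        b = self._chron_from(rng.normal(0, 1, 25))
        with pytest.raises(ValueError, match="common span"):
            pca_sites([a, b])
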
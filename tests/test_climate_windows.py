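"""Window enumeration, aggregation, AICc model, scan and randomization."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

import phenolink as pl
from phenolink.climate import (
    WindowSpec,
    _reference_dates,
    enumerate_windows,
)
from phenolink.errors import CollinearityError, CoverageError, TooShortSeriesError


class TestEnumerateWindows:
    def test_tiny_exhaustive(self):
        got = [(w.open_week, w.close_week) for w in enumerate_windows(2)]
        assert got == [(1, 1), (2, 1), (2, 2)]

    @pytest.mark.parametrize("k", [1, 6, 26, 104])
    def test_count_law(self, k):
        assert len(enumerate_windows(k)) == k * (k + 1) // 2

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            enumerate_windows(0)
        with pytest.raises(ValueError):
            enumerate_windows(105)
        with pytest.raises(ValueError):
            WindowSpec(3, 4)


def brute_force_aggregate(climate, reference_day, years, window, variable):
    """Day-by-day loop oracle for window aggregation."""
    series = climate.as_series()
    out = []
    for y, ref in zip(years, _reference_dates(reference_day, np.asarray(years))):
        days = [
            pd.Timestamp(ref) - pd.Timedelta(days=b + 1)
            for b in range(7 * (window.close_week - 1), 7 * window.open_week)
        ]
        vals = np.array([series.loc[d] for d in days])
        out.append(vals.mean() if variable == "temperature" else vals.sum())
    return np.array(out)


class TestAggregateWindow:
    def test_constant_temperature_mean(self, flat_climate):
        years = np.arange(1995, 2005)
        v = pl.aggregate_window(flat_climate, 150, years, WindowSpec(10, 2))
        assert np.allclose(v, 1.0)

    def test_constant_precipitation_sum(self, flat_climate):
        clim = pl.DailyClimate("precipitation", flat_climate.dates, flat_climate.values)
        v = pl.aggregate_window(clim, 150, np.arange(1995, 2000), WindowSpec(2, 1))
        assert np.allclose(v, 14.0)

    @pytest.mark.parametrize("window", [WindowSpec(1, 1), WindowSpec(6, 3), WindowSpec(30, 7)])
    @pytest.mark.parametrize("variable", ["temperature", "precipitation"])
    def test_matches_day_loop_oracle(self, seeded_climate, window, variable):
        clim = pl.DailyClimate(variable, seeded_climate.dates, seeded_climate.values)
        years = np.arange(1998, 2010)
        got = pl.aggregate_window(clim, 170, years, window, variable)
        want = brute_force_aggregate(clim, 170, years, window, variable)
        assert np.allclose(got, want, atol=1e-10)

    def test_coverage_error_names_date(self, seeded_climate):
        with pytest.raises(CoverageError, match=r"\d{4}-\d{2}-\d{2}"):
            pl.aggregate_window(
                seeded_climate, 170, np.array([1990]), WindowSpec(60, 1)
            )


def direct_aicc_oracle(y, se, cov, years):
    """Independent AICc: statsmodels WLS + hand-written likelihood."""
    n = len(y)
    X = sm.add_constant(np.column_stack([cov, years]))
    w = 1.0 / se**2
    res = sm.WLS(y, X, weights=w).fit()
    sigma2 = float(np.sum(w * res.resid**2) / n)
    ll = (
        -0.5 * n * math.log(2 * math.pi)
        - 0.5 * float(np.sum(np.log(sigma2 * se**2)))
        - 0.5 * n
    )
    k = 4
    return -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)


class TestFitWindowModel:
    def test_equal_se_matches_ols(self):
        rng = np.random.default_rng(1)
        years = np.arange(2000, 2012)
        cov = rng.standard_normal(12)
        y = 1.0 + 0.5 * cov + rng.standard_normal(12)
        fit = pl.fit_window_model(y, np.full(12, 0.7), cov, years)
        X = sm.add_constant(np.column_stack([cov, years]))
        ols = sm.OLS(y, X).fit()
        assert np.allclose(fit.coef, ols.params, atol=1e-10)

    def test_aicc_matches_direct_oracle(self):
        rng = np.random.default_rng(42)
        years = np.arange(2000, 2012)
        cov = rng.standard_normal(12)
        se = rng.uniform(0.3, 1.2, 12)
        y = 2.0 - 0.4 * cov + 0.02 * (years - 2006) + se * rng.standard_normal(12)
        fit = pl.fit_window_model(y, se, cov, years)
        assert fit.aicc == pytest.approx(direct_aicc_oracle(y, se, cov, years), abs=1e-8)

    def test_collinear_covariate_rejected(self):
        years = np.arange(2000, 2012)
        with pytest.raises(CollinearityError):
            pl.fit_window_model(
                np.linspace(0, 1, 12), np.full(12, 0.5), years.astype(float), years
            )

    def test_too_short(self):
        with pytest.raises(TooShortSeriesError):
            pl.fit_window_model(np.ones(4), np.ones(4), np.ones(4), np.arange(4))


class TestScan:
    def test_best_window_self_consistent(self, seeded_study, seeded_climate):
        res = pl.scan_best_window(seeded_study, seeded_climate, max_weeks=12)
        vals = pl.aggregate_window(
            seeded_climate, seeded_study.reference_day, seeded_study.years, res.window
        )
        direct = pl.fit_window_model(
            seeded_study.trait_mean, seeded_study.trait_se, vals, seeded_study.years
        )
        assert direct.aicc == pytest.approx(res.aicc_best, abs=1e-8)

    def test_table_matches_scalar_path(self, seeded_study, seeded_climate):
        """Batched scan equals per-window scalar fits (oracle equivalence)."""
        res = pl.scan_best_window(seeded_study, seeded_climate, max_weeks=6)
        assert len(res.table) == 21
        for _, row in res.table.iterrows():
            w = WindowSpec(int(row["open_week"]), int(row["close_week"]))
            vals = pl.aggregate_window(
                seeded_climate, seeded_study.reference_day, seeded_study.years, w
            )
            scalar = pl.fit_window_model(
                seeded_study.trait_mean, seeded_study.trait_se, vals, seeded_study.years
            )
            assert scalar.aicc == pytest.approx(row["aicc"], abs=1e-8)

    def test_recovers_true_window(self, strong_signal_truth, seeded_climate):
        st = pl.simulate_study(strong_signal_truth, seeded_climate, 30, seed=77)
        res = pl.scan_best_window(st, seeded_climate, max_weeks=12)
        assert (res.window.open_week, res.window.close_week) == (6, 3)
        assert res.delta_aicc < 0


class TestRandomization:
    def test_overwhelming_signal_floor(self, seeded_climate):
        truth = pl.TruthParams(cz_true=-0.9, trait_resid_sd=0.05, true_window=(6, 3))
        st = pl.simulate_study(truth, seeded_climate, 30, seed=5)
        p, deltas, _ = pl.randomization_probability(
            st, seeded_climate, max_weeks=12, n_rand=200, seed=1
        )
        assert p == pytest.approx(1 / 201)
        assert len(deltas) == 200

    def test_probability_bounds(self, seeded_study, seeded_climate):
        p, _, _ = pl.randomization_probability(
            seeded_study, seeded_climate, max_weeks=8, n_rand=19, seed=2
        )
        assert 1 / 20 <= p <= 1.0

    def test_seeded_determinism(self, seeded_study, seeded_climate):
        a = pl.randomization_probability(seeded_study, seeded_climate, 8, 25, seed=9)
        b = pl.randomization_probability(seeded_study, seeded_climate, 8, 25, seed=9)
        assert a[0] == b[0]
        assert np.array_equal(a[1], b[1])


class TestDetrend:
    def test_perfect_trend_removed(self):
        r = pl.detrend_climate(np.array([1.0, 2.0, 3.0]), np.array([2000, 2001, 2002]))
        assert np.allclose(r, 0.0, atol=1e-10)

    def test_trendless_centered(self):
        rng = np.random.default_rng(3)
        v = rng.standard_normal(20)
        years = np.arange(2000, 2020)
        # remove any sample trend first so residuals equal centred values
        v = pl.detrend_climate(v, years)
        assert np.allclose(pl.detrend_climate(v + 5.0, years), v, atol=1e-10)

    def test_normal_equations(self):
        rng = np.random.default_rng(4)
        years = np.arange(1990, 2015)
        r = pl.detrend_climate(rng.standard_normal(25) * 3 + 0.1 * years, years)
        assert abs(r.sum()) < 1e-8
        assert abs((r * years).sum()) < 1e-6 * np.abs(r * years).max()

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        years = np.arange(1990, 2010)
        r1 = pl.detrend_climate(rng.standard_normal(20), years)
        assert np.allclose(pl.detrend_climate(r1, years), r1, atol=1e-10)

    def test_constant_years_rejected(self):
        with pytest.raises(ValueError):
            pl.detrend_climate(np.arange(3.0), np.array([2000, 2000, 2000]))

    @given(st.integers(0, 100_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_properties_hold_for_random_series(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 50))
        years = np.sort(rng.choice(np.arange(1900, 2030), size=n, replace=False))
        v = rng.normal(scale=rng.uniform(0.1, 50), size=n) + rng.uniform(-5, 5) * years
        r = pl.detrend_climate(v, years)
        scale = max(np.abs(v).max(), 1.0)
        assert abs(r.sum()) < 1e-6 * scale * n
        assert np.allclose(pl.detrend_climate(r, years), r, atol=1e-8 * scale)
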
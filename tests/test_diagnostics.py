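import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

from idiolm import fit_mcmc, simulate_person
from idiolm.diagnostics import (
    acf,
    describe_by_period,
    posterior_predictive,
    residual_acf_check,
    residuals,
)
from idiolm.model import PosteriorDraws

from conftest import make_params, person_model_data


def _fixed_draws(md, coefs, sigma):
    """Point-mass posterior at given coefficients and residual SD."""
    arr = np.zeros((2, 60, len(coefs) + 1))
    arr[:, :, : len(coefs)] = coefs
    arr[:, :, -1] = sigma
    return PosteriorDraws(arr, md.feature_names() + ["sigma"])


@pytest.fixture(scope="module")
def fitted():
    md = person_model_data(make_params(gamma_pre=-25.0, seed=31))
    draws = fit_mcmc(md, chains=2, iterations=1000, warmup=500, seed=2)
    return md, draws


class TestPosteriorPredictive:
    def test_zero_sigma_replicates_equal_fitted(self, fitted):
        md, _ = fitted
        coefs = np.array([430.0, -20.0, 0, 0, 0, 0, 0, 0])
        draws = _fixed_draws(md, coefs, sigma=0.0)
        ppc = posterior_predictive(draws, md, n_rep=5, seed=0)
        X = md.design_matrix()
        np.testing.assert_allclose(ppc.replicated_y, np.tile(X @ coefs, (5, 1)))

    def test_replicate_count(self, fitted):
        md, draws = fitted
        assert posterior_predictive(draws, md, n_rep=5, seed=0).n_rep == 5
        ppc = posterior_predictive(draws, md, seed=0)
        assert ppc.n_rep == 100
        assert ppc.replicated_y.shape == (100, md.n)

    def test_well_specified_fit_is_calibrated(self, fitted):
        md, draws = fitted
        ppc = posterior_predictive(draws, md, seed=1)
        assert ppc.observed_mean_in_envelope()

    def test_correct_model_beats_misspecified_on_ks(self, fitted):
        """Replicates from the right model sit closer to the data than
        replicates from a fit to heavily skewed outcomes."""
        md, draws = fitted
        ppc_good = posterior_predictive(draws, md, seed=3)
        ks_good = ks_2samp(ppc_good.observed_y, ppc_good.replicated_y.ravel()).statistic

        import copy

        md_bad = copy.deepcopy(md)
        rng = np.random.default_rng(5)
        md_bad.y = 300.0 + 120.0 * rng.exponential(1.0, md.n) ** 2
        draws_bad = fit_mcmc(md_bad, chains=2, iterations=1000, warmup=500, seed=4)
        ppc_bad = posterior_predictive(draws_bad, md_bad, seed=3)
        ks_bad = ks_2samp(ppc_bad.observed_y, ppc_bad.replicated_y.ravel()).statistic
        assert ks_good < ks_bad


class TestResiduals:
    def test_perfect_linear_data_zero_residuals(self, fitted):
        md, _ = fitted
        coefs = np.array([100.0, 7.0, 0, 0, 0, 0, 0, 0])
        import copy

        md2 = copy.deepcopy(md)
        md2.y = md.design_matrix() @ coefs
        draws = _fixed_draws(md2, coefs, sigma=1.0)
        resid, fitted_vals = residuals(draws, md2)
        np.testing.assert_allclose(resid, 0.0, atol=1e-9)
        assert len(resid) == len(fitted_vals) == md2.n

    def test_residual_mean_near_zero(self, fitted):
        md, draws = fitted
        resid, _ = residuals(draws, md)
        sigma = draws.median("sigma")
        assert abs(resid.mean()) < 2 * sigma / np.sqrt(md.n)


class TestAcf:
    def test_equals_brute_force_pairing(self):
        rng = np.random.default_rng(7)
        n = 45
        dates = np.datetime64("2017-09-04") + np.sort(
            rng.choice(np.arange(70), size=n, replace=False)
        )
        vals = rng.standard_normal(n)
        prof = acf(vals, dates, max_lag=10, min_pairs=3)
        day = dates.astype("int64")
        for li, k in enumerate(prof.lags):
            a, b = [], []
            for i in range(n):
                for j in range(n):
                    if day[j] - day[i] == k:
                        a.append(vals[i])
                        b.append(vals[j])
            if len(a) < 3:
                assert np.isnan(prof.values[li])
            else:
                expected = np.corrcoef(a, b)[0, 1]
                assert prof.values[li] == pytest.approx(expected, abs=1e-12)

    def test_periodic_series_peaks_at_lag7(self):
        dates = np.datetime64("2017-09-04") + np.arange(700)
        vals = np.where(np.arange(700) % 7 < 2, 60.0, 0.0)
        vals = vals + np.random.default_rng(8).normal(0, 10, 700)
        prof = acf(vals, dates)
        # weekly periodicity: lag 7 dominates lags 1..6
        assert np.nanargmax(prof.values[:7]) + 1 == 7

    def test_sample_estimator_matches_statsmodels(self):
        import statsmodels.tsa.stattools as st

        rng = np.random.default_rng(12)
        x = rng.standard_normal(300)
        x[rng.random(300) < 0.25] = np.nan
        dates = np.datetime64("2017-01-01") + np.arange(300)
        ours = acf(x, dates, max_lag=10, method="sample", min_pairs=3).values
        theirs = st.acf(x, nlags=10, missing="conservative")[1:]
        np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_white_noise_stays_low(self):
        dates = np.datetime64("2017-09-04") + np.arange(1000)
        vals = np.random.default_rng(9).standard_normal(1000)
        prof = acf(vals, dates)
        assert np.all(np.abs(prof.values) < 0.1)
        assert prof.adequate

    def test_alternate_day_gaps_make_odd_lags_unavailable(self):
        dates = np.datetime64("2017-09-04") + np.arange(0, 80, 2)
        vals = np.random.default_rng(10).standard_normal(40)
        prof = acf(vals, dates, max_lag=6)
        assert np.isnan(prof.values[[0, 2, 4]]).all()  # lags 1, 3, 5
        assert not np.isnan(prof.values[[1, 3, 5]]).any()  # lags 2, 4, 6


class TestResidualAcf:
    def test_weekday_covariate_absorbs_weekly_structure(self):
        # strong weekend sleep-in: weekly variance ~0.3 of total
        profile = (90.0, 90.0, -36.0, -36.0, -36.0, -36.0, -36.0)
        md = person_model_data(
            make_params(seed=41, weekday_profile=profile),
            preset="stress_day_before",
            n=None,
        )
        draws = fit_mcmc(md, chains=2, iterations=1000, warmup=500, seed=5)
        prof_with = residual_acf_check(draws, md)

        # same person, no weekday covariate: weekly rhythm leaks into residuals
        X = np.column_stack([np.ones(md.n), md.x])
        beta, *_ = np.linalg.lstsq(X, md.y, rcond=None)
        prof_without = acf(md.y - X @ beta, md.dates, method="sample")
        lag7 = lambda p: p.values[p.lags.tolist().index(7)]
        assert lag7(prof_without) > 0.2  # weekly structure visible without it
        assert abs(lag7(prof_with)) < 0.2  # absorbed by the covariate
        assert lag7(prof_without) > lag7(prof_with)

    def test_iid_outcome_flagged_adequate(self, fitted):
        md, draws = fitted
        assert residual_acf_check(draws, md).adequate


class TestDescribeByPeriod:
    def test_single_participant_group_mean_is_person_mean(self, calendar):
        s = simulate_person(make_params(seed=51), calendar)
        period_tbl, weekday_tbl = describe_by_period([s], calendar)
        fall = s[s["date"].dt.date.map(calendar.in_fall)]
        assert period_tbl.loc["fall", "sleep_duration_min_mean"] == pytest.approx(
            fall["sleep_duration_min"].mean()
        )

    def test_weekday_table_saturday_first(self, calendar):
        s = simulate_person(make_params(seed=51), calendar)
        _, weekday_tbl = describe_by_period([s], calendar)
        assert list(weekday_tbl.index) == [
            "Saturday",
            "Sunday",
            "Monday",
            "Tuesday",
            "Wednesday",
            "Thursday",
            "Friday",
        ]

    def test_break_lifts_sleep_in_cohort_table(self, calendar):
        cohort = [
            simulate_person(make_params(seed=60 + i), calendar, f"S{i}") for i in range(6)
        ]
        period_tbl, _ = describe_by_period(cohort, calendar)
        assert (
            period_tbl.loc["break", "sleep_duration_min_mean"]
            > period_tbl.loc["fall", "sleep_duration_min_mean"]
        )
        assert period_tbl.loc["break", "stress_mean"] < period_tbl.loc["fall", "stress_mean"]

    def test_empty_cohort_rejected(self, calendar):
        with pytest.raises(ValueError):
            describe_by_period([], calendar)


class TestPlotExports:
    def test_plot_files_written(self, fitted, tmp_path):
        import matplotlib

        matplotlib.use("Agg")
        from idiolm.diagnostics import posterior_predictive, residual_acf_check
        from idiolm.plots import (
            plot_acf_profile,
            plot_ppc_density,
            plot_residuals_vs_fitted,
        )

        md, draws = fitted
        ppc = posterior_predictive(draws, md, n_rep=20, seed=0)
        plot_ppc_density(ppc, tmp_path / "ppc.png")
        resid, fit_vals = residuals(draws, md)
        plot_residuals_vs_fitted(resid, fit_vals, tmp_path / "resid.png")
        plot_acf_profile(residual_acf_check(draws, md), tmp_path / "acf.png")
        for name in ("ppc.png", "resid.png", "acf.png"):
            assert (tmp_path / name).stat().st_size > 0
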
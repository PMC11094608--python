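import numpy as np
import pandas as pd
import pytest

from idiolm import (
    MLMFit,
    compare_shrinkage,
    fit_mcmc,
    fit_mlm,
    summarize,
)
from idiolm.model import PosteriorDraws
from idiolm.simulate import _oracle_slopes_for

from conftest import make_params, person_model_data, trim

REDUCED = dict(chains=2, iterations=800, warmup=400)


def _ilm_summary(md, seed):
    draws = fit_mcmc(md, chains=2, iterations=800, warmup=400, seed=seed)
    return summarize(draws, md)


def _cohort_mds(gammas, n=178, sigmas=None, seed0=500):
    mds = []
    for i, g in enumerate(gammas):
        kw = dict(gamma_pre=g, seed=seed0 + i)
        if sigmas is not None:
            kw["sigma_sleep"] = sigmas[i]
        md = person_model_data(make_params(**kw), n=n)
        md.participant_id = f"S{i:02d}"
        mds.append(md)
    return mds


class TestFitMLM:
    def test_homogeneous_cohort_recovers_common_slope(self):
        mds = _cohort_mds([-20.0] * 10)
        fit = fit_mlm(mds, seed=1, **REDUCED)
        oracle = _oracle_slopes_for(make_params(gamma_pre=-20.0), "x", 100_000, 77)
        oracle_slope = next(
            r["slope"] for r in oracle if r["preset"] == "stress_day_before"
        )
        assert fit.fixed_slope == pytest.approx(oracle_slope, abs=2.0)
        assert fit.tau_slope < 5.0
        assert fit.converged

    def test_heterogeneity_detected_in_slope_variance(self):
        hom = fit_mlm(_cohort_mds([-20.0] * 10), seed=2, **REDUCED)
        het = fit_mlm(
            _cohort_mds(list(np.linspace(-45, 15, 10))), seed=2, **REDUCED
        )
        assert het.tau_slope > 2 * hom.tau_slope
        assert het.tau_slope > 8.0

    def test_single_participant_duplicated_pins_fixed_slope(self):
        base = person_model_data(make_params(gamma_pre=-25.0, seed=900))
        mds = []
        for i in range(10):
            import copy

            md = copy.deepcopy(base)
            md.participant_id = f"D{i}"
            mds.append(md)
        fit = fit_mlm(mds, seed=3, **REDUCED)
        ilm = _ilm_summary(base, seed=3)
        assert fit.fixed_slope == pytest.approx(ilm.median_slope, abs=2.0)

    def test_fewer_than_three_participants_rejected(self):
        mds = _cohort_mds([-20.0, -20.0])
        with pytest.raises(ValueError):
            fit_mlm(mds, seed=0, **REDUCED)

    def test_mixed_presets_rejected(self):
        mds = _cohort_mds([-20.0] * 3)
        other = person_model_data(make_params(seed=77), preset="stress_day_after")
        other.participant_id = "X"
        with pytest.raises(ValueError, match="mixed"):
            fit_mlm(mds + [other], seed=0, **REDUCED)

    def test_random_effects_roughly_centered(self):
        mds = _cohort_mds(list(np.linspace(-40, 5, 12)))
        fit = fit_mlm(mds, seed=4, **REDUCED)
        mean_dev = fit.person_effects["slope_dev"].mean()
        assert abs(mean_dev) < 0.5 * fit.tau_slope


@pytest.fixture(scope="module")
def het_cohort():
    gammas = list(np.linspace(-45, -10, 11)) + [18.0]
    sigmas = [90.0] * 11 + [60.0]
    mds = _cohort_mds(gammas, sigmas=sigmas, seed0=700)
    mds[-1] = trim(mds[-1], 40)  # low-n minority-phenotype participant
    ilms = [_ilm_summary(md, seed=i) for i, md in enumerate(mds)]
    mlm = fit_mlm(mds, seed=5, **REDUCED)
    return mds, ilms, mlm


class TestShrinkage:

    def test_pooling_contracts_all_estimates(self, het_cohort):
        _, ilms, mlm = het_cohort
        pooled = mlm.fixed_slope
        for s in ilms:
            dist_ilm = abs(s.median_slope - pooled)
            dist_mlm = abs(mlm.person_slope(s.participant_id) - pooled)
            assert dist_mlm <= dist_ilm + 2.0

    def test_attenuation_ratios_below_one(self, het_cohort):
        _, ilms, mlm = het_cohort
        report = compare_shrinkage(ilms, mlm)
        frac = (report.table["attenuation_ratio"] < 1.0).mean()
        assert frac >= 0.9
        assert report.median_attenuation < 1.0

    def test_minority_participant_reverses_sign(self, het_cohort):
        mds, ilms, mlm = het_cohort
        report = compare_shrinkage(ilms, mlm)
        minority = report.table[report.table.participant_id == mds[-1].participant_id]
        assert minority["ilm_slope"].iloc[0] > 0  # person-level estimate positive
        assert minority["mlm_slope"].iloc[0] < 0  # pulled across zero by the pool
        assert bool(minority["sign_reversed"].iloc[0])

    def test_attenuation_strengthens_as_n_shrinks(self):
        gammas = [-30.0, -28.0, -26.0, -24.0, -22.0, -20.0, 18.0]
        ratios = {}
        for n_min in (30, 90, 178):
            mds = _cohort_mds(gammas, seed0=800)
            mds[-1] = trim(mds[-1], n_min)
            ilms = [_ilm_summary(md, seed=i) for i, md in enumerate(mds)]
            mlm = fit_mlm(mds, seed=6, **REDUCED)
            report = compare_shrinkage(ilms, mlm)
            row = report.table[report.table.participant_id == mds[-1].participant_id]
            ratios[n_min] = float(row["attenuation_ratio"].iloc[0])
        assert ratios[30] < ratios[178]
        assert ratios[30] < ratios[90] + 0.1
        assert ratios[90] < ratios[178] + 0.1


class TestCompareShrinkage:
    def _fake_mlm(self, ids, slopes, pooled):
        effects = pd.DataFrame(
            {
                "participant_id": ids,
                "intercept_dev": 0.0,
                "slope_dev": np.asarray(slopes) - pooled,
                "slope_total": slopes,
            }
        )
        tiny = PosteriorDraws(np.zeros((2, 4, 1)), ["slope"])
        return MLMFit(
            draws=tiny,
            participant_ids=list(ids),
            fixed_intercept=400.0,
            fixed_slope=pooled,
            fixed_weekday={},
            person_effects=effects,
            tau_intercept=1.0,
            tau_slope=1.0,
            rho=0.0,
            sigma=90.0,
            rhat_fixed_slope=1.0,
        )

    def _summaries(self, ids, slopes):
        from test_inference import _summary

        return [_summary(pid=i, slope=s) for i, s in zip(ids, slopes)]

    def test_identical_estimates_give_unit_ratios(self):
        ids = ["A", "B", "C"]
        slopes = [-30.0, -20.0, -10.0]
        report = compare_shrinkage(
            self._summaries(ids, slopes), self._fake_mlm(ids, slopes, -20.0)
        )
        assert (report.table["attenuation_ratio"] == 1.0).all()
        assert report.n_reversed == 0

    def test_slope_at_pool_reported_as_one_by_convention(self):
        ids = ["A", "B", "C"]
        report = compare_shrinkage(
            self._summaries(ids, [-20.0, -25.0, -15.0]),
            self._fake_mlm(ids, [-20.0, -24.0, -16.0], -20.0),
        )
        assert report.table.set_index("participant_id").loc["A", "attenuation_ratio"] == 1.0

    def test_participant_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_shrinkage(
                self._summaries(["A", "B"], [-20.0, -10.0]),
                self._fake_mlm(["A", "C"], [-20.0, -10.0], -15.0),
            )
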
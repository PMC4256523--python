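"""Count-model oracles: likelihood closed forms, recovery, quantiles."""

from types import SimpleNamespace

import numpy as np
import pytest
from scipy import stats

from jsyimpact.config import ScenarioConfig, SourceSpec
from jsyimpact.data_io import DomainError
from jsyimpact.stage1 import (
    Stage1Data,
    Stage1Model,
    Stage1Spec,
    fit_stage1,
    nb_log_likelihood,
    percent_change,
    predict_mmr,
    sample_mmr_draws,
)
from jsyimpact.synth import generate_observations, generate_truth

from conftest import tiny_scenario


class TestNBLogLikelihood:
    def test_poisson_limit(self):
        # dispersion -> infinity reduces the NB to Poisson; at mean 5,
        # deaths 5 the Poisson pmf is 0.175467...
        val = nb_log_likelihood(5, 5.0, 1e8)
        assert val == pytest.approx(np.log(0.1754674), abs=1e-5)
        assert val == pytest.approx(stats.poisson.logpmf(5, 5.0), abs=1e-5)

    def test_normalization(self):
        ys = np.arange(0, 10_001)
        total = np.exp(nb_log_likelihood(ys, 20.0, 2.0)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("y,mean,k", [(0, 3.0, 1.5), (7, 2.2, 0.7),
                                          (120, 95.0, 30.0)])
    def test_matches_independent_formula(self, y, mean, k):
        # textbook parameterization: NB(r=k, p=k/(k+m))
        oracle = stats.nbinom.logpmf(y, k, k / (k + mean))
        assert nb_log_likelihood(y, mean, k) == pytest.approx(oracle,
                                                              abs=1e-12)

    def test_non_integer_deaths_rejected(self):
        with pytest.raises(DomainError):
            nb_log_likelihood(2.5, 3.0, 1.0)

    def test_domain_checks(self):
        with pytest.raises(DomainError):
            nb_log_likelihood(2, -1.0, 1.0)
        with pytest.raises(DomainError):
            nb_log_likelihood(2, 1.0, 0.0)


class TestPercentChange:
    @pytest.mark.parametrize("a,b,expected", [
        (371, 327, 12),           # headline example
        (200, 200, 0),
        (100, 130, -30),          # increases are negative declines
    ])
    def test_headline_rounding(self, a, b, expected):
        assert percent_change(a, b) == expected

    def test_district_precision(self):
        assert percent_change(371, 327, ndigits=1) == pytest.approx(11.9)

    def test_zero_start_rejected(self):
        with pytest.raises(DomainError):
            percent_change(0, 10)


def _fake_fit(log_draws, districts=("D01",), years=(2005,)):
    arr = np.asarray(log_draws, dtype=float).reshape(-1, len(districts),
                                                     len(years))
    return SimpleNamespace(
        log_mmr_draws=arr,
        data=SimpleNamespace(districts=list(districts), years=list(years)),
        n_draws=arr.shape[0],
    )


class TestPredictMMR:
    def test_degenerate_draws(self):
        fit = _fake_fit(np.full(100, np.log(200.0)))
        post = predict_mmr(fit)
        assert post.loc[0, ["median", "lower", "upper"]].tolist() == \
            pytest.approx([200.0, 200.0, 200.0])

    def test_quantile_rule_on_constructed_draws(self):
        draws = np.concatenate([np.full(975, np.log(100.0)),
                                np.full(25, np.log(500.0))])
        post = predict_mmr(_fake_fit(draws))
        # brute-force quantile of the constructed set (linear interpolation)
        expected_upper = np.quantile(np.exp(draws), 0.975)
        assert post.loc[0, "upper"] == pytest.approx(expected_upper)
        assert 100.0 < post.loc[0, "upper"] < 500.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(np.log(300), 0.2, size=500)
        post = predict_mmr(_fake_fit(draws))
        assert post.loc[0, "median"] == pytest.approx(
            np.exp(np.median(draws)))
        assert post.loc[0, "lower"] == pytest.approx(
            np.exp(np.quantile(draws, 0.025)))


class TestSampleDraws:
    def test_identity_when_n_matches(self):
        fit = _fake_fit(np.log([100.0, 200.0, 300.0]))
        out = sample_mmr_draws(fit, 3)
        assert np.allclose(out[:, 0, 0], [100.0, 200.0, 300.0])

    def test_seeded_resampling_is_deterministic(self):
        fit = _fake_fit(np.log(np.linspace(100, 400, 50)))
        a = sample_mmr_draws(fit, 20, seed=7)
        b = sample_mmr_draws(fit, 20, seed=7)
        assert np.array_equal(a, b)

    def test_resampling_mean_consistency(self):
        rng = np.random.default_rng(1)
        fit = _fake_fit(rng.normal(np.log(250), 0.15, size=800))
        out = sample_mmr_draws(fit, 1000, seed=3)
        post_mean = np.exp(fit.log_mmr_draws).mean()
        mc_se = np.exp(fit.log_mmr_draws).std() / np.sqrt(1000)
        assert abs(out.mean() - post_mean) < 4 * mc_se

    def test_nonpositive_n_rejected(self):
        fit = _fake_fit(np.log([100.0]))
        with pytest.raises(DomainError):
            sample_mmr_draws(fit, 0)


class TestModelInternals:
    def test_latent_gradient_and_hessian_match_finite_differences(self):
        cfg = tiny_scenario()
        truth = generate_truth(cfg)
        obs = generate_observations(truth)
        spec = Stage1Spec(draws=10, seed=0)
        data = Stage1Data(obs, truth.covariates, truth.live_births,
                          truth.membership, spec)
        model = Stage1Model(data, spec)
        rng = np.random.default_rng(0)
        psi = model._psi_start() + 0.05 * rng.standard_normal(
            model.idx.n_latent)
        ll, g, H = model._loglik_parts(psi, 20.0)
        for i in range(len(psi)):
            h = 1e-6
            pp, pm = psi.copy(), psi.copy()
            pp[i] += h
            pm[i] -= h
            lp, gp, _ = model._loglik_parts(pp, 20.0)
            lm, gm, _ = model._loglik_parts(pm, 20.0)
            assert g[i] == pytest.approx((lp - lm) / (2 * h), rel=1e-4,
                                         abs=1e-6)
            assert np.allclose(H[:, i], (gp - gm) / (2 * h), rtol=1e-4,
                               atol=1e-6)

    def test_fit_is_seed_deterministic(self):
        cfg = tiny_scenario()
        truth = generate_truth(cfg)
        obs = generate_observations(truth)
        kwargs = dict(spec=Stage1Spec(draws=50, seed=5))
        f1 = fit_stage1(obs, truth.covariates, truth.live_births,
                        truth.membership, **kwargs)
        f2 = fit_stage1(obs, truth.covariates, truth.live_births,
                        truth.membership, **kwargs)
        assert np.array_equal(f1.theta_draws, f2.theta_draws)
        assert np.array_equal(f1.log_mmr_draws, f2.log_mmr_draws)


class TestFitRecovery:
    def test_source_bias_recovered(self):
        # district source over-reports deaths by 1.5x relative to the
        # state gold standard: delta for that source should be near
        # log 1.5 (within 3 posterior sd)
        cfg = ScenarioConfig(
            seed=23,
            sources=(
                SourceSpec("bulletin", "district", bias=1.5, coverage=1.0),
                SourceSpec("srs", "state", bias=1.0, coverage=1.0),
            ),
        )
        truth = generate_truth(cfg)
        obs = generate_observations(truth)
        fit = fit_stage1(obs, truth.covariates, truth.live_births,
                         truth.membership, Stage1Spec(draws=300, seed=1))
        assert fit.converged
        eff = fit.source_effects().set_index("source_id")
        est, sd = eff.at["bulletin", "mean"], eff.at["bulletin", "sd"]
        assert abs(est - np.log(1.5)) < 3 * sd

    def test_median_mmr_recovery_on_default_scenario(self):
        cfg = ScenarioConfig(seed=7)
        truth = generate_truth(cfg)
        obs = generate_observations(truth)
        fit = fit_stage1(obs, truth.covariates, truth.live_births,
                         truth.membership, Stage1Spec(draws=300, seed=2))
        assert fit.converged
        post = predict_mmr(fit)
        med = post.pivot(index="district_id", columns="year",
                         values="median").loc[truth.districts]
        rel = np.abs(med.to_numpy() - truth.mmr.to_numpy()) \
            / truth.mmr.to_numpy()
        assert np.median(rel) < 0.15

    def test_conjugate_small_case_grid_oracle(self):
        # single district, single source, constant truth: the fit's
        # interval should cover the posterior median computed by brute
        # force on a dense (mu, trend, log-dispersion) grid
        from jsyimpact.config import TrendConfig, UptakeConfig

        cfg = ScenarioConfig(
            seed=31, n_districts=1, n_divisions=1,
            year_start=2005, year_end=2008,
            covariate_effects={"tfr": 0.0, "hdi": 0.0},
            district_intercept_sd=0.0, division_intercept_sd=0.0,
            trend=TrendConfig(slope_mean=0.0, slope_sd=0.0,
                              division_slope_sd=0.0, nonlinear_scale=0.0),
            program_effect=0.0,
            sources=(SourceSpec("only", "district", bias=1.0, coverage=1.0),),
        )
        truth = generate_truth(cfg)
        obs = generate_observations(truth)
        spec = Stage1Spec(covariates=(), trend="linear_only", draws=2000,
                          seed=3)
        fit = fit_stage1(obs, truth.covariates, truth.live_births,
                         truth.membership, spec)
        model = fit.model
        assert model.idx.size == 3          # mu, z0, log_phi

        mu0, z00 = fit.theta_map[0], fit.theta_map[1]
        lp0 = fit.theta_map[2]
        mus = np.linspace(mu0 - 0.4, mu0 + 0.4, 61)
        z0s = np.linspace(z00 - 0.3, z00 + 0.3, 41)
        lps = np.linspace(lp0 - 4.0, lp0 + 4.0, 31)
        logpost = np.empty((61, 41, 31))
        for i, m in enumerate(mus):
            for j, z in enumerate(z0s):
                for kk, lp in enumerate(lps):
                    logpost[i, j, kk] = model.log_joint(
                        np.array([m, z, lp]))
        w = np.exp(logpost - logpost.max())
        w /= w.sum()
        tc = np.asarray(fit.data.years, float)
        tc -= tc.mean()
        post = predict_mmr(fit).set_index("year")
        for t_idx, year in enumerate(fit.data.years):
            log_mmr_grid = mus[:, None] + z0s[None, :] * tc[t_idx]
            wz = w.sum(axis=2)
            order = np.argsort(log_mmr_grid.ravel())
            cdf = np.cumsum(wz.ravel()[order])
            oracle_median = np.exp(
                log_mmr_grid.ravel()[order][np.searchsorted(cdf, 0.5)]
            )
            assert post.at[year, "lower"] <= oracle_median \
                <= post.at[year, "upper"]
            assert post.at[year, "median"] == pytest.approx(
                oracle_median, rel=0.05)

    def test_shrinkage_toward_division_mean(self):
        # a district-year with an extreme reported count and little other
        # information is pulled toward its division's level
        cfg = ScenarioConfig(seed=13)
        truth = generate_truth(cfg)
        obs = generate_observations(truth)
        # make one district-year report triple its expected deaths
        mask = (obs["unit_id"] == "D01") & (obs["level"] == "district")
        idx = obs[mask].index[0]
        year = int(obs.at[idx, "year"])
        obs.at[idx, "deaths"] = 3 * truth.expected_deaths.at["D01", year]
        fit = fit_stage1(obs, truth.covariates, truth.live_births,
                         truth.membership, Stage1Spec(draws=200, seed=1))
        post = predict_mmr(fit)
        raw_mmr = obs.at[idx, "deaths"] / truth.live_births.at["D01", year] \
            * 1e5
        division = truth.membership["D01"]
        members = [d for d in truth.districts
                   if truth.membership[d] == division and d != "D01"]
        div_mean = post[
            (post["year"] == year) & post["district_id"].isin(members)
        ]["median"].mean()
        est = post[(post["year"] == year)
                   & (post["district_id"] == "D01")]["median"].iloc[0]
        assert abs(est - div_mean) < abs(raw_mmr - div_mean)

    def test_mcmc_cross_check_on_tiny_joint(self):
        # independent route: ensemble MCMC on the exact joint posterior
        # of the 3-parameter single-district model vs the Laplace fit
        import emcee

        from jsyimpact.config import TrendConfig

        cfg = ScenarioConfig(
            seed=31, n_districts=1, n_divisions=1,
            year_start=2005, year_end=2012,
            covariate_effects={"tfr": 0.0, "hdi": 0.0},
            district_intercept_sd=0.0, division_intercept_sd=0.0,
            trend=TrendConfig(slope_mean=0.0, slope_sd=0.0,
                              division_slope_sd=0.0, nonlinear_scale=0.0),
            program_effect=0.0,
            sources=(SourceSpec("only", "district", bias=1.0, coverage=1.0),),
        )
        truth = generate_truth(cfg)
        obs = generate_observations(truth)
        spec = Stage1Spec(covariates=(), trend="linear_only", draws=2000,
                          seed=3)
        fit = fit_stage1(obs, truth.covariates, truth.live_births,
                         truth.membership, spec)
        model = fit.model
        rng = np.random.default_rng(0)
        nwalkers = 12
        p0 = fit.theta_map + 0.01 * rng.standard_normal((nwalkers, 3))
        sampler = emcee.EnsembleSampler(nwalkers, 3, model.log_joint)
        sampler.random_state = np.random.RandomState(42).get_state()
        sampler.run_mcmc(p0, 3000, progress=False)
        chain = sampler.get_chain(discard=1000, flat=True)
        mmr_mcmc = np.exp(chain[:, 0])       # mid-year MMR (tc = +/-)
        mmr_fit = np.exp(fit.theta_draws[:, 0])
        assert np.median(mmr_mcmc) == pytest.approx(np.median(mmr_fit),
                                                    rel=0.05)
        assert np.quantile(mmr_mcmc, 0.975) == pytest.approx(
            np.quantile(mmr_fit, 0.975), rel=0.10)
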
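"""Impact-regression oracles: OLS limit, recovery, pooling, formatting."""

import numpy as np
import pandas as pd
import pytest

from jsyimpact.config import ScenarioConfig, UptakeConfig
from jsyimpact.stage2 import (
    CollinearityError,
    Stage2Spec,
    district_slope_report,
    fit_propagated,
    fit_single,
    make_coefficient_table,
)
from jsyimpact.synth import (
    generate_truth,
    posterior_like_draws,
    true_exposure_panel,
)

from conftest import impact_scenario


@pytest.fixture(scope="module")
def impact_truth():
    truth = generate_truth(impact_scenario(-0.3, seed=77))
    return truth, true_exposure_panel(truth)


class TestFitSingle:
    def test_zero_variance_limit_equals_brute_force_ols(self, impact_truth):
        truth, expo = impact_truth
        fit = fit_single(truth.log_mmr, truth.covariates, expo,
                         Stage2Spec(random_terms=()))
        # brute-force normal equations on the same design
        cov = truth.covariates.set_index("district_id")
        rows = []
        panel = expo.set_index(["district_id", "year"])
        for d in truth.districts:
            for t in truth.years:
                rows.append([
                    1.0, cov.at[d, "literacy"], cov.at[d, "urban"],
                    panel.at[(d, t), "anc3"], panel.at[(d, t), "njsy_prop"],
                    panel.at[(d, t), "jsy_prop"],
                ])
        X = np.array(rows)
        y = truth.log_mmr.to_numpy().reshape(-1)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-8)

    def test_recovers_known_effect_without_noise(self, impact_truth):
        # generated with beta5 = -0.3 and a correctly specified model:
        # the estimate lands within 2 se of the truth
        truth, expo = impact_truth
        fit = fit_single(truth.log_mmr, truth.covariates, expo, Stage2Spec())
        est, se = fit.params["jsy_prop"], fit.se["jsy_prop"]
        assert abs(est - (-0.3)) < max(2 * se, 1e-4)

    def test_constant_exposure_is_collinearity_error(self, impact_truth):
        truth, expo = impact_truth
        flat = expo.copy()
        flat["jsy_prop"] = 0.5
        with pytest.raises(CollinearityError, match="jsy_prop"):
            fit_single(truth.log_mmr, truth.covariates, flat, Stage2Spec())

    def test_needs_minimum_panel(self, impact_truth):
        truth, expo = impact_truth
        small = truth.log_mmr.iloc[:2]
        with pytest.raises(ValueError):
            fit_single(small, truth.covariates, expo, Stage2Spec())

    def test_variance_components_nonnegative(self, impact_truth):
        truth, expo = impact_truth
        draws = posterior_like_draws(truth, 1, sd=0.05, seed=3)
        surf = pd.DataFrame(np.log(draws[0]), index=truth.districts,
                            columns=truth.years)
        fit = fit_single(surf, truth.covariates, expo, Stage2Spec())
        assert all(v >= 0 for v in fit.varcomps.values())

    def test_matches_statsmodels_mixedlm(self, impact_truth):
        # independent implementation of the same crossed-random-effects
        # REML problem via the single-group variance-component trick
        import statsmodels.formula.api as smf

        from jsyimpact.stage2 import (
            _build_design,
            _reml_value_grad,
            _surface_to_y,
        )

        truth, expo = impact_truth
        draws = posterior_like_draws(truth, 1, sd=0.05, seed=2)
        surf = pd.DataFrame(np.log(draws[0]), index=truth.districts,
                            columns=truth.years)
        spec = Stage2Spec()
        ours = fit_single(surf, truth.covariates, expo, spec)

        cov = truth.covariates.set_index("district_id")
        panel = expo.set_index(["district_id", "year"])
        rows = []
        for d in truth.districts:
            for t in truth.years:
                rows.append(dict(
                    y=surf.at[d, t], district=d, year=str(t),
                    literacy=cov.at[d, "literacy"],
                    urban=cov.at[d, "urban"],
                    anc3=panel.at[(d, t), "anc3"],
                    njsy=panel.at[(d, t), "njsy_prop"],
                    jsy=panel.at[(d, t), "jsy_prop"],
                    g=1,
                ))
        df = pd.DataFrame(rows)
        vc = {"year": "0 + C(year)", "district": "0 + C(district)",
              "slope": "0 + C(district):jsy"}
        sm_fit = smf.mixedlm(
            "y ~ literacy + urban + anc3 + njsy + jsy", df, groups="g",
            vc_formula=vc,
        ).fit(reml=True, method="lbfgs", maxiter=500)
        assert np.allclose(ours.params.to_numpy(),
                           sm_fit.fe_params.to_numpy(), atol=0.02)
        # our optimizer should do at least as well on the REML criterion
        design = _build_design(truth.covariates, expo, spec,
                               truth.districts, truth.years)
        y = _surface_to_y(surf, truth.districts, surf.columns)
        sm_logvars = np.log(np.r_[
            sm_fit.scale,
            max(sm_fit.vcomp[2], 1e-12),   # year
            max(sm_fit.vcomp[0], 1e-12),   # district
            max(sm_fit.vcomp[1], 1e-12),   # slope
        ])
        ours_val = _reml_value_grad(ours.theta, y, design.X, design.ZZt)[0]
        sm_val = _reml_value_grad(sm_logvars, y, design.X, design.ZZt)[0]
        assert ours_val <= sm_val + 1e-6


class TestFitPropagated:
    def test_identical_draws_reduce_to_single_fit(self, impact_truth):
        truth, expo = impact_truth
        draws = posterior_like_draws(truth, 5, sd=0.0, seed=1)
        res = fit_propagated(draws, truth.covariates, expo,
                             Stage2Spec(n_draws=5),
                             districts=truth.districts, years=truth.years)
        single = fit_single(truth.log_mmr, truth.covariates, expo,
                            Stage2Spec())
        got = res.coefficients.set_index("term")["estimate"]
        assert np.allclose(got.to_numpy(), single.params.to_numpy(),
                           atol=1e-6)

    def test_pooled_estimate_is_mean_of_draw_estimates(self, impact_truth):
        truth, expo = impact_truth
        draws = posterior_like_draws(truth, 20, sd=0.05, seed=6)
        res = fit_propagated(draws, truth.covariates, expo,
                             Stage2Spec(n_draws=20),
                             districts=truth.districts, years=truth.years)
        assert np.allclose(
            res.coefficients["estimate"].to_numpy(),
            res.draw_estimates.mean().to_numpy(),
        )

    def test_rubin_variance_exceeds_between_draw_component(self, impact_truth):
        truth, expo = impact_truth
        draws = posterior_like_draws(truth, 20, sd=0.05, seed=6)
        res = fit_propagated(draws, truth.covariates, expo,
                             Stage2Spec(n_draws=20),
                             districts=truth.districts, years=truth.years)
        B = res.draw_estimates.var(ddof=1).to_numpy()
        T = res.coefficients["se"].to_numpy() ** 2
        assert np.all(T >= (1 + 1 / 20) * B - 1e-12)


class TestDistrictSlopes:
    def test_injected_extreme_slope_is_flagged(self):
        # one district is given a strong extra exposure response; with
        # low noise its pooled interval should exclude zero
        truth = generate_truth(impact_scenario(-0.2, seed=31))
        expo = true_exposure_panel(truth)
        log_mmr = truth.log_mmr.copy()
        jsy = truth.jsy_prop.loc["D03"]
        log_mmr.loc["D03"] = log_mmr.loc["D03"] - 1.0 * jsy
        draws = np.exp(
            np.log(posterior_like_draws(truth, 30, sd=0.01, seed=5))
            + (log_mmr - truth.log_mmr).to_numpy()[None, :, :]
        )
        res = fit_propagated(draws, truth.covariates, expo,
                             Stage2Spec(n_draws=30),
                             districts=truth.districts, years=truth.years)
        table, summary = district_slope_report(res)
        flagged = table.set_index("district_id")["excludes_zero"]
        assert flagged["D03"]
        assert table.set_index("district_id").at["D03", "estimate"] < -0.5

    def test_report_requires_slope_term(self, impact_truth):
        truth, expo = impact_truth
        draws = posterior_like_draws(truth, 3, sd=0.02, seed=2)
        res = fit_propagated(
            draws, truth.covariates, expo,
            Stage2Spec(n_draws=3,
                       random_terms=("year_intercept", "district_intercept")),
            districts=truth.districts, years=truth.years,
        )
        with pytest.raises(ValueError, match="district_exposure_slope"):
            district_slope_report(res)


class TestFormatting:
    def _result(self, estimate, lower, upper, p):
        from jsyimpact.stage2 import Stage2Result
        coef = pd.DataFrame({
            "term": ["x"], "estimate": [estimate], "se": [1.0],
            "lower": [lower], "upper": [upper], "p": [p],
            "emp_lower": [lower], "emp_upper": [upper],
        })
        return Stage2Result(coefficients=coef, phi=None, varcomps={},
                            n_draws_used=1, n_failed=0, spec=Stage2Spec())

    def test_three_decimal_rounding(self):
        table = make_coefficient_table(self._result(-0.2231, -0.440, 0.063,
                                                    0.108))
        row = table.iloc[0]
        assert row["estimate"] == "-0.223"
        assert row["95% CI"] == "(-0.440, 0.063)"
        assert row["p"] == "0.108"

    def test_tiny_coefficient_prints_zero_with_scientific_interval(self):
        table = make_coefficient_table(
            self._result(1.2e-07, -2.488e-06, 1.682e-06, 0.486))
        row = table.iloc[0]
        assert row["estimate"] == "0.000"
        assert row["95% CI"] == "(-2.488e-06, 1.682e-06)"

    def test_small_p_prints_bare_zero(self):
        table = make_coefficient_table(self._result(6.752, 6.518, 6.942,
                                                    0.0004))
        assert table.iloc[0]["p"] == "0"

    def test_expenditure_scale_not_rescaled(self):
        # exposure in lakh on a realistic 1e2-1e4 scale must yield
        # coefficients on the ~1e-06 order, i.e. no silent rescaling
        truth = generate_truth(impact_scenario(-0.2, seed=9))
        expo = true_exposure_panel(truth)
        assert 1e2 < expo["expenditure"].median() < 1e4
        fit = fit_single(truth.log_mmr, truth.covariates, expo,
                         Stage2Spec(exposure="expenditure"))
        # per-lakh coefficient ~= per-proportion effect divided by the
        # lakh-per-unit-proportion scale (~1e3), so ~1e-4 magnitude
        scale = (expo["expenditure"] / expo["jsy_prop"]).median()
        assert fit.params["expenditure"] * scale == pytest.approx(-0.2,
                                                                  rel=0.4)
        assert abs(fit.params["expenditure"]) < 1e-3
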
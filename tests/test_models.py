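import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from rohid import models


def make_samples(rng, n, n_pcs=15):
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "sex": rng.choice(["male", "female"], n),
            "age": rng.uniform(40, 60, n),
            "site": rng.choice(["a", "b", "c"], n),
            "SES.Q": rng.integers(1, 6, n),
            "edu": rng.integers(1, 5, n),
            "occu": rng.integers(1, 6, n),
            "night_light": rng.integers(0, 64, n),
            "height": rng.normal(165, 8, n),
            "BMI": rng.normal(26, 4, n),
        }
    )
    for j in range(1, n_pcs + 1):
        samples[f"pc{j}"] = rng.normal(0, 1, n)
    return samples


class TestBuildDesign:
    def test_weight_spec_columns(self, rng):
        samples = make_samples(rng, 50)
        samples["weight"] = rng.normal(70, 10, 50)
        y, x, kept = models.build_design("weight", samples)
        cols = list(x.columns)
        assert cols[0] == "intercept"
        assert any(c.startswith("sex_") for c in cols)
        assert "age" in cols and "age2" in cols
        assert any(c.startswith("SES.Q_") for c in cols)
        assert "night_light" in cols
        assert all(f"pc{j}" in cols for j in range(1, 16))
        assert "BMI" not in cols

    def test_pulse_spec_contains_bmi(self, rng):
        samples = make_samples(rng, 50)
        samples["pulse"] = rng.normal(70, 8, 50)
        _, x, _ = models.build_design("pulse", samples)
        assert "BMI" in x.columns

    def test_ses_spec_uses_edu_occu(self, rng):
        samples = make_samples(rng, 50)
        _, x, _ = models.build_design("SES.Q", samples)
        assert any(c.startswith("edu_") for c in x.columns)
        assert any(c.startswith("occu_") for c in x.columns)
        assert "age2" not in x.columns

    def test_unknown_covariate_error(self, rng):
        samples = make_samples(rng, 20)
        samples["trait"] = 1.0
        spec = models.CovariateModelSpec("trait", ["nonexistent"])
        with pytest.raises(KeyError):
            models.build_design("trait", samples, spec)

    def test_missing_rows_dropped(self, rng):
        samples = make_samples(rng, 30)
        samples["trait"] = rng.normal(0, 1, 30)
        samples.loc[3, "age"] = np.nan
        spec = models.CovariateModelSpec("trait", ["age", "sex"])
        y, x, kept = models.build_design("trait", samples, spec)
        assert len(y) == 29 and 3 not in kept


class TestFitPolygenic:
    def test_identity_grm_gives_ols_residuals(self, rng):
        n = 120
        x = pd.DataFrame({"intercept": 1.0, "z": rng.normal(0, 1, n)})
        y = 2 + 0.5 * x["z"].to_numpy() + rng.normal(0, 1, n)
        fit = models.fit_polygenic(y, x, np.eye(n))
        assert fit.unidentifiable
        assert fit.sigma_g2 == 0.0
        ols = sm.OLS(y, x).fit()
        assert np.allclose(fit.residuals, ols.resid, atol=1e-8)

    def test_variance_component_recovery(self, rng):
        # sib-pair GRM blocks, sigma_g2 = 2, sigma_e2 = 1
        n = 800
        a = np.kron(np.eye(n // 2), np.array([[1.0, 0.5], [0.5, 1.0]]))
        chol = np.linalg.cholesky(a + 1e-10 * np.eye(n))
        estimates = []
        for _ in range(8):
            u = np.sqrt(2.0) * (chol @ rng.standard_normal(n))
            y = 1.0 + u + rng.normal(0, 1, n)
            x = pd.DataFrame({"intercept": np.ones(n)})
            estimates.append(models.fit_polygenic(y, x, a).sigma_g2)
        estimates = np.array(estimates)
        se = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean() - 2.0) < 3 * se

    def test_exact_fit_zero_residuals(self, rng):
        n = 60
        x = pd.DataFrame({"intercept": 1.0, "z": rng.normal(0, 1, n)})
        y = 3.0 - 1.5 * x["z"].to_numpy()
        a = np.eye(n)
        fit = models.fit_polygenic(y, x, a)
        assert np.linalg.norm(fit.residuals) < 1e-8 * np.linalg.norm(y)

    def test_asymmetric_grm_rejected(self, rng):
        n = 10
        a = np.eye(n)
        a[0, 1] = 0.7
        with pytest.raises(ValueError, match="symmetric"):
            models.fit_polygenic(rng.normal(0, 1, n), np.ones((n, 1)), a)


def planted_profile(rng, n, beta=-30.0, noise_sd=1.0):
    froh = rng.exponential(0.01, n)
    resid = beta * froh + rng.normal(0, noise_sd, n)
    profile = pd.DataFrame({"F_ROH": froh}, index=[f"s{i}" for i in range(n)])
    return resid, profile


class TestFitId:
    def test_planted_effect_recovery(self, rng):
        resid, profile = planted_profile(rng, 4000)
        est = models.fit_id(resid, profile, include_f_outside=False)
        assert abs(est.beta - (-30.0)) < 3 * est.se

    def test_zero_variance_froh_error(self, rng):
        resid = rng.normal(0, 1, 100)
        profile = pd.DataFrame({"F_ROH": np.zeros(100)})
        with pytest.raises(ValueError, match="zero variance"):
            models.fit_id(resid, profile, include_f_outside=False)

    def test_scale_equivariance(self, rng):
        resid, profile = planted_profile(rng, 1000)
        e1 = models.fit_id(resid, profile, include_f_outside=False)
        e10 = models.fit_id(10 * resid, profile, include_f_outside=False)
        assert e10.beta == pytest.approx(10 * e1.beta)
        assert e10.beta_standardized == pytest.approx(e1.beta_standardized)

    def test_ci_contains_estimate(self, rng):
        resid, profile = planted_profile(rng, 500)
        est = models.fit_id(resid, profile, include_f_outside=False)
        assert est.ci_low < est.beta < est.ci_high

    def test_f_outside_included_when_present(self, rng):
        resid, profile = planted_profile(rng, 500)
        profile["F_outsideROH"] = rng.normal(0, 0.01, 500)
        est = models.fit_id(resid, profile, include_f_outside=True)
        assert np.isfinite(est.beta)


class TestFitBivariate:
    def test_fgrm_noise_covers_zero(self, rng):
        n = 2000
        resid, profile = planted_profile(rng, n)
        profile["F_GRM"] = rng.normal(0, 0.02, n)
        est = models.fit_bivariate(resid, profile)
        assert abs(est.beta_fgrm) < 2.5 * est.se_fgrm

    def test_collinear_error(self, rng):
        n = 200
        froh = rng.exponential(0.01, n)
        profile = pd.DataFrame({"F_ROH": froh, "F_GRM": froh})
        with pytest.raises(ValueError, match="collinear"):
            models.fit_bivariate(rng.normal(0, 1, n), profile)


class TestTwoStepProperty:
    def test_matches_one_step_when_orthogonalized(self, rng):
        # with identity GRM, residual-on-F regression equals the joint OLS
        # coefficient once F is orthogonal to the covariates
        n = 500
        x = pd.DataFrame(
            {"intercept": 1.0, "c1": rng.normal(0, 1, n), "c2": rng.normal(0, 1, n)}
        )
        raw_f = rng.exponential(0.01, n)
        xm = x.to_numpy()
        f_orth = raw_f - xm @ np.linalg.lstsq(xm, raw_f, rcond=None)[0]
        y = xm @ np.array([1.0, 0.3, -0.2]) - 25.0 * f_orth + rng.normal(0, 1, n)

        joint = sm.OLS(y, np.column_stack([xm, f_orth])).fit().params[-1]
        step1 = models.fit_polygenic(y, x, np.eye(n))
        profile = pd.DataFrame({"F_ROH": f_orth})
        step2 = models.fit_id(step1.residuals, profile, include_f_outside=False)
        assert step2.beta == pytest.approx(joint, rel=1e-6)


class TestStratifiedAndComparisons:
    def _sex_cohort(self, rng, n=1200, beta=(-10.0, 10.0)):
        samples = make_samples(rng, n, n_pcs=0)
        froh = rng.exponential(0.02, n)
        sex_beta = np.where(samples["sex"] == "male", beta[0], beta[1])
        samples["trait"] = sex_beta * froh + rng.normal(0, 0.5, n)
        profile = pd.DataFrame(
            {"F_ROH": froh, "F_outsideROH": rng.normal(0, 0.01, n)},
            index=samples["sample_id"].to_numpy(),
        )
        return samples, profile, froh

    def test_sex_specific_signs(self, rng):
        samples, profile, _ = self._sex_cohort(rng)
        spec = models.CovariateModelSpec("trait", ["age", "night_light"])
        ests = models.fit_stratified("trait", samples, profile, strata="sex", spec=spec)
        by = {e.stratum: e for e in ests}
        assert by["male"].beta < 0 < by["female"].beta
        assert by["male"].ci_high < 0 and by["female"].ci_low > 0

    def test_luminosity_strata_drop_night_light(self, rng):
        samples, profile, _ = self._sex_cohort(rng, beta=(-5.0, -5.0))
        spec = models.CovariateModelSpec("trait", ["age", "night_light"])
        ests = models.fit_stratified(
            "trait", samples, profile, strata="luminosity", spec=spec
        )
        assert len(ests) == 2
        assert all("luminosity" in e.stratum for e in ests)

    def test_small_stratum_skipped(self, rng):
        samples, profile, _ = self._sex_cohort(rng, n=200)
        samples.loc[samples.index[:195], "sex"] = "male"  # 5 females only
        spec = models.CovariateModelSpec("trait", ["age"])
        ests = models.fit_stratified("trait", samples, profile, strata="sex", spec=spec)
        assert [e.stratum for e in ests] == ["male"]

    def test_compare_strata_null_covers_zero(self, rng):
        n = 2000
        froh = rng.exponential(0.02, n)
        group = rng.choice(["a", "b"], n)
        resid = -5.0 * froh + rng.normal(0, 1, n)
        delta, p = models.compare_strata(resid, froh, group)
        assert p > 0.01

    def test_compare_strata_detects_opposite_betas(self, rng):
        n = 4000
        froh = rng.exponential(0.02, n)
        group = rng.choice(["a", "b"], n)
        beta = np.where(group == "a", -20.0, 20.0)
        resid = beta * froh + rng.normal(0, 1, n)
        delta, p = models.compare_strata(resid, froh, group)
        assert p < 0.001
        assert abs(delta - 40.0) < 10.0

    def test_compare_strata_single_group_error(self, rng):
        with pytest.raises(ValueError):
            models.compare_strata(rng.normal(0, 1, 10), rng.random(10), np.zeros(10))


def mannwhitney_enumeration_p(a, b):
    """Exact two-sided p by exhausting all rank assignments (oracle)."""
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    na = len(a)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    n = len(pooled)
    stats = []
    for combo in itertools.combinations(range(n), na):
        u = ranks[list(combo)].sum() - na * (na + 1) / 2
        stats.append(u)
    stats = np.array(stats)
    mean_u = na * (n - na) / 2
    return np.mean(np.abs(stats - mean_u) >= abs(u_obs - mean_u) - 1e-12)


class TestCompareBetaSets:
    def test_identical_sets_p_one(self):
        a = [1.0, 2.0, 3.0, 4.0]
        u, p = models.compare_beta_sets(a, a)
        assert p == pytest.approx(1.0)

    def test_fully_separated_nine_vs_nine(self):
        a = list(range(1, 10))
        b = [v + 100 for v in a]
        u, p = models.compare_beta_sets(a, b)
        assert u in (0.0, 81.0)
        # exact probability that all of one group ranks below the other
        import math

        expected = 2.0 / math.comb(18, 9)
        assert p == pytest.approx(expected, rel=1e-9)

    def test_matches_enumeration_oracle_small(self, rng):
        a = rng.normal(0, 1, 5)
        b = rng.normal(0.5, 1, 6)
        u, p = models.compare_beta_sets(a, b)
        assert p == pytest.approx(mannwhitney_enumeration_p(a, b), rel=1e-9)

    def test_one_element_shift_large_sets(self, rng):
        a = rng.normal(0, 1, 30)
        b = a.copy() + 1e-9
        b[0] += 0.1
        _, p = models.compare_beta_sets(a, b)
        assert p > 0.8

    def test_empty_set_error(self):
        with pytest.raises(ValueError):
            models.compare_beta_sets([], [1.0, 2.0])


class TestPredictedChange:
    def test_arithmetic(self):
        est = models.IDEstimate("t", "all", -64.0, 1.0, -66, -62, 0.01, -1.0, 100)
        assert models.predicted_change(est, 1 / 64) == pytest.approx(-1.0)

    def test_zero_beta(self):
        est = models.IDEstimate("t", "all", 0.0, 1.0, -2, 2, 0.9, 0.0, 100)
        assert models.predicted_change(est, 0.5) == 0.0

    def test_composition_with_recovery(self, rng):
        resid, profile = planted_profile(rng, 4000)
        est = models.fit_id(resid, profile, include_f_outside=False)
        change = models.predicted_change(est, models.SECOND_COUSIN_F)
        assert change == pytest.approx(-30.0 / 64.0, abs=3 * est.se / 64.0)
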
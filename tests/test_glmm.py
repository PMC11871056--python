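"""GLMM fitting, inference, and R² against independent oracles."""

import math
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special, stats

import pollscape as ps
from pollscape.glmm import GlmmError, ModelSpec, tweedie_logpdf
from conftest import simulate_nb_glmm


class TestFitGlmm:
    def test_gamma_intercept_is_log_sample_mean(self):
        rng = np.random.default_rng(7)
        y = rng.gamma(5.0, 2.0, size=200)
        df = pd.DataFrame({"y": y, "species": "X",
                           "bird_id": [f"b{i}" for i in range(200)]})
        fit = ps.fit_glmm(ModelSpec("y", "gamma", [], random_effects=None), df)
        assert fit.coefficients_link.iloc[0] == pytest.approx(math.log(y.mean()), abs=1e-6)

    def test_nb_intercept_matches_grid_search_oracle(self):
        rng = np.random.default_rng(8)
        y = rng.poisson(5.0, size=300).astype(float)
        df = pd.DataFrame({"y": y, "species": "X",
                           "bird_id": [f"b{i}" for i in range(300)]})
        fit = ps.fit_glmm(ModelSpec("y", "negative_binomial", [], random_effects=None), df)
        theta = fit.dispersion

        def nb_ll(b0):
            mu = math.exp(b0)
            return np.sum(special.gammaln(y + theta) - special.gammaln(theta)
                          - special.gammaln(y + 1) + theta * math.log(theta)
                          + y * b0 - (y + theta) * np.log(mu + theta))

        grid = np.linspace(1.0, 2.2, 24001)
        best = grid[np.argmax([nb_ll(b) for b in grid])]
        assert fit.coefficients_link.iloc[0] == pytest.approx(best, abs=1e-4)

    def test_mod1_style_parameter_recovery(self):
        """3 species, known log offsets, 50 birds x 5 trials: contrasts within 2 SE."""
        df = simulate_nb_glmm(birds_per_species=50, offsets=(2.0, 1.0, 1.5),
                              theta=1.0, sigma=0.5, seed=21)
        fit = ps.fit_glmm(ModelSpec("y", "negative_binomial", ["species"]), df)
        assert fit.converged
        truth = {"species[sp1]": -1.0, "species[sp2]": -0.5}
        for name, true_val in truth.items():
            est = fit.coefficients_link[name]
            se = fit.param_table.loc[name, "se"]
            assert abs(est - true_val) < 2 * se

    def test_response_scale_is_exp_of_link_scale(self, model_data):
        fit = ps.fit_glmm(ps.MODEL_SPECS["mod1"], model_data["per_trial"])
        assert np.allclose(fit.coefficients_response,
                           np.exp(fit.coefficients_link), rtol=1e-15)

    def test_gamma_rejects_zeros(self):
        df = pd.DataFrame({"y": [0.0, 1.0, 2.0] * 4, "species": "X",
                           "bird_id": ["a", "b", "c"] * 4})
        with pytest.raises(GlmmError, match="gamma"):
            ps.fit_glmm(ModelSpec("y", "gamma", []), df)

    def test_zero_inflation_requires_tweedie(self):
        with pytest.raises(GlmmError, match="tweedie"):
            ModelSpec("y", "gamma", [], zero_inflation="species")

    def test_matches_glmmTMB_reference(self):
        """Independent cross-check against the reference mixed-model fitter in R."""
        df = simulate_nb_glmm(birds_per_species=8, theta=1.0, sigma=0.5, seed=3)
        fit = ps.fit_glmm(ModelSpec("y", "negative_binomial", ["species"]), df)
        rscript = (
            "suppressMessages(library(glmmTMB));"
            "d <- read.csv('data.csv');"
            "m <- glmmTMB(y ~ species + (1|bird_id), data=d,"
            " family=nbinom2, REML=FALSE);"
            "cat(fixef(m)$cond, sigma(m), attr(VarCorr(m)$cond$bird_id,'stddev'), sep='\\n')"
        )
        import tempfile, os
        with tempfile.TemporaryDirectory() as td:
            df.to_csv(os.path.join(td, "data.csv"), index=False)
            out = subprocess.run(["Rscript", "-e", rscript], cwd=td,
                                 capture_output=True, text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        vals = [float(v) for v in out.stdout.split()]
        ref_beta, ref_theta, ref_sd = vals[:3], vals[3], vals[4]
        assert np.allclose(fit.coefficients_link.to_numpy(), ref_beta, atol=5e-3)
        assert fit.dispersion == pytest.approx(ref_theta, rel=0.02)
        assert math.sqrt(fit.random_variances["bird_id"]) == pytest.approx(ref_sd, abs=0.02)


class TestTweedieDensity:
    def test_normalizes_and_zero_mass(self):
        mu, phi, p = 2.0, 0.8, 1.6
        p0 = math.exp(tweedie_logpdf(np.array([0.0]), mu, phi, p)[0])
        mass, _ = integrate.quad(
            lambda v: math.exp(tweedie_logpdf(np.array([v]), mu, phi, p)[0]),
            1e-9, 60.0, limit=200)
        assert p0 + mass == pytest.approx(1.0, abs=1e-6)

    def test_moments(self):
        # mean mu, variance phi * mu^p
        mu, phi, p = 3.0, 0.5, 1.4
        m1, _ = integrate.quad(
            lambda v: v * math.exp(tweedie_logpdf(np.array([v]), mu, phi, p)[0]),
            1e-9, 100.0, limit=200)
        m2, _ = integrate.quad(
            lambda v: v * v * math.exp(tweedie_logpdf(np.array([v]), mu, phi, p)[0]),
            1e-9, 100.0, limit=200)
        assert m1 == pytest.approx(mu, rel=1e-6)
        assert m2 - m1 ** 2 == pytest.approx(phi * mu ** p, rel=1e-5)

    def test_matches_mgcv_ldTweedie(self):
        """Independent series-evaluation oracle from R's mgcv."""
        y = np.array([0.0, 0.1, 0.5, 1.0, 2.5, 7.0, 20.0])
        mu, phi, p = 2.0, 0.8, 1.6
        ours = tweedie_logpdf(y, mu, phi, p)
        rscript = (
            "suppressMessages(library(mgcv));"
            f"y <- c({','.join(map(str, y))});"
            f"cat(ldTweedie(y, mu={mu}, p={p}, phi={phi})[,1], sep='\\n')"
        )
        out = subprocess.run(["Rscript", "-e", rscript],
                             capture_output=True, text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        ref = np.array([float(v) for v in out.stdout.split()])
        assert np.allclose(ours, ref, atol=1e-8)

    def test_zero_inflated_tweedie_recovers_zi_probs(self):
        rng = np.random.default_rng(30)
        rows = []
        zi_true = {"spA": 0.45, "spB": 0.15}
        for sp, zp in zi_true.items():
            for b in range(25):
                u = rng.normal(0, 0.3)
                for _ in range(20):
                    if rng.random() < zp:
                        y = 0.0
                    else:  # compound Poisson-gamma: p=1.5, phi=0.5
                        mu = math.exp(1.0 + u)
                        lam = mu ** 0.5 / (0.5 * 0.5)
                        n = rng.poisson(lam)
                        y = rng.gamma(n, 0.5 * 0.5 * mu ** 0.5) if n else 0.0
                    rows.append({"bird_id": f"{sp}b{b}", "species": sp, "y": y})
        df = pd.DataFrame(rows)
        fit = ps.fit_glmm(ModelSpec("y", "tweedie", ["species"],
                                    zero_inflation="species"), df)
        assert fit.converged
        for sp, zp in zi_true.items():
            est = fit.zi_probs[sp]
            logit_se = fit.param_table.loc[f"zi[{sp}]", "se"]
            # delta method on the logit scale
            se = logit_se * est * (1 - est)
            assert abs(est - zp) < 2 * max(se, 0.01)


class TestInference:
    def test_one_df_term_equals_wald_z_test(self, model_data):
        fit = ps.fit_glmm(ps.MODEL_SPECS["mod7"], model_data["per_trial"])
        term = "patch_area_mm2"
        b = fit.coefficients_link[term]
        se = math.sqrt(fit.vcov_fixed.loc[term, term])
        p_z = 2 * stats.norm.sf(abs(b) / se)
        assert ps.type3_test(fit, term) == pytest.approx(p_z, rel=1e-10)

    def test_unknown_term_rejected(self, model_data):
        fit = ps.fit_glmm(ps.MODEL_SPECS["mod1"], model_data["per_trial"])
        with pytest.raises(GlmmError, match="term"):
            ps.type3_test(fit, "nonexistent")

    def test_tukey_with_two_levels_equals_z_test(self):
        df = simulate_nb_glmm(n_species=2, birds_per_species=10,
                              offsets=(2.0, 1.4), seed=5)
        fit = ps.fit_glmm(ModelSpec("y", "negative_binomial", ["species"]), df)
        (ct,) = ps.pairwise_contrasts(fit, "species")
        p_z = 2 * stats.norm.sf(abs(ct.estimate_link) / ct.se)
        assert ct.p_adjusted == pytest.approx(p_z, rel=1e-4)

    def test_tukey_adjustment_is_conservative(self, model_data):
        fit = ps.fit_glmm(ps.MODEL_SPECS["mod1"], model_data["per_trial"])
        for ct in ps.pairwise_contrasts(fit, "species"):
            p_raw = 2 * stats.norm.sf(abs(ct.estimate_link) / ct.se)
            assert ct.p_adjusted >= p_raw - 1e-12

    def test_identical_level_means_give_zero_contrast(self):
        rng = np.random.default_rng(9)
        y = rng.poisson(6.0, size=60).astype(float)
        df = pd.DataFrame({
            "y": np.concatenate([y, y, rng.poisson(20.0, 60)]).astype(float),
            "species": ["a"] * 60 + ["b"] * 60 + ["c"] * 60,
            "bird_id": [f"{g}{i % 10}" for g in "abc" for i in range(60)]})
        fit = ps.fit_glmm(ModelSpec("y", "negative_binomial", ["species"]), df)
        pair_ab = [c for c in ps.pairwise_contrasts(fit, "species")
                   if c.pair == ("a", "b")][0]
        assert pair_ab.estimate_link == pytest.approx(0.0, abs=1e-4)


class TestCohensD:
    def test_identical_groups_give_zero(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0] * 2, "species": ["a"] * 3 + ["b"] * 3})
        assert ps.cohens_d(df, "y", "a", "b") == 0.0

    def test_one_pooled_sd_apart_gives_unit_d(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = a + a.std(ddof=1)  # same spread, shifted by exactly one SD
        df = pd.DataFrame({"y": np.r_[a, b], "species": ["a"] * 4 + ["b"] * 4})
        assert abs(ps.cohens_d(df, "y", "a", "b")) == pytest.approx(1.0)

    def test_formula_oracle(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 13), rng.normal(0.7, 1.6, 9)
        df = pd.DataFrame({"y": np.r_[a, b], "species": ["a"] * 13 + ["b"] * 9})
        pooled = math.sqrt((12 * a.var(ddof=1) + 8 * b.var(ddof=1)) / 20)
        assert ps.cohens_d(df, "y", "a", "b") == pytest.approx(
            (a.mean() - b.mean()) / pooled, abs=1e-12)

    def test_zero_pooled_sd_is_error(self):
        df = pd.DataFrame({"y": [2.0] * 6, "species": ["a"] * 3 + ["b"] * 3})
        with pytest.raises(GlmmError, match="pooled SD"):
            ps.cohens_d(df, "y", "a", "b")


class TestR2Nakagawa:
    def test_intercept_only_marginal_zero(self):
        df = simulate_nb_glmm(n_species=1, birds_per_species=30, offsets=(2.0,), seed=6)
        fit = ps.fit_glmm(ModelSpec("y", "negative_binomial", []), df)
        r2 = ps.r2_nakagawa(fit)
        assert r2.marginal == pytest.approx(0.0, abs=1e-10)
        assert 0.0 <= r2.marginal <= r2.conditional <= 1.0

    def test_no_random_variance_makes_marginal_equal_conditional(self):
        df = simulate_nb_glmm(birds_per_species=10, sigma=0.0, seed=7)
        fit = ps.fit_glmm(ModelSpec("y", "negative_binomial", ["species"],
                                    random_effects=None), df)
        r2 = ps.r2_nakagawa(fit)
        assert r2.marginal == pytest.approx(r2.conditional, abs=1e-12)

    def test_trigamma_matches_asymptotic_expansion_at_large_theta(self):
        # large-theta NB limit: psi1(x) ~ 1/x + 1/(2x^2) for x = mu
        for mu in (10.0, 40.0):
            v = special.polygamma(1, 1.0 / (1.0 / mu + 1e-9))
            assert v == pytest.approx(1.0 / mu + 0.5 / mu ** 2, rel=0.05)

    def test_null_pc_effect_concentrates_marginal_r2_near_zero(self, model_data):
        """Replacing the matching scores by noise leaves marginal R² < 0.05."""
        rng = np.random.default_rng(23)
        r2s = []
        for _ in range(11):
            df = model_data["per_trial"].copy()
            df["abs_PC1_donor"] = np.abs(rng.normal(0, 2, len(df)))
            df["abs_PC2_donor"] = np.abs(rng.normal(0, 1, len(df)))
            fit = ps.fit_glmm(ps.MODEL_SPECS["mod6"], df)
            r2s.append(ps.r2_nakagawa(fit).marginal)
        assert np.median(r2s) < 0.05

    def test_ordering_invariant_on_study_models(self, model_data):
        for name in ("mod1", "mod4"):
            fit = ps.fit_glmm(ps.MODEL_SPECS[name], model_data["per_trial"])
            r2 = ps.r2_nakagawa(fit)
            assert 0.0 <= r2.marginal <= r2.conditional <= 1.0


class TestTrialEffectCheck:
    def test_returns_three_pvalues(self, metrics):
        res = ps.trial_effect_check(metrics)
        assert set(res) == {"trial", "species", "interaction"}
        assert all(0.0 <= p <= 1.0 for p in res.values())

    def test_power_against_injected_trial_trend(self):
        """+1 log unit per trial must be detected at 45 birds x 5 trials."""
        rng = np.random.default_rng(11)
        rows = []
        for k in range(3):
            for b in range(15):
                for t in range(1, 6):
                    mu = math.exp(0.5 * k + 1.0 * t)
                    rows.append({"bird_id": f"S{k}B{b}", "species": f"sp{k}",
                                 "trial_number": t,
                                 "stigma_pollen_count": float(rng.poisson(mu))})
        res = ps.trial_effect_check(pd.DataFrame(rows))
        assert res["trial"] < 0.001

    def test_null_trial_p_is_uniform(self):
        """With no trial effect the trial p value is Uniform(0,1)."""
        rng = np.random.default_rng(13)
        pvals = []
        for rep in range(200):
            rows = []
            for k in range(3):
                for b in range(5):
                    lam = math.exp(1.0 + 0.5 * k)
                    for t in range(1, 6):
                        rows.append({"bird_id": f"S{k}B{b}", "species": f"sp{k}",
                                     "trial_number": t,
                                     "stigma_pollen_count": float(rng.poisson(lam))})
            pvals.append(ps.trial_effect_check(pd.DataFrame(rows))["trial"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_balanced_design_type3_equals_type1(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(17)
        rows = [{"trial": t, "species": f"sp{k}", "y": rng.normal(k + t, 1.0)}
                for k in range(3) for t in range(1, 6) for _ in range(4)]
        df = pd.DataFrame(rows)
        m = smf.ols("y ~ C(trial, Sum) * C(species, Sum)", data=df).fit()
        t3 = sm.stats.anova_lm(m, typ=3)
        t1 = sm.stats.anova_lm(m, typ=1)
        assert t3.loc["C(trial, Sum)", "F"] == pytest.approx(
            t1.loc["C(trial, Sum)", "F"], rel=1e-8)
        assert t3.loc["C(trial, Sum):C(species, Sum)", "F"] == pytest.approx(
            t1.loc["C(trial, Sum):C(species, Sum)", "F"], rel=1e-8)
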
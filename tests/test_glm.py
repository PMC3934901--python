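"""The Poisson IRLS engine against closed forms, a brute-force likelihood
maximizer, and statsmodels as an independent oracle."""

import numpy as np
import pytest
from scipy import optimize, stats

import famepi as fp
from famepi.glm import poisson_loglik, score_vector
from famepi.simulate import simulate_design

from conftest import random_design


def brute_force_mle(design: fp.DesignResponse, start: np.ndarray | None = None):
    """Independent maximizer of the same likelihood (no IRLS)."""
    if start is None:
        start = np.zeros(design.X.shape[1])
        start[0] = np.log(design.y.mean() + 0.5)

    def neg_ll(beta):
        return -poisson_loglik(design.y, np.exp(design.X @ beta))

    res = optimize.minimize(neg_ll, start, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12,
                                     "maxiter": 20000, "maxfev": 20000})
    res = optimize.minimize(neg_ll, res.x, method="BFGS",
                            options={"gtol": 1e-10})
    return res.x


class TestClosedForms:
    def test_intercept_only_is_log_mean(self):
        d = fp.DesignResponse(np.ones((4, 1)), [2, 2, 2, 2], ("intercept",),
                              np.arange(4))
        fit = fp.fit_poisson(d)
        assert fit.coefficients["intercept"] == pytest.approx(np.log(2), abs=1e-10)
        assert fit.converged

    def test_two_group_slope_is_log_ratio_of_means(self):
        g = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        y = np.array([1, 2, 3, 4, 6, 8])
        d = fp.DesignResponse(np.column_stack([np.ones(6), g]), y,
                              ("intercept", "group"), np.arange(6))
        fit = fp.fit_poisson(d)
        assert fit.coefficients["group"] == pytest.approx(np.log(6 / 2), abs=1e-8)
        assert fit.coefficients["intercept"] == pytest.approx(np.log(2), abs=1e-8)


class TestOracleEquivalence:
    def test_matches_bruteforce_on_many_random_instances(self):
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(50):
            d = random_design(rng)
            fit = fp.fit_poisson(d)
            ref = brute_force_mle(d)
            worst = max(worst, np.abs(fit.coefficients.to_numpy() - ref).max())
        assert worst < 1e-5

    def test_matches_statsmodels_coefficients_and_loglik(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(11)
        d = random_design(rng, n=200, p=4)
        fit = fp.fit_poisson(d)
        ref = sm.GLM(d.y, d.X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-7)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)
        np.testing.assert_allclose(
            fit.covariance.to_numpy(), ref.cov_params(), rtol=1e-3, atol=1e-8
        )

    def test_clustered_sandwich_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(13)
        d = random_design(rng, n=120, p=3)
        groups = np.repeat(np.arange(30), 4)
        d.groups = groups
        fit = fp.fit_poisson(d, robust=True)
        ref = sm.GLM(d.y, d.X, family=sm.families.Poisson()).fit(
            cov_type="cluster", cov_kwds={"groups": groups, "use_correction": False}
        )
        np.testing.assert_allclose(
            fit.robust_covariance.to_numpy(), ref.cov_params(), rtol=1e-3, atol=1e-8
        )


class TestFitProperties:
    def test_score_vanishes_and_deviance_monotone(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            d = random_design(rng)
            fit = fp.fit_poisson(d)
            assert np.abs(score_vector(fit, d)).max() < 1e-6
            trace = np.array(fit.deviance_trace)
            assert (np.diff(trace) <= 1e-8).all()

    def test_aic_identity_and_nesting(self):
        rng = np.random.default_rng(5)
        d = random_design(rng, n=80, p=4)
        full = fp.fit_poisson(d)
        nested = fp.fit_poisson(d.subset(("intercept", "x1")))
        assert full.aic == pytest.approx(-2 * full.loglik + 2 * full.n_params)
        assert full.loglik >= nested.loglik  # adding covariates never hurts

    def test_rank_deficiency_names_the_column(self):
        X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
        d = fp.DesignResponse(X, np.ones(10), ("intercept", "a", "b"),
                              np.arange(10))
        with pytest.raises(fp.GlmError, match="collinear"):
            fp.fit_poisson(d)

    def test_nonconvergence_is_flagged_not_hidden(self):
        rng = np.random.default_rng(9)
        d = random_design(rng, n=100, p=4)
        with pytest.warns(fp.ConvergenceWarning):
            fit = fp.fit_poisson(d, max_iter=1)
        assert not fit.converged

    def test_identity_link_recovers_additive_rates(self):
        rng = np.random.default_rng(21)
        g = (rng.random(4000) < 0.5).astype(float)
        y = rng.poisson(2.0 + 1.5 * g)
        d = fp.DesignResponse(np.column_stack([np.ones(4000), g]), y,
                              ("intercept", "g"), np.arange(4000))
        fit = fp.fit_poisson(d, link="identity")
        assert fit.link == "identity"
        assert fit.coefficients["g"] == pytest.approx(1.5, abs=0.15)
        with pytest.raises(fp.GlmError, match="log-link"):
            fp.rate_ratio(fit, "g")


class TestRateRatio:
    @pytest.mark.parametrize("coef,expected", [(0.1271, 1.1355), (0.1245, 1.1326)])
    def test_exp_of_published_coefficients(self, coef, expected):
        # the published coefficient/rate-ratio pairs agree to 4 decimals
        assert np.exp(coef) == pytest.approx(expected, abs=5e-5)

    def test_null_coefficient_gives_unit_ratio_symmetric_ci(self):
        d = fp.DesignResponse(
            np.column_stack([np.ones(40), np.repeat([0.0, 1.0], 20)]),
            np.tile([1, 2, 3], 14)[:40], ("intercept", "g"), np.arange(40),
        )
        fit = fp.fit_poisson(d)
        fit.coefficients["g"] = 0.0  # evaluate the CI transform at beta = 0
        rr = fp.rate_ratio(fit, "g")
        assert rr.point == 1.0
        assert rr.lower * rr.upper == pytest.approx(1.0, rel=1e-10)

    def test_unknown_coefficient_rejected(self):
        d = fp.DesignResponse(np.ones((5, 1)), np.ones(5), ("intercept",),
                              np.arange(5))
        with pytest.raises(fp.GlmError, match="nope"):
            fp.rate_ratio(fp.fit_poisson(d), "nope")


class TestLrt:
    def test_identical_models_give_null_result(self):
        d = fp.DesignResponse(np.ones((6, 1)), [1, 2, 1, 2, 1, 2], ("intercept",),
                              np.arange(6))
        fit = fp.fit_poisson(d)
        res = fp.lrt(fit, fit)
        assert res.chi2 == 0.0 and res.df == 0 and res.p == 1.0

    def test_chi2_13_89_df1_upper_tail(self):
        # engineered loglik gap of 13.89/2 reproduces the published p = 0.0002
        rng = np.random.default_rng(1)
        d = random_design(rng, n=40, p=2)
        nested = fp.fit_poisson(d.subset(("intercept",)))
        full = fp.fit_poisson(d)
        full.loglik = nested.loglik + 13.89 / 2
        res = fp.lrt(nested, full)
        assert res.chi2 == pytest.approx(13.89)
        assert res.p == pytest.approx(1.938e-4, rel=1e-3)

    def test_differing_rows_rejected(self):
        rng = np.random.default_rng(2)
        d1 = random_design(rng, n=30)
        d2 = random_design(rng, n=31)
        with pytest.raises(fp.GlmError, match="rows"):
            fp.lrt(fp.fit_poisson(d1.subset(("intercept",))), fp.fit_poisson(d2))

    def test_non_nested_labels_rejected(self):
        rng = np.random.default_rng(4)
        d = random_design(rng, n=30, p=3)
        a = fp.fit_poisson(d.subset(("intercept", "x1")))
        b = fp.fit_poisson(d.subset(("intercept", "x2")))
        with pytest.raises(fp.GlmError, match="nested"):
            fp.lrt(a, b)

    def test_null_chi2_distribution_is_chi2_1(self):
        """Interaction LRT statistic ~ chi-square(1) when outcomes are
        independent Poisson draws under the null."""
        rng = np.random.default_rng(17)
        chis = []
        for _ in range(400):
            d = simulate_design(300, (1.18, 0.087, 0.0085, 0.0), rng=rng)
            res = fp.lrt(fp.fit_poisson(d.subset(("intercept", "g1", "g2"))),
                         fp.fit_poisson(d))
            chis.append(res.chi2)
        ks = stats.kstest(chis, stats.chi2(1).cdf)
        assert ks.pvalue > 0.01
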
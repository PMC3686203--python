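import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.special import expit, logit

from deforecast.defor_model import (
    DeforSampleSet,
    LogisticFit,
    annualize_rate,
    credible_interval,
    deviance,
    fit_interval_logistic,
    interval_prob,
    min_sample_size,
    variable_importance,
)
from deforecast.mcmc import McmcConfig
from deforecast.synthgen import generate_defor_samples


def intercept_only(z, Y):
    return DeforSampleSet(pd.DataFrame({
        "pixel_id": np.arange(len(z)), "z": z, "Y": Y,
    }))


class TestIntervalCorrection:
    def test_one_year_identity(self):
        for theta in (0.0, 0.013, 0.5, 0.99):
            assert interval_prob(theta, 1.0) == pytest.approx(theta)

    def test_five_year_example(self):
        assert interval_prob(0.01, 5) == pytest.approx(0.04900995, abs=1e-8)
        assert annualize_rate(0.04900995, 5) == pytest.approx(0.01, abs=1e-8)

    def test_zero_rate_stays_zero(self):
        assert interval_prob(0.0, 7.3) == 0.0

    def test_theta_one_saturates(self):
        assert interval_prob(1.0, 2.5) == 1.0

    def test_certain_loss_cannot_annualize(self):
        with pytest.raises(ValueError):
            annualize_rate(1.0, 5.0)

    @settings(deadline=None, derandomize=True)
    @given(
        theta=st.floats(min_value=0.001, max_value=0.1),
        Y=st.floats(min_value=0.5, max_value=10.0),
    )
    def test_round_trip_is_identity(self, theta, Y):
        assert annualize_rate(interval_prob(theta, Y), Y) == \
            pytest.approx(theta, rel=1e-9)

    @settings(deadline=None, derandomize=True)
    @given(
        t1=st.floats(min_value=0.01, max_value=0.5),
        t2=st.floats(min_value=0.01, max_value=0.5),
        y1=st.floats(min_value=0.5, max_value=10.0),
        y2=st.floats(min_value=0.5, max_value=10.0),
    )
    def test_strictly_increasing_in_rate_and_interval(self, t1, t2, y1, y2):
        if t1 != t2:
            lo, hi = sorted((t1, t2))
            assert interval_prob(lo, y1) < interval_prob(hi, y1)
        if y1 != y2:
            lo, hi = sorted((y1, y2))
            assert interval_prob(t1, lo) < interval_prob(t1, hi)


class TestFit:
    def test_intercept_only_matches_analytic_mle(self):
        """200 events in 20,000 one-year observations: p-hat = 1%."""
        z = np.zeros(20000, dtype=int)
        z[:200] = 1
        fit = fit_interval_logistic(intercept_only(z, np.ones(20000)),
                                    McmcConfig(seed=8))
        p_post = expit(fit.posterior_mean()[0])
        se = math.sqrt(0.01 * 0.99 / 20000)
        assert p_post == pytest.approx(0.01, abs=3 * se)

    def test_interval_exponent_recovers_annual_not_total_rate(self):
        """Constant 1%/yr seen over 2-yr windows: the corrected fit
        lands on the annual rate, a Y=1 fit on the 2-yr proportion."""
        rng = np.random.default_rng(9)
        n, theta = 10000, 0.01
        p2 = interval_prob(theta, 2.0)
        z = (rng.random(n) < p2).astype(int)
        mcmc = McmcConfig(seed=9)
        corrected = fit_interval_logistic(
            intercept_only(z, np.full(n, 2.0)), mcmc)
        naive = fit_interval_logistic(
            intercept_only(z, np.ones(n)), mcmc)
        rate_c = expit(corrected.posterior_mean()[0])
        rate_n = expit(naive.posterior_mean()[0])
        se2 = math.sqrt(p2 * (1 - p2) / n)
        assert rate_c == pytest.approx(annualize_rate(z.mean(), 2.0),
                                       abs=3 * se2)
        assert rate_n / rate_c == pytest.approx(2.0, abs=0.15)

    def test_posterior_matches_grid_search_mle(self):
        """Posterior means sit within 0.05 of a brute-force grid MLE."""
        data = generate_defor_samples(2000, -4.0, 0.02, seed=13)
        X, z, Y = data.arrays()

        def negll(beta):
            theta = expit(X @ beta)
            p = np.clip(interval_prob(theta, Y), 1e-12, 1 - 1e-12)
            return -float(z @ np.log(p) + (1 - z) @ np.log1p(-p))

        b0_grid = np.linspace(-6.0, -2.0, 81)
        b1_grid = np.linspace(-0.02, 0.06, 81)
        lls = np.array([[negll(np.array([b0, b1])) for b1 in b1_grid]
                        for b0 in b0_grid])
        i, j = np.unravel_index(lls.argmin(), lls.shape)
        mle = np.array([b0_grid[i], b1_grid[j]])

        fit = fit_interval_logistic(data, McmcConfig(seed=13))
        np.testing.assert_allclose(fit.posterior_mean(), mle, atol=0.05)

    def test_all_unit_intervals_reduce_to_standard_logistic(self):
        """With every Y=1 the likelihood is plain logistic regression:
        its optimum matches statsmodels GLM to 1e-3."""
        sm = pytest.importorskip("statsmodels.api")
        data = generate_defor_samples(5000, -2.0, 0.02,
                                      y_range=(1.0, 1.0 + 1e-12), seed=14)
        X, z, Y = data.arrays()
        glm = sm.GLM(z, X, family=sm.families.Binomial()).fit()

        def negll(beta):
            p = np.clip(interval_prob(expit(X @ beta), Y), 1e-12, 1 - 1e-12)
            return -float(z @ np.log(p) + (1 - z) @ np.log1p(-p))

        res = minimize(negll, np.zeros(2), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10})
        np.testing.assert_allclose(res.x, glm.params, atol=1e-3)

    def test_all_zero_outcomes_rejected(self):
        with pytest.raises(ValueError, match="no deforestation events"):
            fit_interval_logistic(
                intercept_only(np.zeros(100, dtype=int), np.ones(100)))

    def test_rank_deficient_design_rejected(self):
        df = pd.DataFrame({
            "pixel_id": range(100),
            "z": [1, 0] * 50,
            "Y": 1.0,
            "c": 3.0,  # constant: collinear with the intercept
        })
        with pytest.raises(ValueError, match="rank deficient"):
            fit_interval_logistic(DeforSampleSet(df, ["c"]))


class TestDeviance:
    def test_closed_form_at_even_split(self):
        """10 obs, 5 events, p-hat=0.5: D = -2*10*ln(0.5)."""
        z = np.array([1] * 5 + [0] * 5)
        data = intercept_only(z, np.ones(10))
        fit = LogisticFit(names=["intercept"],
                          samples=np.zeros((200, 1)), deviance=np.nan)
        assert deviance(fit, data) == pytest.approx(-2 * 10 * math.log(0.5),
                                                    abs=1e-9)
        assert deviance(fit, data) == pytest.approx(13.8629, abs=1e-4)

    def test_perfect_predictions_drive_deviance_to_zero(self):
        df = pd.DataFrame({
            "pixel_id": range(20),
            "z": [1] * 10 + [0] * 10,
            "Y": 1.0,
            "x": [30.0] * 10 + [-30.0] * 10,
        })
        data = DeforSampleSet(df, ["x"])
        fit = LogisticFit(names=["intercept", "x"],
                          samples=np.tile([0.0, 1.0], (200, 1)),
                          deviance=np.nan)
        assert deviance(fit, data) < 1e-6

    def test_nested_model_deviance_not_lower_at_optimum(self):
        """Adding a covariate can only lower the optimized deviance."""
        data = generate_defor_samples(2000, -3.0, 0.03, seed=15)
        X, z, Y = data.arrays()

        def best_dev(cols):
            Xs = X[:, cols]

            def negll(beta):
                p = np.clip(interval_prob(expit(Xs @ beta), Y),
                            1e-12, 1 - 1e-12)
                return -float(z @ np.log(p) + (1 - z) @ np.log1p(-p))

            res = minimize(negll, np.zeros(len(cols)), method="Nelder-Mead")
            return 2 * res.fun

        assert best_dev([0, 1]) <= best_dev([0]) + 1e-6


class TestVariableImportance:
    def test_null_covariate_gains_little_strong_covariate_gains_much(self):
        rng = np.random.default_rng(16)
        n = 10000
        x = rng.standard_normal(n)
        noise = rng.standard_normal(n)
        eta = -2.5 + 2.0 * x  # strong effect: 2 SD of the covariate
        z = (rng.random(n) < expit(eta)).astype(int)
        df = pd.DataFrame({"pixel_id": range(n), "z": z, "Y": 1.0,
                           "x": x, "noise": noise})
        data = DeforSampleSet(df, ["x", "noise"])
        table = variable_importance(
            data, mcmc=McmcConfig(n_burn=1500, n_iter=1500, thin=3, seed=16))
        gains = dict(zip(table["factor"], table["gain"]))
        assert abs(gains["noise"]) < 4.0
        assert gains["x"] > 100.0

    def test_gains_report_integer_deviance_points(self):
        table = pd.DataFrame({"factor": ["a"], "gain": [584.3]})
        table["gain_points"] = table["gain"].round().astype("Int64")
        assert table["gain_points"].iloc[0] == 584


class TestCredibleInterval:
    @staticmethod
    def fit_from(draws):
        draws = np.asarray(draws, dtype=float).reshape(-1, 1)
        return LogisticFit(names=["intercept"], samples=draws,
                           deviance=np.nan)

    def test_quantile_rule_on_1_to_100(self):
        ci = credible_interval(self.fit_from(np.arange(1, 101)))
        assert ci["low"].iloc[0] == pytest.approx(3.475)
        assert ci["high"].iloc[0] == pytest.approx(97.525)
        assert bool(ci["significant"].iloc[0])

    def test_symmetric_draws_not_significant(self):
        draws = np.concatenate([np.linspace(-1, 1, 200)])
        ci = credible_interval(self.fit_from(draws))
        assert not bool(ci["significant"].iloc[0])

    def test_constant_nonzero_draws_significant(self):
        ci = credible_interval(self.fit_from(np.full(150, 2.5)))
        assert ci["low"].iloc[0] == ci["high"].iloc[0] == 2.5
        assert bool(ci["significant"].iloc[0])

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="100"):
            credible_interval(self.fit_from(np.arange(50)))


class TestMinSampleSize:
    def test_design_rate_one_percent(self):
        n = min_sample_size(0.01, 0.001, 0.95)
        assert round(n, -3) == 38000  # two significant figures

    def test_half_rate(self):
        assert min_sample_size(0.5, 0.05, 0.95) == 385

    def test_quadratic_scaling_in_halfwidth(self):
        base = 1.959963984540054**2 * 0.01 * 0.99
        n1 = min_sample_size(0.01, 0.001)
        n4 = min_sample_size(0.01, 0.002)
        # exact quarter before the ceiling
        assert base / 0.001**2 == pytest.approx(4 * base / 0.002**2)
        assert n1 == pytest.approx(4 * n4, abs=4)
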
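"""Censored-data log-likelihood, score, information and ML fitting."""

import math

import numpy as np
import pytest
from scipy import optimize

import firthaft as fa
from firthaft._numdiff import approx_gradient, approx_hessian
from firthaft.likelihood import ParamVector, SurvivalDataset

from conftest import simulate_data


def one_subject(y, delta):
    return SurvivalDataset(y=[y], delta=[delta], X=[[1.0]])


def theta_loglik(data, dist):
    return lambda th: fa.loglik(data, dist, ParamVector(th[:-1], th[-1]))


class TestLoglik:
    def test_single_event_normal(self):
        pv = ParamVector([0.0], 1.0)
        assert fa.loglik(one_subject(0.0, 1), "normal", pv) == pytest.approx(
            -0.9189385, abs=1e-6
        )

    def test_single_censored_extreme_value(self):
        pv = ParamVector([0.0], 1.0)
        assert fa.loglik(one_subject(0.0, 0), "extreme_value", pv) == pytest.approx(-1.0)

    def test_matches_hand_summed_logistic(self):
        # independent scalar-by-scalar evaluation of the likelihood formula
        y, delta, b = (0.0, 0.5, -0.5), (1, 1, 0), 0.67
        expected = -2 * math.log(b)
        for yi, di in zip(y, delta):
            z = yi / b
            if di:
                expected += z - 2 * math.log(1 + math.exp(z))
            else:
                expected += -math.log(1 + math.exp(z))
        data = SurvivalDataset(y=y, delta=delta, X=np.ones((3, 1)))
        got = fa.loglik(data, "logistic", ParamVector([0.0], b))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_rejects_nonpositive_scale(self):
        with pytest.raises(ValueError):
            ParamVector([0.0], 0.0)


class TestScoreAndInformation:
    def test_score_hand_example(self):
        # single uncensored normal subject: U_0 = z/b, U_b = -1/b + z^2/b
        data = one_subject(0.3, 1)
        s = fa.score(data, "normal", ParamVector([0.0], 1.0))
        np.testing.assert_allclose(s, [0.3, -1 + 0.09], atol=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_score_and_information_match_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        dist = fa.available_distributions()[seed % 3]
        data = simulate_data(dist=dist, n=40, target_censoring=0.3, seed=100 + seed)
        pv = ParamVector(np.array([3.0, 0.7, 1.2]) + 0.3 * rng.standard_normal(3),
                         0.67 * math.exp(0.2 * rng.standard_normal()))
        f = theta_loglik(data, dist)
        np.testing.assert_allclose(
            fa.score(data, dist, pv), approx_gradient(f, pv.theta), rtol=1e-5, atol=1e-5
        )
        info = fa.observed_information(data, dist, pv)
        np.testing.assert_allclose(info, -approx_hessian(f, pv.theta),
                                   rtol=1e-4, atol=1e-4)

    def test_information_uncensored_normal_beta_block(self, uncensored_normal_data):
        """A_i = -1 for uncensored normal errors, so the beta block is X'X/b^2."""
        data = uncensored_normal_data
        pv = ParamVector([1.0, 0.5, -0.3], 0.8)
        info = fa.observed_information(data, "normal", pv)
        np.testing.assert_allclose(info[:3, :3], data.X.T @ data.X / 0.8**2, rtol=1e-12)

    def test_information_single_censored_extreme_value(self):
        info = fa.observed_information(one_subject(0.0, 0), "extreme_value",
                                       ParamVector([0.0], 1.0))
        assert info[0, 0] == pytest.approx(1.0)  # -A_1 x^2 / b^2 with A_1 = -e^0


class TestFitMLE:
    def test_score_vanishes_at_optimum(self, weibull_data):
        fit = fa.fit_mle(weibull_data, "weibull")
        assert fit.converged
        assert np.max(np.abs(fa.score(weibull_data, "weibull", fit.params))) < 1e-4

    def test_uncensored_lognormal_equals_least_squares(self, uncensored_normal_data):
        data = uncensored_normal_data
        fit = fa.fit_mle(data, "lognormal")
        beta_ols, *_ = np.linalg.lstsq(data.X, data.y, rcond=None)
        rss = float(np.sum((data.y - data.X @ beta_ols) ** 2))
        np.testing.assert_allclose(fit.params.beta, beta_ols, atol=1e-6)
        assert fit.params.b == pytest.approx(math.sqrt(rss / data.n), abs=1e-6)

    def test_uncensored_weibull_matches_multistart_oracle(self):
        """Direct multi-start optimization of an independently coded objective."""
        data = simulate_data(n=50, target_censoring=0.0, seed=17)

        def neg_ll(th):  # extreme-value regression log-likelihood, written out
            beta, b = th[:-1], th[-1]
            if b <= 0:
                return 1e12
            z = (data.y - data.X @ beta) / b
            return -(np.sum(z - np.exp(z)) - data.n * np.log(b))

        best = np.inf
        for s in range(3):
            rng = np.random.default_rng(s)
            x0 = np.concatenate([rng.normal(3, 1, 1), rng.normal(0, 1, 2), [0.5]])
            res = optimize.minimize(neg_ll, x0, method="Nelder-Mead",
                                    options={"xatol": 1e-10, "fatol": 1e-12,
                                             "maxiter": 20000})
            best = min(best, res.fun)
        fit = fa.fit_mle(data, "weibull")
        assert fit.objective == pytest.approx(-best, abs=1e-6)

    def test_location_equivariance(self, weibull_data):
        """Shifting all log-times by c moves only the intercept, by exactly c."""
        fit = fa.fit_mle(weibull_data, "weibull")
        shifted = SurvivalDataset(y=weibull_data.y + 2.5, delta=weibull_data.delta,
                                  X=weibull_data.X,
                                  covariate_names=weibull_data.covariate_names)
        fit2 = fa.fit_mle(shifted, "weibull")
        assert fit2.params.beta[0] == pytest.approx(fit.params.beta[0] + 2.5, abs=1e-6)
        np.testing.assert_allclose(fit2.params.beta[1:], fit.params.beta[1:], atol=1e-6)
        assert fit2.params.b == pytest.approx(fit.params.b, abs=1e-6)

    def test_covariate_scaling_equivariance(self, weibull_data):
        fit = fa.fit_mle(weibull_data, "weibull")
        X = weibull_data.X.copy()
        X[:, 2] *= 4.0
        scaled = SurvivalDataset(y=weibull_data.y, delta=weibull_data.delta, X=X,
                                 covariate_names=weibull_data.covariate_names)
        fit2 = fa.fit_mle(scaled, "weibull")
        assert fit2.params.beta[2] * 4.0 == pytest.approx(fit.params.beta[2], abs=1e-6)
        assert fit2.objective == pytest.approx(fit.objective, abs=1e-6)

    def test_all_censored_refused(self):
        data = SurvivalDataset(y=np.zeros(10), delta=np.zeros(10), X=np.ones((10, 1)))
        with pytest.raises(ValueError, match="no events"):
            fa.fit_mle(data, "weibull")

    def test_rank_deficient_design_names_columns(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(20)
        X = np.column_stack([np.ones(20), x, 2 * x])
        data = SurvivalDataset(y=rng.standard_normal(20), delta=np.ones(20), X=X,
                               covariate_names=("x1", "x1_copy"))
        with pytest.raises(ValueError, match="rank deficient"):
            fa.fit_mle(data, "weibull")

    def test_too_few_subjects_refused(self):
        data = SurvivalDataset(y=[0.1, 0.2], delta=[1, 1],
                               X=np.column_stack([np.ones(2), [0.0, 1.0]]))
        with pytest.raises(ValueError, match="p\\+2"):
            fa.fit_mle(data, "weibull")


class TestDatasetValidation:
    def test_rejects_bad_event_codes(self):
        with pytest.raises(ValueError, match="0 or 1"):
            SurvivalDataset(y=[0.0], delta=[2.0], X=[[1.0]])

    def test_rejects_missing_intercept(self):
        with pytest.raises(ValueError, match="ones"):
            SurvivalDataset(y=[0.0, 1.0], delta=[1, 0], X=[[2.0], [1.0]])

    def test_rejects_nonfinite_logtime(self):
        with pytest.raises(ValueError, match="finite"):
            SurvivalDataset(y=[np.inf], delta=[1], X=[[1.0]])
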
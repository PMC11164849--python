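"""Likelihood, gradient, oracle agreement, recovery and crossover logic
of the cumulative-logit model."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import approx_fprime
from scipy.special import expit

from borg_anchor.errors import DomainError, FitFailedError
from borg_anchor.ordinal import (
    ModelSpec,
    _nll_grad,
    _objective,
    _pack,
    find_crossovers,
    fit_cumulative_logit,
    negative_log_likelihood,
    odds_ratio_table,
    predict_probabilities,
)


def simulate_design(n, beta, zeta, seed, covariates=("a", "b", "c", "d", "e")):
    """Ordinal draws straight from the model on a random Gaussian design."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, len(beta)))
    u = X @ beta + rng.logistic(size=n)
    y = (u[:, None] > np.asarray(zeta)[None, :]).sum(axis=1)
    frame = pd.DataFrame(X, columns=covariates)
    frame["y"] = y
    return frame


BETA = np.array([0.5, -0.3, 0.25, 0.0, 0.15])
ZETA = np.array([-2.0, -1.0, -0.2, 0.6, 1.5, 2.5])


class TestLikelihood:
    def test_single_symmetric_observation(self):
        # one observation, two categories, cutpoint at 0, beta = 0 -> p = 1/2
        nll = negative_log_likelihood([0.0], [0.0], [[1.0]], [0])
        assert nll == pytest.approx(-math.log(0.5))

    def test_category_probabilities_sum_to_one(self):
        rng = np.random.default_rng(1)
        zeta = np.sort(rng.normal(size=6))
        beta = rng.normal(size=3)
        for _ in range(10):
            x = rng.normal(size=3)
            z = np.concatenate(([-np.inf], zeta, [np.inf]))
            probs = np.diff(expit(z - x @ beta))
            assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_non_increasing_cutpoints_rejected(self):
        with pytest.raises(DomainError):
            negative_log_likelihood([0.0], [1.0, 0.5], [[1.0]], [0])

    def test_matches_statsmodels_loglike_on_fixed_design(self):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        frame = simulate_design(200, BETA, ZETA, seed=7)
        X = frame[list("abcde")].to_numpy()
        y = frame["y"].to_numpy()
        model = OrderedModel(y, X, distr="logit")
        # statsmodels parameterises cutpoint increments on the log scale
        params = np.concatenate([BETA, [ZETA[0]], np.log(np.diff(ZETA))])
        ours = negative_log_likelihood(BETA, ZETA, X, y)
        assert ours == pytest.approx(-model.loglike(params), rel=1e-10)

    def test_analytic_gradient_matches_central_differences(self):
        frame = simulate_design(300, BETA, ZETA, seed=3)
        X = frame[list("abcde")].to_numpy()
        y = frame["y"].to_numpy()
        theta = _pack(np.full(5, 0.1), np.linspace(-1.8, 1.8, 6))
        f = lambda t: _objective(t, X, y, 5, 7)[0]  # noqa: E731
        num = np.empty_like(theta)
        h = 1e-6
        for j in range(len(theta)):
            up, dn = theta.copy(), theta.copy()
            up[j] += h
            dn[j] -= h
            num[j] = (f(up) - f(dn)) / (2.0 * h)
        ana = _objective(theta, X, y, 5, 7)[1]
        assert np.max(np.abs(num - ana) / (1.0 + np.abs(num))) < 1e-5


class TestFit:
    def test_two_category_outcome_reduces_to_binary_logistic(self):
        import statsmodels.api as sm

        frame = simulate_design(800, BETA, [0.3], seed=11)
        fit = fit_cumulative_logit(ModelSpec("y", tuple("abcde")), frame)
        assert fit.converged
        logit = sm.Logit(frame["y"], sm.add_constant(frame[list("abcde")])).fit(disp=False)
        params = logit.params.to_numpy()
        # P(Y=1) = logistic(x'b - zeta): slopes match, intercept = -zeta
        assert np.allclose(fit.beta, params[1:], atol=1e-6)
        assert fit.zeta[0] == pytest.approx(-params[0], abs=1e-6)

    def test_oracle_agreement_on_fixed_design(self):
        """Coefficients, ORs and predictions against statsmodels' ordinal
        model on one frozen 200 x 5 design."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        frame = simulate_design(200, BETA, ZETA, seed=7)
        fit = fit_cumulative_logit(ModelSpec("y", tuple("abcde")), frame)
        assert fit.converged
        om = OrderedModel(frame["y"], frame[list("abcde")], distr="logit").fit(
            method="bfgs", disp=False, gtol=1e-10
        )
        sm_beta = om.params.iloc[:5].to_numpy()
        assert np.allclose(fit.beta, sm_beta, atol=2e-5)
        ours = odds_ratio_table(fit)
        assert np.allclose(ours["or"], np.exp(sm_beta), rtol=1e-4)
        x = {"a": 0.3, "b": -1.0, "c": 0.5, "d": 0.0, "e": 2.0}
        sm_probs = om.model.predict(om.params, exog=np.array([[*x.values()]]))[0]
        assert np.allclose(predict_probabilities(fit, x), sm_probs, atol=1e-6)

    def test_loglik_at_optimum_beats_truth(self):
        frame = simulate_design(500, BETA, ZETA, seed=19)
        fit = fit_cumulative_logit(ModelSpec("y", tuple("abcde")), frame)
        X = frame[list("abcde")].to_numpy()
        truth_nll = negative_log_likelihood(BETA, ZETA, X, frame["y"].to_numpy())
        assert fit.loglik >= -truth_nll - 1e-8

    def test_unobserved_levels_are_dropped_with_labels_kept(self):
        frame = simulate_design(300, BETA, ZETA, seed=2)
        frame["y"] = frame["y"].replace({3: 2})  # level 3 never observed
        fit = fit_cumulative_logit(ModelSpec("y", tuple("abcde")), frame)
        assert fit.converged
        assert 3 not in fit.category_labels
        assert len(fit.zeta) == len(fit.category_labels) - 1

    def test_constant_covariate_yields_failure_result(self):
        frame = simulate_design(200, BETA, ZETA, seed=5)
        frame["a"] = 1.0
        fit = fit_cumulative_logit(ModelSpec("y", tuple("abcde")), frame)
        assert not fit.converged
        assert "a" in fit.failure
        with pytest.raises(FitFailedError):
            odds_ratio_table(fit)

    def test_single_category_outcome_yields_failure_result(self):
        frame = simulate_design(100, BETA, ZETA, seed=5)
        frame["y"] = 4
        fit = fit_cumulative_logit(ModelSpec("y", tuple("abcde")), frame)
        assert not fit.converged and "categories" in fit.failure

    def test_proportional_odds_identity(self):
        """log cumulative-odds difference between two profiles is the
        same at every cutpoint (algebraic structure of the model)."""
        frame = simulate_design(400, BETA, ZETA, seed=23)
        fit = fit_cumulative_logit(ModelSpec("y", tuple("abcde")), frame)
        x1 = dict(zip("abcde", [0.2, 0.1, -0.4, 1.0, 0.0]))
        x2 = dict(zip("abcde", [-1.0, 0.6, 0.3, -0.2, 0.8]))
        p1 = np.cumsum(predict_probabilities(fit, x1))[:-1]
        p2 = np.cumsum(predict_probabilities(fit, x2))[:-1]
        diff = np.log(p1 / (1 - p1)) - np.log(p2 / (1 - p2))
        assert np.allclose(diff, diff[0], atol=1e-8)

    def test_wald_ci_coverage_over_replicates(self):
        """Pooled 95% CI coverage across 50 simulated refits stays in a
        binomial-plausible band around 0.95."""
        hits = 0
        total = 0
        for rep in range(50):
            frame = simulate_design(2000, BETA, ZETA, seed=100 + rep)
            fit = fit_cumulative_logit(ModelSpec("y", tuple("abcde")), frame)
            assert fit.converged
            table = odds_ratio_table(fit)
            truth = np.exp(BETA)
            hits += int(((table["ci_low"] <= truth) & (truth <= table["ci_high"])).sum())
            total += 5
        assert 0.905 <= hits / total <= 0.985


class TestPrediction:
    def _fit(self):
        frame = simulate_design(600, BETA, ZETA, seed=31)
        return fit_cumulative_logit(ModelSpec("y", tuple("abcde")), frame)

    def test_zero_beta_probabilities_are_cutpoint_increments(self):
        from borg_anchor.ordinal import OrdinalFit

        zeta = np.array([-1.0, 0.0, 1.2])
        fit = OrdinalFit(
            beta=np.zeros(2), zeta=zeta, loglik=0.0, vcov=np.eye(5),
            covariate_names=("a", "b"), category_labels=np.arange(4),
            converged=True, n_used=10,
        )
        probs = predict_probabilities(fit, {"a": 3.0, "b": -7.0})
        expected = np.diff(expit(np.concatenate(([-np.inf], zeta, [np.inf]))))
        assert np.allclose(probs, expected)

    def test_extreme_linear_predictor_concentrates_top_category(self):
        fit = self._fit()
        probs = predict_probabilities(fit, dict(zip("abcde", [50.0, -50.0, 50.0, 0.0, 50.0])))
        assert probs[-1] == pytest.approx(1.0, abs=1e-6)

    def test_profile_dimension_mismatch_rejected(self):
        fit = self._fit()
        with pytest.raises(DomainError):
            predict_probabilities(fit, [0.1, 0.2])


def _toy_fit(beta, zeta, names=("a", "b")):
    from borg_anchor.ordinal import OrdinalFit

    beta = np.asarray(beta, dtype=float)
    zeta = np.asarray(zeta, dtype=float)
    k = len(beta) + len(zeta)
    return OrdinalFit(
        beta=beta, zeta=zeta, loglik=0.0, vcov=np.eye(k),
        covariate_names=tuple(names), category_labels=np.arange(len(zeta) + 1),
        converged=True, n_used=100,
    )


class TestCrossovers:
    def _fit(self):
        frame = simulate_design(600, BETA, ZETA, seed=37)
        return fit_cumulative_logit(ModelSpec("y", tuple("abcde")), frame)

    def test_zero_effect_covariate_has_no_crossover(self):
        fit = _toy_fit([0.7, 0.0], [-1.0, 0.0, 1.0])
        profile = find_crossovers(fit, "b", np.linspace(-5, 5, 41), {"a": 0.0})
        assert profile.crossovers == []

    def test_constructed_crossover_found_at_known_location(self):
        """With evenly spaced cutpoints the most-probable category flips
        from j to j+1 exactly where the linear predictor crosses zeta_j;
        the detected midpoint must land within one grid step of it."""
        fit = _toy_fit([1.0, 0.0], [-3.0, -1.0, 1.0, 3.0])
        grid = np.linspace(-0.5, 2.5, 61)  # brackets only the eta = 1.0 flip
        profile = find_crossovers(fit, "a", grid, {"b": 0.0})
        assert len(profile.crossovers) == 1
        at, lo, hi = profile.crossovers[0]
        assert (lo, hi) == (2, 3)
        assert abs(at - 1.0) <= grid[1] - grid[0]

    def test_monotone_effect_gives_monotone_categories(self):
        fit = self._fit()
        fixed = dict(zip("bcde", [0.0, 0.0, 0.0, 0.0]))
        profile = find_crossovers(fit, "a", np.linspace(-6.0, 6.0, 121), fixed)
        assert fit.beta[0] > 0
        assert np.all(np.diff(profile.most_probable) >= 0)

    def test_probability_rows_sum_to_one(self):
        fit = self._fit()
        fixed = dict(zip("bcde", [0.3, -0.1, 0.2, 0.4]))
        profile = find_crossovers(fit, "a", np.linspace(-2, 2, 11), fixed)
        assert np.allclose(profile.probabilities.sum(axis=1), 1.0, atol=1e-10)

    def test_short_grid_rejected(self):
        fit = self._fit()
        with pytest.raises(DomainError):
            find_crossovers(fit, "a", [0.0], dict(zip("bcde", [0.0] * 4)))
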
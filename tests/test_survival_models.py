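"""Tests of parametric fitting, model selection and HR adjustment."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from lifelines import LogLogisticFitter, WeibullFitter

from sincea.survival_models import (
    FAMILIES,
    FitError,
    ParametricFit,
    fit_all_families,
    fit_family,
    hr_adjust,
    loglogistic_survival,
    select_best,
)


def sample_family(family, params, n, rng):
    """Inverse-transform sampler per family — the independent oracle used
    to generate ground-truth data for MLE recovery checks."""
    u = rng.uniform(size=n)
    if family == "exponential":
        (lam,) = params
        return -np.log(u) / lam
    if family == "weibull":
        k, s = params
        return s * (-np.log(u)) ** (1 / k)
    if family == "lognormal":
        mu, s = params
        return np.exp(mu + s * rng.standard_normal(n))
    if family == "loglogistic":
        th, ka = params
        return ((1 - u) / u) ** (1 / ka) * np.exp(-th / ka)
    if family == "gompertz":
        a, b = params
        return np.log1p(-(b / a) * np.log(u)) / b
    raise ValueError(family)


TRUE_PARAMS = {
    "exponential": (0.05,),
    "weibull": (1.4, 20.0),
    "lognormal": (2.7, 0.9),
    "loglogistic": (-4.0, 1.5),
    "gompertz": (0.02, 0.08),
}


def _censored_sample(family, n=2000, seed=7, censor_q=0.8):
    rng = np.random.default_rng(seed)
    t = sample_family(family, TRUE_PARAMS[family], n, rng)
    cutoff = np.quantile(t, censor_q)
    return np.minimum(t, cutoff), (t <= cutoff).astype(int)


class TestLogLogisticSurvival:
    def test_starts_at_one_and_halves_at_median(self):
        theta, kappa = -3.0, 1.2
        assert loglogistic_survival(theta, kappa, 0.0) == 1.0
        med = math.exp(-theta / kappa)
        assert loglogistic_survival(theta, kappa, med) == pytest.approx(0.5, rel=1e-12)

    def test_direct_evaluation(self):
        # 1 / (1 + e^{-1} * 2^2)
        expected = 1.0 / (1.0 + math.exp(-1.0) * 4.0)
        assert loglogistic_survival(-1.0, 2.0, 2.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.40461, rel=1e-4)

    def test_strictly_decreasing(self):
        t = np.linspace(0.1, 50, 200)
        s = loglogistic_survival(-2.0, 1.3, t)
        assert np.all(np.diff(s) < 0)

    def test_invalid_kappa_rejected(self):
        with pytest.raises(ValueError):
            loglogistic_survival(0.0, -1.0, 1.0)


class TestHrAdjust:
    def test_identity_and_extremes(self):
        assert hr_adjust(0.8, 1.0) == 0.8
        assert hr_adjust(1.0, 7.3) == 1.0
        assert hr_adjust(0.8, 0.5) == pytest.approx(math.sqrt(0.8), rel=1e-12)

    def test_nonpositive_hr_rejected(self):
        with pytest.raises(ValueError):
            hr_adjust(0.5, 0.0)

    @given(st.floats(min_value=0.05, max_value=5.0))
    def test_preserves_monotonicity_and_bounds(self, hr):
        s = np.linspace(1.0, 0.0, 50)
        out = hr_adjust(s, hr)
        assert np.all((out >= 0) & (out <= 1))
        assert np.all(np.diff(out) <= 0)


class TestFitFamily:
    def test_exponential_mle_matches_closed_form(self):
        """events / total-time is the exponential MLE — the independent
        closed-form oracle for the numeric optimizer."""
        time, event = _censored_sample("exponential", seed=11)
        fit = fit_family((time, event), "exponential")
        closed_form = event.sum() / time.sum()
        assert fit.params[0] == pytest.approx(closed_form, rel=1e-4)
        assert fit.params[0] == pytest.approx(0.05, rel=0.05)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_parameter_recovery_within_ten_percent(self, family):
        time, event = _censored_sample(family, n=2000, seed=7)
        fit = fit_family((time, event), family)
        for est, true in zip(fit.params, TRUE_PARAMS[family]):
            assert abs(est - true) / abs(true) < 0.10

    @pytest.mark.parametrize("family", FAMILIES)
    def test_fitted_survivor_function_is_valid(self, family):
        time, event = _censored_sample(family, n=500, seed=3)
        fit = fit_family((time, event), family)
        t = np.linspace(0, 200, 400)
        s = fit.survival(t)
        assert s[0] == 1.0
        assert np.all((s >= 0) & (s <= 1))
        assert np.all(np.diff(s) <= 1e-12)

    def test_information_criterion_identities(self):
        time, event = _censored_sample("weibull", n=300, seed=5)
        for fit in fit_all_families((time, event)):
            k = len(fit.params)
            assert fit.aic == pytest.approx(2 * k - 2 * fit.loglik, abs=1e-9)
            assert fit.bic == pytest.approx(k * math.log(fit.n) - 2 * fit.loglik, abs=1e-9)

    def test_loglikelihood_agrees_with_lifelines(self):
        """Independent cross-check: lifelines' Weibull and log-logistic
        fitters reach the same maximized log-likelihood (within optimizer
        tolerance) on the same censored sample."""
        time, event = _censored_sample("weibull", n=800, seed=9)
        ours = fit_family((time, event), "weibull")
        wf = WeibullFitter().fit(time, event)
        assert ours.loglik == pytest.approx(wf.log_likelihood_, abs=0.05)
        ours_ll = fit_family((time, event), "loglogistic")
        llf = LogLogisticFitter().fit(time, event)
        # lifelines: S = 1/(1+(t/alpha)^beta)  <=>  kappa=beta, theta=-beta ln alpha
        assert ours_ll.loglik == pytest.approx(llf.log_likelihood_, abs=0.05)
        alpha, beta = llf.alpha_, llf.beta_
        assert ours_ll.params[1] == pytest.approx(beta, rel=1e-2)
        assert ours_ll.params[0] == pytest.approx(-beta * math.log(alpha), rel=1e-2)

    def test_all_censored_input_is_a_fit_error(self):
        with pytest.raises(FitError):
            fit_family((np.array([1.0, 2.0, 3.0]), np.zeros(3, int)), "weibull")

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            fit_family((np.array([1.0, 2.0]), np.array([1, 1])), "cauchy")


class TestSelectBest:
    def _fit(self, family, aic, bic):
        return ParametricFit(family, (1.0,), 0.0, aic, bic, 100)

    def test_minimal_aic_wins(self):
        fits = [self._fit("exponential", 210, 1), self._fit("weibull", 205, 9),
                self._fit("gompertz", 207, 2)]
        assert select_best(fits).family == "weibull"

    def test_aic_tie_broken_by_bic_then_family_order(self):
        fits = [self._fit("lognormal", 205, 8), self._fit("weibull", 205, 7)]
        assert select_best(fits).family == "weibull"
        fits = [self._fit("loglogistic", 205, 7), self._fit("weibull", 205, 7)]
        assert select_best(fits).family == "weibull"  # fixed family order

    def test_single_candidate_returned(self):
        only = self._fit("gompertz", 999, 999)
        assert select_best([only]) is only

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_best([])
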
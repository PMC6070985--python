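"""TR mixture: density/CDF analytics, likelihood, fitting, derived measures."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from drltiming import (
    DegenerateDataError,
    InsufficientDataError,
    InvalidParameterError,
    TRParams,
    derived_proportions,
    fit_tr_model,
    mixture_cdf,
    mixture_pdf,
    neg_log_likelihood,
    response_threshold,
    sample_irts,
    weber_fraction,
)

valid_params = st.builds(
    TRParams,
    p=st.floats(0.0, 1.0),
    q=st.floats(0.0, 1.0),
    N=st.floats(0.5, 30.0),
    c=st.floats(0.05, 5.0),
    L=st.floats(0.1, 10.0),
    Lprime=st.floats(0.005, 1.0),
    delta=st.floats(0.0, 2.0),
)


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"p": 1.2},
            {"q": -0.1},
            {"N": 0.0},
            {"c": -1.0},
            {"L": 0.0},
            {"Lprime": -2.0},
            {"delta": -0.5},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs, baseline):
        base = dict(p=0.7, q=0.6, N=6.0, c=2.67, L=2.0, Lprime=0.05, delta=0.3)
        base.update(kwargs)
        with pytest.raises(InvalidParameterError):
            TRParams(**base)


class TestPdfCdf:
    def test_zero_below_shift(self, baseline):
        assert mixture_pdf(0.1, baseline) == 0.0
        assert mixture_pdf(baseline.delta - 1e-9, baseline) == 0.0
        assert mixture_cdf(baseline.delta, baseline) == 0.0

    def test_pure_exponential_density(self):
        params = TRParams(p=0.0, q=1.0, N=1, c=1, L=1.0, Lprime=0.05, delta=0.0)
        assert mixture_pdf(1.0, params) == pytest.approx(math.exp(-1), abs=1e-12)

    def test_exponential_median(self):
        params = TRParams(p=0.0, q=1.0, N=1, c=1, L=1.0, Lprime=0.05, delta=0.0)
        assert mixture_cdf(math.log(2), params) == pytest.approx(0.5, abs=1e-12)

    def test_gamma_reduction_matches_scipy(self, baseline):
        """With p=1 the mixture collapses to scipy's shifted gamma."""
        params = baseline.replace(p=1.0)
        t = np.linspace(0.0, 60.0, 301)
        expected = stats.gamma.pdf(t, a=params.N, scale=params.c, loc=params.delta)
        np.testing.assert_allclose(mixture_pdf(t, params), expected, atol=1e-12)
        expected_cdf = stats.gamma.cdf(t, a=params.N, scale=params.c, loc=params.delta)
        np.testing.assert_allclose(mixture_cdf(t, params), expected_cdf, atol=1e-12)

    def test_normalizes_for_default_params(self, baseline):
        total, _ = integrate.quad(
            lambda s: mixture_pdf(s, baseline), baseline.delta, np.inf, limit=300
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_cdf_matches_quadrature(self, baseline):
        for t in (1.0, 5.0, 15.0, 60.0):
            num, _ = integrate.quad(
                lambda s: mixture_pdf(s, baseline), baseline.delta, t, limit=300
            )
            assert mixture_cdf(t, baseline) == pytest.approx(num, abs=1e-8)

    @given(valid_params)
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_cdf_monotone_and_bounded(self, params):
        t = np.linspace(0.0, 120.0, 241)
        cdf = mixture_cdf(t, params)
        assert np.all(cdf >= 0.0) and np.all(cdf <= 1.0)
        assert np.all(np.diff(cdf) >= -1e-12)


class TestLikelihood:
    def test_reduces_to_gamma_closed_form(self, baseline, rng):
        params = baseline.replace(p=1.0)
        x = params.delta + rng.gamma(params.N, params.c, size=500)
        expected = -np.sum(
            stats.gamma.logpdf(x, a=params.N, scale=params.c, loc=params.delta)
        )
        assert neg_log_likelihood(x, params) == pytest.approx(expected, abs=1e-9)

    def test_generator_beats_rival_on_average(self, baseline, rng):
        """Gibbs inequality: the generating parameters have the lower NLL."""
        rival = baseline.replace(p=0.4, L=5.0)
        wins = 0
        for _ in range(10):
            x = sample_irts(baseline, rng, 500)
            if neg_log_likelihood(x, baseline) < neg_log_likelihood(x, rival):
                wins += 1
        assert wins >= 9

    def test_too_few_observations(self, baseline):
        with pytest.raises(InsufficientDataError):
            neg_log_likelihood([], baseline)
        with pytest.raises(InsufficientDataError):
            neg_log_likelihood([1.0], baseline)


class TestFit:
    def test_recovers_default_generator(self, baseline, rng):
        x = sample_irts(baseline, rng, 2000)
        fit = fit_tr_model(x, seed=0)
        assert fit.converged
        assert abs(fit.params.p - baseline.p) <= 0.07
        assert abs(fit.params.L - baseline.L) / baseline.L <= 0.25
        nc_true = baseline.N * baseline.c
        assert abs(fit.params.timed_mean_s - nc_true) / nc_true <= 0.10

    def test_pure_gamma_collapses_to_timed(self, baseline, rng):
        params = baseline.replace(p=1.0)
        x = params.delta + rng.gamma(params.N, params.c, size=2000)
        fit = fit_tr_model(x, seed=0)
        assert fit.params.p >= 0.9

    def test_cdf_lsq_agrees_with_mle_on_separated_mixture(self, rng):
        truth = TRParams(p=0.7, q=0.6, N=6.0, c=2.67, L=5.0, Lprime=0.02, delta=0.3)
        x = sample_irts(truth, rng, 3000)
        mle = fit_tr_model(x, mode="mle", seed=0)
        lsq = fit_tr_model(x, mode="cdf_lsq", seed=0)
        for a, b in zip(mle.params.proportions, lsq.params.proportions):
            assert abs(a - b) <= 0.1

    def test_error_shrinks_with_sample_size(self, baseline):
        """MLE consistency: median |p-hat - p| decreases as n grows."""
        med_err = {}
        for n in (200, 1000, 5000):
            errs = []
            for rep in range(5):
                x = sample_irts(baseline, np.random.default_rng(100 * n + rep), n)
                errs.append(abs(fit_tr_model(x, seed=rep).params.p - baseline.p))
            med_err[n] = np.median(errs)
        assert med_err[5000] < med_err[200]

    def test_derived_proportions_sum_to_one(self, baseline, rng):
        x = sample_irts(baseline, rng, 500)
        fit = fit_tr_model(x, seed=0)
        d = fit.derived
        assert d["prop_timed"] + d["prop_burst"] + d["prop_long"] == pytest.approx(
            1.0, abs=1e-12
        )
        assert d["theta"] > 0

    def test_degenerate_and_insufficient_data(self):
        with pytest.raises(DegenerateDataError):
            fit_tr_model([2.0] * 100)
        with pytest.raises(InsufficientDataError):
            fit_tr_model([1.0])

    def test_small_sample_warns(self, baseline, rng):
        x = sample_irts(baseline, rng, 10)
        with pytest.warns(UserWarning, match="unreliable"):
            fit_tr_model(x, seed=0)

    def test_fixed_seed_reproducible(self, baseline, rng):
        x = sample_irts(baseline, rng, 300)
        f1 = fit_tr_model(x, seed=7)
        f2 = fit_tr_model(x, seed=7)
        assert f1.params == f2.params
        assert f1.objective_value == f2.objective_value


class TestDerivedMeasures:
    @pytest.mark.parametrize(
        "N, c, theta, low",
        [(6, 2.5, 1.0, False), (3, 2, 0.4, True), (7.02, 2.5, 1.17, False)],
    )
    def test_response_threshold(self, N, c, theta, low):
        res = response_threshold(N, c)
        assert res.theta == pytest.approx(theta)
        assert res.low_accuracy is low

    def test_response_threshold_rejects_nonpositive(self):
        with pytest.raises(InvalidParameterError):
            response_threshold(-1, 2)

    @pytest.mark.parametrize(
        "p, q, expected",
        [(1.0, 0.3, (1.0, 0.0, 0.0)), (0.0, 0.0, (0.0, 0.0, 1.0))],
    )
    def test_proportions_examples(self, p, q, expected):
        assert derived_proportions(p, q) == pytest.approx(expected)

    def test_proportions_bracket_reported_sucrose_values(self):
        """p = 0.67 with burst 0.16 implies q ~ 0.485 and long ~ 0.17."""
        p, q = 0.67, 0.16 / (1 - 0.67)
        timed, burst, long_ = derived_proportions(p, q)
        assert burst == pytest.approx(0.16, abs=1e-12)
        assert long_ == pytest.approx(0.17, abs=0.01)
        assert timed + burst + long_ == pytest.approx(1.0, abs=1e-15)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(derandomize=True, max_examples=100)
    def test_proportions_always_sum_to_one(self, p, q):
        assert sum(derived_proportions(p, q)) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("N, omega", [(4, 0.5), (1, 1.0)])
    def test_weber_fraction(self, N, omega):
        assert weber_fraction(N) == pytest.approx(omega)

    def test_weber_fraction_decreasing_in_N(self):
        Ns = np.linspace(0.5, 30, 50)
        omegas = [weber_fraction(n) for n in Ns]
        assert np.all(np.diff(omegas) < 0)
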
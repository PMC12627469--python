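"""Analytic core: normal-normal integration, shrinkage form, habituation,
dynamic unpredictable prior, truncated-normal moments and sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from paincontrol.bayes_core import (
    DynamicPriorInput,
    PriorState,
    alpha_from_variances,
    dynamic_prior_mean,
    habituated_mean,
    integrate_normal,
    sample_trunc_normal,
    shrink_mean,
    trunc_normal_logpdf,
    trunc_normal_mean,
)


class TestIntegration:
    @pytest.mark.parametrize(
        "mu0,tau0,y,sigma,mu1,tau1",
        [
            (50, 10, 70, 10, 60.0, np.sqrt(50)),   # equal precision: midpoint
            (42, 3, 42, 8, 42.0, None),            # agreement case
        ],
    )
    def test_known_posteriors(self, mu0, tau0, y, sigma, mu1, tau1):
        post = integrate_normal(PriorState(mu0, tau0), y, sigma)
        assert post.mu1 == pytest.approx(mu1)
        if tau1 is not None:
            assert post.tau1 == pytest.approx(tau1)

    def test_flat_prior_limit(self):
        post = integrate_normal(PriorState(50, 1e6), 70, 10)
        assert abs(post.mu1 - 70) < 1e-3

    def test_invalid_sds_raise(self):
        with pytest.raises(ValueError):
            PriorState(50, 0.0)
        with pytest.raises(ValueError):
            integrate_normal(PriorState(50, 10), 70, -1.0)

    @given(
        mu0=st.floats(0, 100),
        tau0=st.floats(0.5, 50),
        y=st.floats(0, 100),
        sigma=st.floats(0.5, 50),
    )
    @settings(max_examples=300, derandomize=True)
    def test_shrinkage_form_matches_precision_weighting(self, mu0, tau0, y, sigma):
        """The weighted-mean and alpha-shrinkage expressions are algebraically
        identical, and the posterior SD never exceeds either component SD."""
        post = integrate_normal(PriorState(mu0, tau0), y, sigma)
        alpha = alpha_from_variances(tau0**2, sigma**2)
        assert shrink_mean(mu0, alpha, y) == pytest.approx(post.mu1, abs=1e-10)
        assert post.tau1 <= min(tau0, sigma) + 1e-12
        assert min(mu0, y) - 1e-9 <= post.mu1 <= max(mu0, y) + 1e-9


class TestAlphaAndHabituation:
    @pytest.mark.parametrize(
        "tau0_sq,sigma_sq,expected",
        [(100, 100, 0.5), (300, 100, 0.75), (0, 50, 0.0), (50, 0, 1.0)],
    )
    def test_alpha_values(self, tau0_sq, sigma_sq, expected):
        assert alpha_from_variances(tau0_sq, sigma_sq) == pytest.approx(expected)

    def test_alpha_undefined_at_origin(self):
        with pytest.raises(ValueError):
            alpha_from_variances(0.0, 0.0)

    @pytest.mark.parametrize(
        "mu0,alpha,y,expected",
        [(50, 0.0, 70, 50.0), (50, 1.0, 70, 70.0), (50, 0.74, 70, 64.8)],
    )
    def test_shrink_mean(self, mu0, alpha, y, expected):
        assert shrink_mean(mu0, alpha, y) == pytest.approx(expected)

    def test_shrink_mean_rejects_bad_alpha(self):
        with pytest.raises(ValueError):
            shrink_mean(50, 1.2, 70)

    @pytest.mark.parametrize(
        "y_i,h,t,expected",
        [(70, 0.0, 9, 70.0), (70, 1.0, 5, 65.0), (30, -0.5, 4, 32.0)],
    )
    def test_habituated_mean(self, y_i, h, t, expected):
        assert habituated_mean(y_i, h, t) == pytest.approx(expected)


class TestDynamicPrior:
    def test_trial_one_weights_are_uniform(self):
        inp = DynamicPriorInput({30: 5, 50: 5, 70: 5}, {30: 30, 50: 50, 70: 70})
        assert dynamic_prior_mean(inp) == pytest.approx(50.0)

    def test_three_high_stimuli_lower_the_prior(self):
        inp = DynamicPriorInput({30: 5, 50: 5, 70: 2}, {30: 30, 50: 50, 70: 70})
        assert dynamic_prior_mean(inp) == pytest.approx(45.0)

    def test_single_remaining_outcome(self):
        inp = DynamicPriorInput({30: 0, 50: 0, 70: 1}, {30: 30, 50: 50, 70: 70})
        assert dynamic_prior_mean(inp) == pytest.approx(70.0)

    def test_exhausted_run_raises(self):
        with pytest.raises(ValueError):
            dynamic_prior_mean(
                DynamicPriorInput({30: 0, 50: 0, 70: 0}, {30: 30, 50: 50, 70: 70})
            )

    @given(
        c1=st.integers(0, 5), c2=st.integers(0, 5), c3=st.integers(0, 5),
        m1=st.floats(0, 100), m2=st.floats(0, 100), m3=st.floats(0, 100),
    )
    @settings(max_examples=200, derandomize=True)
    def test_bounds_and_permutation_invariance(self, c1, c2, c3, m1, m2, m3):
        if c1 + c2 + c3 == 0:
            return
        val = dynamic_prior_mean(
            DynamicPriorInput({30: c1, 50: c2, 70: c3}, {30: m1, 50: m2, 70: m3})
        )
        assert min(m1, m2, m3) - 1e-9 <= val <= max(m1, m2, m3) + 1e-9
        # permuting which level carries which (count, mean) leaves the mean alone
        swapped = dynamic_prior_mean(
            DynamicPriorInput({30: c3, 50: c2, 70: c1}, {30: m3, 50: m2, 70: m1})
        )
        assert val == pytest.approx(swapped, abs=1e-9)


def _quad_trunc_mean(mu, sd):
    z = stats.norm.cdf(100, mu, sd) - stats.norm.cdf(0, mu, sd)
    val, _ = integrate.quad(lambda x: x * stats.norm.pdf(x, mu, sd) / z, 0, 100)
    return val


class TestTruncatedNormal:
    def test_midpoint_symmetry(self):
        for sd in (1.0, 10.0, 40.0):
            assert trunc_normal_mean(50, sd) == pytest.approx(50.0, abs=1e-9)

    def test_mean_matches_quadrature(self):
        for mu in (-10, 10, 30, 50, 70, 90, 120):
            for sd in (2, 8, 20, 40):
                assert trunc_normal_mean(mu, sd) == pytest.approx(
                    _quad_trunc_mean(mu, sd), abs=1e-6
                )

    def test_dispersion_biases_toward_midpoint(self):
        """Less precise ratings drift up at low and down at high intensity."""
        lows = [trunc_normal_mean(30, sd) for sd in (2, 5, 10, 20, 40)]
        highs = [trunc_normal_mean(70, sd) for sd in (2, 5, 10, 20, 40)]
        assert np.all(np.diff(lows) > 0)
        assert np.all(np.diff(highs) < 0)

    def test_degenerate_sd_limit(self):
        assert trunc_normal_mean(30, 1e-8) == pytest.approx(30.0, abs=1e-6)

    def test_logpdf_normalizes_over_scale(self):
        for mu, sd in [(50, 10), (10, 25), (110, 15)]:
            val, _ = integrate.quad(
                lambda x: np.exp(trunc_normal_logpdf(x, mu, sd)), 0, 100
            )
            assert val == pytest.approx(1.0, abs=1e-8)

    def test_logpdf_finite_inside_inf_outside(self):
        assert np.isfinite(trunc_normal_logpdf(0.0, 70, 5))
        assert np.isfinite(trunc_normal_logpdf(100.0, 30, 5))
        assert trunc_normal_logpdf(-0.5, 50, 5) == -np.inf

    def test_sampler_bounds_and_mean(self, rng):
        draws = sample_trunc_normal(50, 10, rng=rng, size=100_000)
        assert draws.min() >= 0 and draws.max() <= 100
        assert draws.mean() == pytest.approx(50.0, abs=0.1)

    def test_sampler_handles_location_outside_scale(self, rng):
        draws = sample_trunc_normal(120, 10, rng=rng, size=1000)
        assert np.all((draws >= 0) & (draws <= 100))
        assert draws.mean() == pytest.approx(
            trunc_normal_mean(120, 10), abs=0.5
        )

    def test_sampler_rejects_bad_sd(self):
        with pytest.raises(ValueError):
            sample_trunc_normal(50, 0.0)
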
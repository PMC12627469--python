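"""Model variants: predictive distributions, likelihoods, HPDI, fitting,
posterior prediction and parameter recovery."""

import numpy as np
import pytest
from scipy import integrate

from paincontrol.models import (
    ModelSpec,
    SubjectParameters,
    VARIANTS,
    fit_hierarchical,
    hpdi,
    log_likelihood,
    parameter_recovery,
    posterior_predict,
    trial_predictive_params,
)
from paincontrol.synthetic import sample_group_parameters
from paincontrol.trial_data import TrialRecord


def _params(**kw):
    base = dict(
        mu0_C={30: 30.0, 50: 50.0, 70: 70.0},
        mu0_P={30: 30.0, 50: 50.0, 70: 70.0},
        tau0_C=5.0, tau0_P=10.0, tau1=4.0, alpha=0.74, h=0.0,
    )
    base.update(kw)
    return SubjectParameters(**base)


def _trial(cond="C", level=50, t=1):
    return TrialRecord("s1", 1, 1, t, cond, level, None, None, cond == "C")


class TestTrialPredictiveParams:
    def test_controllable_trial_reads_prior_directly(self):
        spec = ModelSpec.with_profile("precision_change_dynamic", "smoke")
        mu, sd = trial_predictive_params(spec, _params(), _trial("C", 50))
        assert (mu, sd) == (pytest.approx(50.0), pytest.approx(5.0))
        mu, sd = trial_predictive_params(spec, _params(), _trial("P", 50))
        assert (mu, sd) == (pytest.approx(50.0), pytest.approx(10.0))

    def test_unpredictable_first_trial_uses_uniform_weights(self):
        spec = ModelSpec.with_profile("precision_change_dynamic", "smoke")
        mu, sd = trial_predictive_params(spec, _params(), _trial("U", 70))
        # prior mean 50 (weights 1/3), shrinkage toward the input
        assert mu == pytest.approx(50 + 0.74 * 20)
        assert sd == pytest.approx(4.0)

    def test_dynamic_prior_tracks_history(self):
        spec = ModelSpec.with_profile("precision_change_dynamic", "smoke")
        mu, _ = trial_predictive_params(
            spec, _params(), _trial("U", 70, t=4), history=[70, 70, 70]
        )
        # remaining (5,5,2)/12 -> prior mean 45
        assert mu == pytest.approx(45 + 0.74 * 25)

    def test_null_model_predicts_habituated_target(self):
        spec = ModelSpec.with_profile("null_hab", "smoke")
        p = SubjectParameters(h=1.0, noise=6.0)
        mu, sd = trial_predictive_params(spec, p, _trial("U", 70, t=5))
        assert (mu, sd) == (pytest.approx(65.0), pytest.approx(6.0))

    def test_habituation_applies_to_cue_conditions(self):
        spec = ModelSpec.with_profile("precision_change_dynamic", "smoke")
        mu, _ = trial_predictive_params(spec, _params(h=0.5), _trial("C", 70, t=10))
        assert mu == pytest.approx(65.0)

    def test_mean_shift_separates_condition_means(self):
        spec = ModelSpec.with_profile("mean_shift_dynamic", "smoke")
        p = _params(
            mu0_C={30: 25.0, 50: 48.0, 70: 72.0},
            mu0_P={30: 33.0, 50: 52.0, 70: 68.0},
            tau0_C=7.0, tau0_P=7.0,
        )
        muC, sdC = trial_predictive_params(spec, p, _trial("C", 70))
        muP, sdP = trial_predictive_params(spec, p, _trial("P", 70))
        assert (muC, muP) == (pytest.approx(72.0), pytest.approx(68.0))
        assert sdC == sdP == pytest.approx(7.0)

    def test_multi_alpha_shrinks_every_condition(self):
        spec = ModelSpec.with_profile("two_alpha", "smoke")
        p = SubjectParameters(
            mu0_C={30: 30.0, 50: 50.0, 70: 70.0},
            tau1=4.0, alpha_U=0.6, alpha_CP=0.9, h=1.0,
        )
        # C trial: prior 70, habituated input 69, alpha_CP
        mu, sd = trial_predictive_params(spec, p, _trial("C", 70, t=1))
        assert mu == pytest.approx(70 + 0.9 * (69 - 70))
        assert sd == pytest.approx(4.0)

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_parameter_vector_round_trip(self, variant):
        p = sample_group_parameters(variant, 1, seed=11)["sub001"]
        vec = p.to_vector(variant)
        back = SubjectParameters.from_vector(vec, variant).to_vector(variant)
        np.testing.assert_allclose(vec, back)


class TestLogLikelihood:
    def test_identical_trials_identical_densities(self, small_cohort):
        data, params, cfg = small_cohort
        spec = ModelSpec.with_profile(cfg.model, "smoke")
        ll = log_likelihood(data, params, spec)
        assert np.all(np.isfinite(ll))
        # two C trials at the same level and trial position in different
        # sessions share a predictive distribution only if ratings match;
        # instead check a duplicated dataset reproduces its densities
        ll2 = log_likelihood(data, params, spec)
        np.testing.assert_array_equal(ll, ll2)

    def test_near_uniform_limit(self):
        spec = ModelSpec.with_profile("null_hab", "smoke")
        p = SubjectParameters(h=0.0, noise=1e5)
        mu, sd = trial_predictive_params(spec, p, _trial("U", 50))
        from paincontrol.bayes_core import trunc_normal_logpdf
        val = trunc_normal_logpdf(23.0, mu, sd)
        assert val == pytest.approx(np.log(1 / 100), abs=1e-3)

    def test_density_normalizes(self):
        from paincontrol.bayes_core import trunc_normal_logpdf
        total, _ = integrate.quad(
            lambda x: np.exp(trunc_normal_logpdf(x, 63.5, 4.0)), 0, 100
        )
        assert total == pytest.approx(1.0, abs=1e-8)


def _brute_force_hpdi(draws, mass):
    x = np.sort(np.asarray(draws))
    n = len(x)
    k = min(max(int(np.ceil(mass * n)), 2), n)
    best = None
    for i in range(n - k + 1):
        width = x[i + k - 1] - x[i]
        if best is None or width < best[0] - 1e-15:
            best = (width, x[i], x[i + k - 1])
    return best[1], best[2]


class TestHpdi:
    def test_integer_ramp(self):
        lo, hi = hpdi(np.arange(1, 101), 0.95)
        assert (lo, hi) == (1, 95)

    def test_mass_near_one_returns_range(self):
        x = np.array([3.0, 1.0, 9.0, 4.0])
        assert hpdi(x, 0.999) == (1.0, 9.0)

    def test_symmetric_sample_close_to_central_interval(self, rng):
        x = rng.normal(0, 1, 20_000)
        lo, hi = hpdi(x, 0.95)
        q = np.quantile(x, [0.025, 0.975])
        assert lo == pytest.approx(q[0], abs=0.1)
        assert hi == pytest.approx(q[1], abs=0.1)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 400))
            mass = float(rng.uniform(0.5, 0.99))
            x = rng.choice(
                [rng.normal(0, 1, n), rng.exponential(1, n), rng.uniform(0, 1, n)][
                    int(rng.integers(3))
                ],
                size=n,
                replace=False,
            )
            assert hpdi(x, mass) == _brute_force_hpdi(x, mass)

    def test_invalid_mass_rejected(self):
        with pytest.raises(ValueError):
            hpdi([1.0, 2.0], 1.5)


class TestFitting:
    def test_fit_is_deterministic_under_seed(self, null_cohort):
        data, _, _ = null_cohort
        spec = ModelSpec(variant="null_hab", chains=2, iterations=120, warmup=60)
        f1 = fit_hierarchical(data, spec, seed=5)
        f2 = fit_hierarchical(data, spec, seed=5)
        for name in f1.draws:
            np.testing.assert_array_equal(f1.draws[name], f2.draws[name])

    def test_null_fit_recovers_noise_and_drift(self, null_cohort):
        data, params, _ = null_cohort
        spec = ModelSpec.with_profile("null_hab", "smoke")
        fit = fit_hierarchical(data, spec, seed=6)
        noise_hat = np.asarray(fit.posterior_mean("noise"))
        assert np.all(np.abs(noise_hat - 6.0) < 1.2)
        h_true = np.array([p.h for p in params.values()])
        h_hat = np.asarray(fit.posterior_mean("h"))
        assert np.all(np.abs(h_hat - h_true) < 0.35)

    def test_loglik_matrix_aligns_with_observed_trials(self, null_cohort):
        data, _, _ = null_cohort
        spec = ModelSpec(variant="null_hab", chains=2, iterations=300, warmup=100)
        fit = fit_hierarchical(data, spec, seed=7)
        n_obs = data.df["rating"].notna().sum()
        assert fit.loglik.shape[1] == n_obs == len(fit.trial_meta)
        assert np.all(np.isfinite(fit.loglik))

    def test_posterior_predictions_stay_on_scale(self, null_cohort):
        data, _, _ = null_cohort
        spec = ModelSpec(variant="null_hab", chains=2, iterations=300, warmup=100)
        fit = fit_hierarchical(data, spec, seed=8)
        meta = posterior_predict(fit, data, seed=9, n_draws=50)
        draws = meta.attrs["draws"]
        assert np.all((draws >= 0) & (draws <= 100))
        # predictions track the data at cell level
        resid = meta["pred_mean"] - meta["rating"]
        assert abs(resid.mean()) < 2.0


class TestRecovery:
    def test_null_model_noise_recovery_is_strong(self):
        spec = ModelSpec.with_profile("null_hab", "smoke")
        rep = parameter_recovery(spec, n_subjects=8, seed=21, mcmc_profile="smoke")
        assert rep.correlations["noise"] > 0.9
        assert rep.correlations["h"] > 0.9

    @pytest.mark.parametrize("variant", ["precision_change_dynamic"])
    def test_integration_model_parameters_recoverable(self, variant):
        spec = ModelSpec.with_profile(variant, "recovery")
        rep = parameter_recovery(
            spec, n_subjects=10, seed=22, mcmc_profile="recovery"
        )
        assert not rep.flagged, rep.correlations
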
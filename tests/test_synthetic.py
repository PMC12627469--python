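"""Schedule generation, matching, group-parameter draws, full simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paincontrol.synthetic import (
    GeneratorConfig,
    ScheduleConfig,
    generate_controllable_sequence,
    generate_matched_sequences,
    sample_group_parameters,
    simulate_dataset,
    simulate_power,
    _sequence_frequencies,
)
from paincontrol.trial_data import LEVELS, PER_LEVEL, within_subject_sd_table


class TestControllableSequences:
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_balanced_multiset_for_any_seed(self, seed):
        seq = generate_controllable_sequence(ScheduleConfig(seed=seed))
        assert sorted(seq) == sorted(LEVELS * PER_LEVEL)

    def test_zero_bias_is_uniform_at_first_trial(self):
        rng = np.random.default_rng(0)
        cfg = ScheduleConfig(choice_bias=0.0)
        firsts = [
            generate_controllable_sequence(cfg, rng=rng)[0] for _ in range(6000)
        ]
        freqs = np.array([firsts.count(l) / len(firsts) for l in LEVELS])
        np.testing.assert_allclose(freqs, 1 / 3, atol=0.03)

    def test_extreme_bias_front_loads_high_level(self):
        rng = np.random.default_rng(1)
        cfg = ScheduleConfig(choice_bias=200.0)
        for _ in range(50):
            seq = generate_controllable_sequence(cfg, rng=rng)
            assert seq[:5] == [70] * 5

    def test_early_high_late_low_preference(self):
        rng = np.random.default_rng(2)
        cfg = ScheduleConfig()
        freq = _sequence_frequencies(
            [generate_controllable_sequence(cfg, rng=rng) for _ in range(3000)]
        )
        t = np.arange(1, 16)
        assert np.polyfit(t, freq[:, LEVELS.index(70)], 1)[0] < 0
        assert np.polyfit(t, freq[:, LEVELS.index(30)], 1)[0] > 0
        medium = freq[:, LEVELS.index(50)]
        assert medium[5:10].mean() > medium[:3].mean()


class TestMatchedSequences:
    def test_yoked_returns_donor_verbatim(self):
        donor = [70, 70, 70, 70, 70, 50, 50, 50, 50, 50, 30, 30, 30, 30, 30]
        out = generate_matched_sequences(donor, "yoked")
        assert out["P"] == donor and out["U"] == donor

    def test_probability_matched_respects_cap(self):
        freq = np.full((15, 3), 1 / 3)
        for seed in range(20):
            out = generate_matched_sequences(freq, "probability_matched", seed=seed)
            for seq in out.values():
                assert sorted(seq) == sorted(LEVELS * PER_LEVEL)

    def test_front_loaded_mass_yields_earlier_high_positions(self):
        freq = np.zeros((15, 3))
        freq[:7] = [0.1, 0.2, 0.7]     # high mass early
        freq[7:] = [0.55, 0.35, 0.1]   # low mass late
        rng = np.random.default_rng(5)
        pos70, pos30 = [], []
        for _ in range(1000):
            seq = generate_matched_sequences(
                freq, "probability_matched", rng=rng
            )["U"]
            arr = np.array(seq)
            pos70.append(np.flatnonzero(arr == 70).mean())
            pos30.append(np.flatnonzero(arr == 30).mean())
        assert np.mean(pos70) < np.mean(pos30)

    def test_invalid_frequencies_raise(self):
        bad = np.full((15, 3), 0.5)
        with pytest.raises(ValueError, match="sum to 1"):
            generate_matched_sequences(bad, "probability_matched")


class TestGroupParameters:
    def test_alpha_draws_respect_unit_interval(self):
        params = sample_group_parameters("precision_change_dynamic", 500, seed=1)
        alphas = np.array([p.alpha for p in params.values()])
        assert np.all((alphas >= 0) & (alphas <= 1))

    def test_sd_type_median_matches_lognormal_prior(self):
        params = sample_group_parameters("precision_change_dynamic", 4000, seed=2)
        tau0 = np.array([p.tau0_C for p in params.values()])
        assert np.median(tau0) == pytest.approx(np.exp(1.5), rel=0.05)

    def test_fixed_group_values_make_identical_subjects(self):
        params = sample_group_parameters(
            "precision_change_dynamic",
            5,
            seed=3,
            group_params={
                "alpha": 0.74, "tau0_C": 5.0, "tau0_P": 10.0,
                "tau1": 4.0, "h": 0.1, "sigma_mu0": 0.0,
            },
        )
        vecs = [p.to_vector("precision_change_dynamic") for p in params.values()]
        for v in vecs[1:]:
            np.testing.assert_allclose(v, vecs[0])

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="unknown model variant"):
            sample_group_parameters("no_such_model", 2, seed=0)


class TestSimulateDataset:
    def test_same_seed_reproduces_dataset(self):
        cfg = GeneratorConfig(model="mean_shift_dynamic", n_subjects=2, seed=9)
        d1, p1 = simulate_dataset(cfg)
        d2, p2 = simulate_dataset(cfg)
        assert d1 == d2
        for s in p1:
            np.testing.assert_allclose(
                p1[s].to_vector(cfg.model), p2[s].to_vector(cfg.model)
            )

    def test_ratings_stay_on_scale(self, small_cohort):
        data, _, _ = small_cohort
        r = data.df["rating"]
        assert r.between(0, 100).all()

    def test_every_run_is_balanced(self, small_cohort):
        data, _, _ = small_cohort
        counts = data.df.groupby(["subject_id", "run"])["intensity_level"].value_counts()
        assert (counts == PER_LEVEL).all()

    def test_noise_free_null_model_reproduces_targets(self):
        cfg = GeneratorConfig(
            model="null_hab", n_subjects=1, seed=4,
            group_params={"noise": 1e-6, "h": 0.0},
        )
        data, _ = simulate_dataset(cfg)
        np.testing.assert_allclose(
            data.df["rating"], data.df["intensity_level"], atol=1e-4
        )

    def test_precision_change_moves_condition_sds(self):
        cfg = GeneratorConfig(
            model="precision_change_dynamic", n_subjects=6, seed=5,
            group_params={"tau0_C": 3.0, "tau0_P": 9.0, "tau1": 5.0,
                          "alpha": 0.74, "h": 0.0},
        )
        data, _ = simulate_dataset(cfg)
        sds = within_subject_sd_table(data).groupby("condition")["sd"].mean()
        assert sds["C"] < sds["P"]

    def test_timeouts_become_missing(self):
        cfg = GeneratorConfig(
            model="null_hab", n_subjects=2, seed=6, timeout_rate=0.2
        )
        data, _ = simulate_dataset(cfg)
        frac = data.df["rating"].isna().mean()
        assert 0.05 < frac < 0.4

    def test_generator_and_likelihood_share_distribution(self, rng):
        """Ratings simulated for one predictive cell match the model's
        truncated-normal density (moment check on the shared code path)."""
        from paincontrol.bayes_core import trunc_normal_mean
        cfg = GeneratorConfig(
            model="precision_change_dynamic", n_subjects=40, seed=8,
            group_params={"alpha": 0.74, "tau0_C": 5.0, "tau0_P": 10.0,
                          "tau1": 4.48, "h": 0.0, "sigma_mu0": 0.0},
        )
        data, params = simulate_dataset(cfg)
        df = data.df
        cell = df[(df.condition == "C") & (df.intensity_level == 70)]["rating"]
        assert cell.mean() == pytest.approx(trunc_normal_mean(70, 5.0), abs=0.5)
        assert cell.std(ddof=1) == pytest.approx(5.0, rel=0.15)


class TestPower:
    def test_single_rep_power_is_binary(self):
        tab = simulate_power([4], effect=0.5, reps=1, seed=1, mcmc=(2, 500, 200))
        assert tab["power"].iloc[0] in (0.0, 1.0)

    def test_power_rises_with_sample_size_for_real_effect(self):
        tab = simulate_power(
            [3, 12], effect=0.4, reps=6, seed=2, mcmc=(2, 500, 200)
        )
        assert tab["power"].iloc[1] >= tab["power"].iloc[0]
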
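"""Descriptive Bayesian regressions: rating LMM, SD LMM, choice models,
within-subject SEM."""

import numpy as np
import pandas as pd
import pytest

from paincontrol.descriptive import (
    LmmSpec,
    fit_choice_freq,
    fit_rating_lmm,
    fit_sd_lmm,
    within_subject_sem,
)
from paincontrol.synthetic import (
    GeneratorConfig,
    _simulate_lmm_cohort,
    simulate_dataset,
)
from paincontrol.trial_data import choice_percentages, within_subject_sd_table

_FAST = dict(chains=2, iterations=900, warmup=300)


class TestRatingLmm:
    def test_positive_interaction_recovered(self):
        rng = np.random.default_rng(10)
        data = _simulate_lmm_cohort(15, 0.4, rng)
        res = fit_rating_lmm(data, LmmSpec(baseline="U"), seed=1, **_FAST)
        draws = res.attrs["result"].coefficient_draws("C:intensity")
        assert (draws > 0).mean() > 0.95

    def test_null_interaction_hpdi_covers_zero(self):
        rng = np.random.default_rng(11)
        data = _simulate_lmm_cohort(12, 0.0, rng)
        res = fit_rating_lmm(data, LmmSpec(baseline="U"), seed=2, **_FAST)
        row = res[res["term"] == "C:intensity"].iloc[0]
        assert row["hpdi_lo"] < 0 < row["hpdi_hi"]

    def test_duplicating_rows_narrows_intervals(self):
        rng = np.random.default_rng(12)
        data = _simulate_lmm_cohort(8, 0.3, rng)
        res1 = fit_rating_lmm(data, LmmSpec(baseline="U"), seed=3, **_FAST)
        from paincontrol.trial_data import Dataset
        doubled = Dataset(
            df=pd.concat([data.df, data.df], ignore_index=True)
        )
        res2 = fit_rating_lmm(doubled, LmmSpec(baseline="U"), seed=3, **_FAST)
        w1 = (res1["hpdi_hi"] - res1["hpdi_lo"])[res1["term"] == "intensity"].iloc[0]
        w2 = (res2["hpdi_hi"] - res2["hpdi_lo"])[res2["term"] == "intensity"].iloc[0]
        assert w2 < w1
        m1 = res1[res1["term"] == "intensity"]["mean"].iloc[0]
        m2 = res2[res2["term"] == "intensity"]["mean"].iloc[0]
        assert m2 == pytest.approx(m1, abs=0.05)

    def test_baseline_switch_preserves_fitted_cell_means(self):
        """The two baseline parameterizations describe the same mean
        structure, so the implied condition-by-intensity cell means agree
        up to MCMC error plus the (weak) prior applied to the re-labelled
        dummies."""
        rng = np.random.default_rng(13)
        data = _simulate_lmm_cohort(10, 0.3, rng)

        def cell_means(res, baseline):
            m = dict(zip(res["term"], res["mean"]))
            out = {}
            for cond in ("C", "P", "U"):
                for i in (30, 50, 70):
                    val = m["intercept"] + m["intensity"] * i
                    if cond != baseline:
                        val += m[cond] + m[f"{cond}:intensity"] * i
                    out[(cond, i)] = val + m["trial"] * 8 + m["session"] * 1.5
            return out

        res_u = fit_rating_lmm(data, LmmSpec(baseline="U"), seed=4, **_FAST)
        res_c = fit_rating_lmm(data, LmmSpec(baseline="C"), seed=5, **_FAST)
        mu_u = cell_means(res_u, "U")
        mu_c = cell_means(res_c, "C")
        for cell in mu_u:
            assert mu_u[cell] == pytest.approx(mu_c[cell], abs=2.0)


class TestSdLmm:
    @pytest.fixture(scope="class")
    def sd_cohort(self):
        cfg = GeneratorConfig(
            model="precision_change_dynamic", n_subjects=10, seed=14,
            group_params={"tau0_C": 4.0, "tau0_P": 9.0, "tau1": 12.0,
                          "alpha": 0.74, "h": 0.0},
        )
        data, _ = simulate_dataset(cfg)
        return within_subject_sd_table(data)

    def test_condition_ordering_recovered(self, sd_cohort):
        res = fit_sd_lmm(
            sd_cohort, LmmSpec(outcome="sd", baseline="C"), seed=6, **_FAST
        )
        m = dict(zip(res["term"], res["mean"]))
        lo = dict(zip(res["term"], res["hpdi_lo"]))
        assert lo["P"] > 0       # tau0_P > tau0_C by construction
        assert lo["U"] > 0       # tau1 > tau0_C by construction

    def test_permuted_labels_destroy_the_effect(self, sd_cohort, rng):
        shuffled = sd_cohort.copy()
        shuffled["condition"] = rng.permutation(shuffled["condition"].to_numpy())
        res = fit_sd_lmm(
            shuffled, LmmSpec(outcome="sd", baseline="C"), seed=7, **_FAST
        )
        row = res[res["term"] == "P"].iloc[0]
        assert row["hpdi_lo"] < 0 < row["hpdi_hi"]


class TestChoiceFreq:
    def _table(self, percents):
        rows = []
        for t in range(1, 16):
            for lvl, p in zip((30, 50, 70), percents(t)):
                rows.append({"trial": t, "intensity_level": lvl, "percent": p})
        return pd.DataFrame(rows)

    def test_constant_percentages_give_flat_slope(self):
        tab = self._table(lambda t: (33.3, 33.4, 33.3))
        res = fit_choice_freq(tab, 70, degree=1, seed=1)
        row = res.summary[res.summary["term"] == "slope"].iloc[0]
        assert row["mean"] == pytest.approx(0.0, abs=1e-4)
        assert row["hpdi_lo"] <= 0 <= row["hpdi_hi"]

    def test_generator_slope_signs(self, small_cohort):
        data, _, _ = small_cohort
        # pool many cohorts' choices for stable group percentages
        from paincontrol.synthetic import simulate_dataset as sim
        cfg = GeneratorConfig(model="null_hab", n_subjects=40, seed=15)
        big, _ = sim(cfg)
        tab = choice_percentages(big)
        high = fit_choice_freq(tab, 70, degree=1, seed=2)
        low = fit_choice_freq(tab, 30, degree=1, seed=3)
        assert high.summary.set_index("term").loc["slope", "mean"] < 0
        assert low.summary.set_index("term").loc["slope", "mean"] > 0

    def test_inverted_u_prefers_quadratic(self):
        cfg = GeneratorConfig(model="null_hab", n_subjects=40, seed=16)
        data, _ = simulate_dataset(cfg)
        tab = choice_percentages(data)
        lin = fit_choice_freq(tab, 50, degree=1, seed=4)
        quad = fit_choice_freq(tab, 50, degree=2, seed=4)
        assert quad.elpd.elpd_total > lin.elpd.elpd_total
        peak = quad.summary.set_index("term")
        assert peak.loc["quadratic", "mean"] < 0


class TestWithinSubjectSem:
    def test_identical_profiles_have_zero_sem(self):
        cells = pd.DataFrame([[1.0, 5.0, 9.0]] * 6, columns=list("abc"))
        assert np.allclose(within_subject_sem(cells), 0.0)

    def test_pure_offsets_removed_but_naive_sem_positive(self, rng):
        profile = np.array([10.0, 20.0, 30.0])
        offsets = rng.normal(0, 8, size=12)
        cells = pd.DataFrame(
            profile[None, :] + offsets[:, None], columns=list("abc")
        )
        corrected = within_subject_sem(cells)
        naive = cells.std(ddof=1) / np.sqrt(len(cells))
        assert np.allclose(corrected, 0.0, atol=1e-12)
        assert (naive > 0.5).all()

    def test_single_cell_equals_naive_sem(self, rng):
        col = rng.normal(50, 5, size=9)
        cells = pd.DataFrame({"only": col})
        sem = within_subject_sem(cells)
        assert sem["only"] == pytest.approx(col.std(ddof=1) / 3.0)

    def test_missing_cells_drop_subject_with_warning(self, rng):
        cells = pd.DataFrame(rng.normal(50, 5, size=(5, 3)), columns=list("abc"))
        cells.iloc[0, 1] = np.nan
        with pytest.warns(UserWarning, match="excluded"):
            sem = within_subject_sem(cells)
        assert len(sem) == 3
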
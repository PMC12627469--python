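# paincontrol

Does being *in control* of pain change how it feels, beyond merely knowing
what is coming? This package implements the behavioral analysis chain for a
three-condition heat-pain rating task designed to answer that question:
participants rate calibrated thermal stimuli (VAS targets 30/50/70 on a
0–100 scale) whose intensity is either self-chosen (**C**, controllable),
computer-chosen but announced (**P**, predictable), or unannounced
(**U**, unpredictable).

The core idea is Bayesian cue integration. A rating is a draw from a
[0,100]-truncated normal around the integrated percept

μ₁ = μ₀ + α·(y − μ₀),  α = τ₀² / (σ² + τ₀²) ∈ [0, 1],

where μ₀, τ₀ describe the expectation (prior), y the habituation-corrected
input (y_t = y_i − h·t), and α the likelihood weight. Under an imprecise
central prior — the unpredictable condition — truncation pulls low-intensity
ratings up and high-intensity ratings down (the central-tendency bias). Two
competing accounts of the *control* effect are formalized as model variants
and compared by leave-one-out cross-validation:

- **mean-shift**: control shifts the prior means (separate μ₀ per condition,
  shared τ₀);
- **precision-change**: control sharpens the prior (shared μ₀, separate
  τ₀_C vs τ₀_P).

Each comes with a fixed or dynamic unpredictable prior (the dynamic prior
re-weights the per-level means by the remaining stimulus counts of the
run), and both are tested against two null models and multi-α variants.
The package provides:

- `trial_data` — long-format trial tables (TSV), validation, within-subject
  SD / choice / RT summaries;
- `synthetic` — a fully seeded cohort generator (choice-driven schedules,
  matched sequences, ratings drawn through the models' own predictive
  distributions) plus a simulation-based power analysis;
- `bayes_core` — the closed-form integration math and truncated-normal
  utilities;
- `models` — the eight variants, hierarchical MCMC fitting
  (slice-within-Gibbs, seeded and deterministic), HPDI, posterior
  prediction, parameter recovery;
- `comparison` — PSIS-LOO with Pareto-k̂ diagnostics, the robust
  mixture-estimator LOO, an exact refit-LOO oracle, paired ELPD comparison;
- `descriptive` — the Bayesian mixed models on ratings and rating SDs,
  choice-frequency regressions, within-subject-corrected SEMs;
- `pipeline` — seeded end-to-end orchestration with manifests.

See `docs/methods.md` for the full model description and numerical choices.

## Worked example

The numbered scripts under `analysis/` run the whole chain on a synthetic
cohort (12 subjects by default, ~minutes each):

```sh
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_descriptives.py
python analysis/03_choice_models.py
python analysis/04_rating_and_sd_lmms.py
python analysis/05_fit_and_compare_models.py
python analysis/06_parameter_recovery.py
python analysis/07_power_analysis.py
```

`01` simulates the cohort from the dynamic precision-change observer
(τ₀_C = 5, τ₀_P = 10, α = 0.74) and `02` prints its descriptive layer:

```
mean rating per condition x intensity:
intensity_level    30    50    70
condition
C                30.7  49.6  70.2
P                30.4  49.3  69.1
U                34.7  49.8  65.9

mean within-subject SD per condition (expect C < P):
C    5.08
P    9.57
U    4.88
```

Unpredictable ratings are biased toward the scale center (34.7 at the low
level, 65.9 at the high level), and control tightens ratings relative to
mere predictability (SD 5.1 vs 9.6) — the two behavioral signatures the
models are built to explain. `03` recovers the choice pattern that shapes
the schedules (high intensities chosen early: slope −2.84 %/trial, low
late: +2.52, inverted U for the medium level, quadratic model preferred by
ELPD). `04` quantifies the biases as interaction coefficients
(C×intensity vs U: 0.19 [0.12, 0.26]; P vs C rating-SD difference:
4.4 [3.7, 5.2]), and `05` fits and compares the integration models — on
this cohort the precision-change model beats the mean-shift model by an
ELPD difference of 71.9 (SE 12.6), with both integration models far ahead
of the null models, and the robust mixture estimator replacing PSIS on the
fits whose Pareto diagnostic flags trials. `06` confirms that every
precision-change parameter is recoverable (r ≥ 0.83 at 12 subjects) and
`07` puts the power to detect the interaction at 0.95 for 10 subjects at
this effect size.

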
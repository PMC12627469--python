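# Methods

## The task and the data model

The package analyses a three-condition heat-pain rating task. On every
trial a calibrated thermal stimulus targeting VAS 30, 50 or 70 (on a 0–100
visual analogue scale anchored at pain threshold and tolerance) is applied,
and the participant rates its painfulness. In the **controllable (C)**
condition the participant chooses the intensity, under the constraint that
each level must be chosen exactly 5 times in a 15-trial run; in the
**predictable (P)** condition the computer chooses but announces the
intensity; in the **unpredictable (U)** condition the intensity is neither
chosen nor announced. Each condition is run twice: 6 runs, 90 trials per
subject. Data live in a long-format TSV (one row per trial) defined in
`trial_data`.

## The observer model

Pain ratings are modelled as draws from a **[0, 100]-truncated normal**
whose location and spread come from Bayesian integration of an expectation
(prior, mean μ₀, SD τ₀) with the nociceptive input (likelihood, mean y,
SD σ):

- posterior mean μ₁ = (μ₀/τ₀² + y/σ²) / (1/τ₀² + 1/σ²), equivalently
  μ₁ = μ₀ + α·(y − μ₀) with **α = τ₀²/(σ² + τ₀²) ∈ [0, 1]**;
- posterior precision 1/τ₁² = 1/τ₀² + 1/σ².

σ is never a free parameter: the separate variance contributions are not
identifiable from ratings, so the models estimate α and τ₁ directly. The
input mean is habituation-corrected, y_t = y_i − h·t with t the 1-based
trial index within a run (h > 0: habituation; h < 0: sensitization). The
habituation term applies in all conditions; restricting it to U trials
would leave it nearly unidentified.

In C and P trials the cue makes the expectation coincide with the input,
so there is no prediction error and ratings are modelled as draws directly
from the (habituated) prior — the prior SD is the rating SD. In U trials
the expectation is central: either **fixed** (a subject-constant prior mean
with a hyperprior centred at VAS 50) or **dynamic** — the weighted average
of the per-level prior means with weights equal to the remaining number of
occurrences of each level divided by the remaining trials of the run
(all weights 1/3 on trial 1; after three consecutive high stimuli the
expectation drops). Because participants cannot see the remaining counts
in U runs, the dynamic prior assumes implicit tracking of the applied
intensities; the model family leaves that assumption open and tests it by
comparing fixed against dynamic variants.

Truncation is what makes precision changes visible in means: with hard
bounds, a wider predictive distribution pushes the expected rating toward
the middle of the scale — up at low intensities, down at high ones (the
central-tendency/unpredictability bias). Ratings at exactly 0 or 100 are
treated as truncated observations (the density at the bound), not censored
point masses.

### The eight variants

| variant | C/P means | C/P spread | U trials |
|---|---|---|---|
| `null_hab` | input y_t | shared noise | input y_t, noise |
| `null_means` | free per condition | shared τ₀ | input y_t, noise |
| `mean_shift_fixed/dynamic` | free per condition | shared τ₀ | α-integration, τ₁ |
| `precision_change_fixed/dynamic` | shared | τ₀_C vs τ₀_P free | α-integration, τ₁ |
| `two_alpha` | shrinkage, α_CP | τ₁ | shrinkage, α_U, τ₁ |
| `three_alpha` | shrinkage, α_C / α_P | τ₁ | shrinkage, α_U, τ₁ |

The two dynamic multi-α variants use the dynamic U prior (the
better-fitting mechanism); in `mean_shift_dynamic` the dynamic U prior
weights the per-level average of the C and P prior means, since the
dynamic construction references a single prior mean per level.

### Hierarchy and priors

Subject-level prior means are partially pooled: μ₀(level) ~
N(m_level, σ_μ0) with group means m_level under weak hyperpriors centred
on the VAS targets (N(30, 100), N(50, 100), N(70, 100); the second
argument is a standard deviation throughout) and log σ_μ0 ~ N(1.5, 0.5).
All other subject parameters are unpooled with the group-level priors
applied per subject: log τ₀, log τ₁, log noise ~ N(1.5, 0.5); α ~
N(0.5, 0.3) truncated to [0, 1] (truncation rather than a logit transform —
simpler density bookkeeping); h ~ N(0, 1). The unpooled choice for α/h/τ
reflects that the study reports subject-level spreads for these parameters
rather than pooled group posteriors.

## Sampling

Posteriors are sampled by **slice-sampling-within-Gibbs**: univariate
slice updates (stepping-out + shrinkage) for every subject-level scalar,
conjugate normal draws for the group-level means, and a slice update for
log σ_μ0. Because the trial mean couples h with the prior means
(μ − h·t), each subject sweep adds one joint slice move along the
direction (δh = 1, δμ₀ = t̄) that leaves mid-run predictions invariant;
this removes the dominant posterior correlation and roughly triples the
effective sample size of h and μ₀. The sampler is gradient-free, exact
(no step-size tuning or acceptance rates), and fully deterministic given
the seed; chains are seeded from a master seed.

MCMC profiles: `paper` (4 chains × 4000 iterations, 1000 warmup),
`recovery` (4 × 1000, 500 warmup) used for recovery studies and the
scaled-down analyses in this repository, and `smoke` (2 × 500, 250) for
fast checks. Convergence is gated at split-R̂ < 1.01 for every stored
parameter (computed with ArviZ, together with bulk ESS); a fit that fails
the gate is returned flagged, never silently.

Initialization is data-driven (cell means/SDs per subject, jittered per
chain), which keeps the short recovery profile well inside its warmup.

## Model comparison

Out-of-sample fit is the expected log pointwise predictive density (ELPD)
under leave-one-out cross-validation:

- `psis_loo` smooths the importance ratios of each held-out trial with a
  generalized-Pareto tail fit and reports the tail-shape diagnostic k̂ per
  trial; trials with k̂ > 0.7 are flagged as unreliable.
- `robust_loo` implements the mixture estimator: the sampler targets the
  posterior tilted by s(θ) = Σᵢ 1/p(yᵢ|θ) (an equal-weight mixture of all
  leave-one-out posteriors); under that proposal each 1/p(yᵢ|y₋ᵢ) is a
  self-normalized average of terms bounded by the normalizer, so every
  pointwise value is finite with no diagnostic gate. The tilt depends only
  on subject-level parameters, so the conjugate group updates carry over.
- `exact_refit_loo` refits the model once per held-out trial (rating
  masked; the applied stimulus still counts for the dynamic-prior weights)
  and is the ground-truth oracle for small data (default cap 200 trials).

Paired comparisons report the ELPD difference with the standard error of
the pointwise differences; |ΔELPD| < 4 is treated as small, and a
difference is called decisive when it exceeds twice its SE.

## Descriptive regressions

Trial ratings are analysed with a Bayesian linear mixed model: fixed
effects for intensity (VAS units, anchored at the pain threshold VAS 0),
condition dummies, condition × intensity interactions, trial and session
number; a random intercept per subject. Priors: intercept N(0, 50),
coefficients Cauchy(0, 2.5), flat positive prior on the residual SD,
half-Cauchy(0, 25) on the random-intercept SD (the study names no prior
for the latter; a weakly-informative default is used). The model is fitted
once per baseline condition so every pairwise interaction is read off
directly. Sampling is blocked Gibbs: a joint multivariate-normal draw for
all fixed effects (Cauchy priors via their normal scale-mixture
representation), conjugate draws for intercepts and variances — the
blocking is what keeps the heavily collinear design (raw-scale intensity,
dummies, interactions) mixing quickly.

Within-subject rating SDs (subject × condition × intensity cells, runs of
a condition pooled, nominally 10 ratings per cell, n−1 denominator) are
modelled the same way but with intensity as a 3-level factor, because the
SDs peak at the medium level; two baseline parameterizations (U + low,
C + medium) give all pairwise contrasts.

Choice behavior: the group-level percentage of self-chosen intensities per
trial position (one observation per position, summing to 100 across
levels) is regressed on trial position with flat priors — the posterior is
conjugate and sampled exactly; a quadratic term captures the medium
level's inverted U, and PSIS-LOO ELPD compares the two degrees.

Condition plots use the SEM corrected for within-subject measurement:
subject-mean centering plus the grand mean, with the √(M/(M−1)) bias
correction for M cells; a single-cell input falls back to the naive SEM.

Interval summaries everywhere are **highest posterior density intervals**:
the narrowest contiguous window over the sorted draws containing
⌈mass·n⌉ draws, earliest window on ties (checked against a brute-force
window search).

## The synthetic cohort generator

The generator emulates the study conditions so the full chain runs without
any external data:

- **Controllable schedules**: a softmax over the levels that still have
  stimuli remaining, with linear trial utilities (high decreasing, low
  increasing, medium tent-shaped peaking mid-run) scaled by `choice_bias`.
  The default `choice_bias = 0.85` was calibrated once so the implied
  group-level choice slopes (≈ +3.0 %/trial for low, −3.8 for high)
  match the study's reported slopes (+3.08, −3.59); only the signs and the
  inverted-U shape are treated as testable claims.
- **Matched schedules**: `yoked` copies the subject's controllable
  sequences verbatim into P and U runs (the study's final approach);
  `probability_matched` samples per-trial levels from donor frequencies
  under the 5-per-level cap (renormalizing when a level is exhausted);
  `free_random` shuffles a balanced multiset.
- **Subject parameters**: drawn from the group-level distributions above.
  The N(level, 100) entries are weakly-informative *fitting* hyperpriors,
  not plausible population spreads, so subject prior means are drawn
  around the VAS targets with spread σ_μ0 at its prior median e^1.5 ≈ 4.48;
  SD-type parameters use their literal log-normal priors, α its truncated
  normal, h its N(0, 1). Any of these can be overridden per parameter —
  a scalar fixes the value for every subject (used when a recovery study
  needs a known group value).
- **Ratings** are drawn through the same `predict` code path the
  likelihood evaluates, so simulated data are by construction distributed
  as the fitted model assumes (a moment test asserts this).
- **Reaction times** are a condition-shift toy model (truncated normals
  with the study's condition means/SDs; choice trials slowest). They
  support the descriptive RT summary only — no RT model is fitted.
- Optional timeouts set ratings to missing; missing ratings are dropped
  from all likelihoods and SD cells, while the applied stimulus still
  counts for dynamic-prior weights (the participant felt it even if the
  rating timed out).

What the generator does **not** emulate: calibration/temperature noise,
drift across sessions beyond the linear h, sequential rating dependencies,
response-scale anchoring effects, or any deviation of real raters from the
truncated-normal observer. Passing tests therefore show that the pipeline
is correct and well calibrated *under the model's own assumptions*, not
that the model is true of real participants.

## Scaled-down study sizes

The recovery and comparison analyses in this repository run at reduced
scale as the package's default problem sizes: recovery cohorts of 10–20
subjects at the `recovery` MCMC profile (the study-scale 60-subject run
uses the same code path with `n_subjects=60`), model comparison on 6–12
subject cohorts, LMM calibration at 50 replicates of 10 subjects with
shortened chains, and the exact-refit LOO oracle on 3-subject single-run
toys to respect its refit-per-trial cost. The power analysis defaults to
20 replicates per sample size.

Model-selection demonstrations generate data with τ₀_C = 5, τ₀_P = 10
(precision halved by control) — consistent in direction with the observed
condition ordering of within-subject rating SDs, amplified to a clearly
detectable ratio — and α = 0.74, the group-level likelihood weight the
study reports.

## Numerical notes

- Truncated-normal log densities use the stable log-CDF difference
  (reflecting the interval into the lower tail before differencing);
  sampling is inverse-CDF based and rejection-free, so locations far
  outside [0, 100] are handled without looping.
- The degenerate PSIS case (importance ratios with zero spread, e.g. a
  constant log-likelihood column) has exact weights; its k̂ is reported
  as 0 rather than the undefined tail fit.
- A constant choice-percentage outcome gives a degenerate conjugate
  posterior; the SSR is floored at 1e-9 so the slope posterior collapses
  to zero width instead of dividing by zero.
- HPDI ties are broken toward the earliest window; samples of fewer than
  2 draws are rejected.

## Known limitations

- The slice-within-Gibbs sampler updates one scalar at a time (plus the
  h-direction line move); it is exact but less efficient than a
  gradient-based sampler on strongly correlated posteriors, which is why
  the convergence gate and ESS are reported with every fit.
- The robust-LOO tilt makes the sampled target slightly heavier-tailed;
  at very small draw counts its ELPD is noisier than PSIS where PSIS is
  valid (both are checked against the exact refit oracle).
- `exact_refit_loo` is O(n) refits and deliberately capped.
- The three-alpha variant is included for completeness; its α_P (and to a
  lesser degree α_C) is structurally non-identifiable on this design, as
  the recovery analysis shows.
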
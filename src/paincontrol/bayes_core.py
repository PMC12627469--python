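"""Closed-form core of the expectation-integration model.

Pain ratings on a bounded 0-100 visual analogue scale (VAS) are modelled as
draws from a truncated normal whose location is the Bayesian combination of
an expectation (prior) and the nociceptive input (likelihood).  This module
collects the pure functions shared by the generative simulator and the
likelihood of the hierarchical fits:

* normal-normal integration in its precision-weighted form and in the
  equivalent shrinkage form ``mu1 = mu0 + alpha * (y - mu0)`` with
  ``alpha = tau0^2 / (sigma^2 + tau0^2)``,
* a linear habituation/sensitization drift subtracted from the trial mean,
* the dynamic prior mean of the unpredictable condition, a weighted average
  of the per-intensity prior means with weights given by the remaining
  number of occurrences of each intensity divided by the remaining trials,
* truncated-normal moments, log-density and rejection-free sampling on the
  VAS bounds.

The likelihood SD ``sigma`` never appears as a free parameter downstream:
its contribution is only identifiable through ``alpha`` and the posterior
SD, so the fitting modules work directly with ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import special, stats

__all__ = [
    "PriorState",
    "PosteriorState",
    "DynamicPriorInput",
    "integrate_normal",
    "alpha_from_variances",
    "shrink_mean",
    "habituated_mean",
    "dynamic_prior_mean",
    "trunc_normal_mean",
    "trunc_normal_logpdf",
    "sample_trunc_normal",
    "VAS_LO",
    "VAS_HI",
]

VAS_LO = 0.0
VAS_HI = 100.0

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class PriorState:
    """Expectation about the upcoming stimulus: mean and SD in VAS units."""

    mu0: float
    tau0: float

    def __post_init__(self) -> None:
        if self.tau0 <= 0:
            raise ValueError(f"prior SD tau0 must be > 0, got {self.tau0}")


@dataclass(frozen=True)
class PosteriorState:
    """Integrated percept: posterior mean and SD in VAS units."""

    mu1: float
    tau1: float

    def __post_init__(self) -> None:
        if self.tau1 <= 0:
            raise ValueError(f"posterior SD tau1 must be > 0, got {self.tau1}")


@dataclass(frozen=True)
class DynamicPriorInput:
    """Remaining stimulus counts and per-intensity prior means for one trial."""

    remaining_counts: Mapping[int, int]
    mu0_by_level: Mapping[int, float]

    def __post_init__(self) -> None:
        for level, count in self.remaining_counts.items():
            if count < 0:
                raise ValueError(f"negative remaining count for level {level}")
            if level not in self.mu0_by_level:
                raise ValueError(f"no prior mean supplied for level {level}")


def integrate_normal(prior: PriorState, y: float, sigma: float) -> PosteriorState:
    """Precision-weighted normal-normal integration.

    The posterior mean is the precision-weighted, normalized sum of the prior
    mean and the likelihood mean; the posterior precision is the sum of the
    component precisions, so ``tau1 < min(tau0, sigma)``.
    """
    if sigma <= 0:
        raise ValueError(f"likelihood SD sigma must be > 0, got {sigma}")
    prior_prec = 1.0 / prior.tau0**2
    lik_prec = 1.0 / sigma**2
    post_prec = prior_prec + lik_prec
    mu1 = (prior_prec * prior.mu0 + lik_prec * y) / post_prec
    return PosteriorState(mu1=mu1, tau1=np.sqrt(1.0 / post_prec))


def alpha_from_variances(tau0_sq: float, sigma_sq: float) -> float:
    """Likelihood weight ``alpha = tau0^2 / (sigma^2 + tau0^2)`` in [0, 1]."""
    if tau0_sq < 0 or sigma_sq < 0:
        raise ValueError("variances must be non-negative")
    total = tau0_sq + sigma_sq
    if total == 0:
        raise ValueError("alpha undefined for tau0^2 = sigma^2 = 0")
    return tau0_sq / total


def shrink_mean(mu0: float, alpha: float, y: float) -> float:
    """Posterior mean in shrinkage form: ``mu0 + alpha * (y - mu0)``.

    ``alpha`` close to 1 leaves the percept at the sensory input; small
    ``alpha`` pulls it toward the expectation.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    return mu0 + alpha * (y - mu0)


def habituated_mean(y_i: float, h: float, t) -> float:
    """Trial-level likelihood mean ``y_t = y_i - h * t``.

    ``h > 0`` models habituation (drift toward lower pain over the run),
    ``h < 0`` sensitization.  ``t`` is the 1-based trial index within a run.
    """
    return y_i - h * np.asarray(t, dtype=float)


def dynamic_prior_mean(inp: DynamicPriorInput) -> float:
    """Expected intensity in the unpredictable condition for one trial.

    Weights are remaining occurrences of each intensity divided by remaining
    trials in the run; the prior mean is the weight-averaged per-intensity
    prior mean.  At trial 1 of a 15-trial run all weights are 5/15 = 1/3.
    """
    total = sum(inp.remaining_counts.values())
    if total <= 0:
        raise ValueError("no remaining trials: all counts are zero")
    return (
        sum(c * inp.mu0_by_level[lvl] for lvl, c in inp.remaining_counts.items())
        / total
    )


def _trunc_bounds(mu, sd, lo, hi):
    mu = np.asarray(mu, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(sd <= 0):
        raise ValueError("sd must be > 0")
    if not np.all(lo < hi):
        raise ValueError("lower bound must be below upper bound")
    a = (lo - mu) / sd
    b = (hi - mu) / sd
    return mu, sd, a, b


def _log_z(a, b):
    # log(Phi(b) - Phi(a)), stable in both tails: reflect so the interval
    # sits in the lower tail, then difference two log CDFs.
    a, b = np.broadcast_arrays(a, b)
    flip = a > 0
    a_ = np.where(flip, -b, a)
    b_ = np.where(flip, -a, b)
    log_cdf_b = special.log_ndtr(b_)
    log_cdf_a = special.log_ndtr(a_)
    with np.errstate(invalid="ignore"):
        out = log_cdf_b + np.log1p(-np.exp(log_cdf_a - log_cdf_b))
    return out


def trunc_normal_mean(mu, sd, lo: float = VAS_LO, hi: float = VAS_HI):
    """Mean of a normal(mu, sd) truncated to [lo, hi].

    Closed form ``mu + sd * (phi(a) - phi(b)) / Z``.  Because probability
    mass reflects off the bounds, a less precise distribution has its mean
    pulled toward the interval midpoint: increasing in ``sd`` for ``mu``
    below the midpoint, decreasing above it.
    """
    mu, sd, a, b = _trunc_bounds(mu, sd, lo, hi)
    log_z = _log_z(a, b)
    phi_a = np.exp(-0.5 * a**2 - _LOG_SQRT_2PI - log_z)
    phi_b = np.exp(-0.5 * b**2 - _LOG_SQRT_2PI - log_z)
    out = mu + sd * (phi_a - phi_b)
    return out if out.ndim else float(out)


def trunc_normal_logpdf(x, mu, sd, lo: float = VAS_LO, hi: float = VAS_HI):
    """Log density of a [lo, hi]-truncated normal, vectorized.

    Finite for every ``x`` in [lo, hi] (the bounds carry the truncated
    density, not censored point mass); -inf outside.
    """
    mu, sd, a, b = _trunc_bounds(mu, sd, lo, hi)
    x = np.asarray(x, dtype=float)
    z = (x - mu) / sd
    out = -0.5 * z**2 - _LOG_SQRT_2PI - np.log(sd) - _log_z(a, b)
    out = np.where((x >= lo) & (x <= hi), out, -np.inf)
    return out if out.ndim else float(out)


def sample_trunc_normal(
    mu,
    sd,
    lo: float = VAS_LO,
    hi: float = VAS_HI,
    rng: np.random.Generator | int | None = None,
    size=None,
):
    """Draw from a [lo, hi]-truncated normal via the inverse CDF.

    Rejection-free, so locations far outside the bounds (e.g. mu = 120 on
    the VAS) return valid draws near the bound instead of looping.
    """
    mu, sd, a, b = _trunc_bounds(mu, sd, lo, hi)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    draws = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)
    return np.clip(draws, lo, hi)
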
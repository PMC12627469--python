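"""Bayesian descriptive regressions for the rating task.

Covers the behavioral results that frame the modelling: the
condition-by-intensity linear mixed model (LMM) on trial ratings, the
condition + intensity-factor LMM on within-subject rating SDs, the
linear/quadratic regressions of group-level choice percentages on trial
position, and the within-subject-corrected SEM used for condition plots.

All mixed models share one Gibbs/slice sampler: subject random intercepts
and the residual SD have conjugate updates, fixed-effect coefficients get
univariate slice updates under their priors — normal(0, 50) for the
intercept, Cauchy(0, 2.5) for predictor weights, a flat positive prior for
the residual SD.  The choice-frequency models use fully flat priors and
are sampled exactly from the conjugate normal-inverse-gamma posterior.
Intervals are highest-posterior-density intervals from the shared
minimal-window routine.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import arviz as az
import numpy as np
import pandas as pd

from .comparison import ElpdResult, psis_loo
from .models import hpdi
from .trial_data import Dataset, LEVELS

__all__ = [
    "LmmSpec",
    "LmmResult",
    "fit_rating_lmm",
    "fit_sd_lmm",
    "fit_choice_freq",
    "within_subject_sem",
]


@dataclasses.dataclass(frozen=True)
class LmmSpec:
    """Design choices of a descriptive mixed model.

    ``baseline`` names the reference condition whose dummies are dropped;
    ``baseline_intensity`` (SD model only) the reference intensity level.
    Intensity enters the rating model as a linear VAS covariate anchored at
    the pain threshold (VAS 0), and the SD model as a 3-level factor.
    """

    outcome: str = "rating"
    baseline: str = "C"
    baseline_intensity: int = 30
    intercept_prior_sd: float = 50.0
    coef_cauchy_scale: float = 2.5
    ranef_cauchy_scale: float = 25.0

    def __post_init__(self) -> None:
        if self.baseline not in ("C", "P", "U"):
            raise ValueError(f"baseline must be C/P/U, got {self.baseline!r}")
        if self.outcome not in ("rating", "sd", "choice_percent"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.baseline_intensity not in LEVELS:
            raise ValueError("baseline_intensity must be one of 30/50/70")


@dataclasses.dataclass
class LmmResult:
    """Posterior summaries plus raw coefficient draws."""

    summary: pd.DataFrame               # term, mean, hpdi_lo, hpdi_hi, rhat, ess
    draws: dict[str, np.ndarray]        # term -> (chains, kept)
    converged: bool

    def coefficient_draws(self, term: str) -> np.ndarray:
        return self.draws[term].reshape(-1)


def _gibbs_lmm(
    y: np.ndarray,
    X: np.ndarray,
    terms: Sequence[str],
    group_idx: np.ndarray,
    n_groups: int,
    spec: LmmSpec,
    seed: int,
    chains: int,
    iterations: int,
    warmup: int,
) -> LmmResult:
    """Blocked Gibbs for the Gaussian mixed model.

    Fixed effects are drawn jointly from their multivariate-normal full
    conditional (the Cauchy priors enter through their normal
    scale-mixture representation, with conjugate inverse-gamma updates of
    the local scales), subject intercepts and both SDs are conjugate as
    well — the half-Cauchy prior on the random-intercept SD via its own
    inverse-gamma auxiliary.  Blocked draws keep mixing fast despite the
    strong collinearity of intercept, intensity and interaction columns.
    """
    n, p = X.shape
    kept = iterations - warmup
    master = np.random.default_rng(seed)
    chain_seeds = master.integers(0, 2**31 - 1, size=chains)
    XtX = X.T @ X
    Xty = X.T @ y
    # per-group sums of predictor rows and outcomes, for O(J p) updates
    G = np.zeros((n_groups, p))
    np.add.at(G, group_idx, X)
    Sy = np.bincount(group_idx, weights=y, minlength=n_groups)
    counts = np.bincount(group_idx, minlength=n_groups)
    cauchy_s2 = spec.coef_cauchy_scale**2

    store = {t: np.empty((chains, kept)) for t in terms}
    store["sigma"] = np.empty((chains, kept))
    store["sigma_subject"] = np.empty((chains, kept))

    for c in range(chains):
        rng = np.random.default_rng(int(chain_seeds[c]))
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        beta = beta + rng.normal(0, 0.1, size=p)
        u = np.zeros(n_groups)
        sigma = float(np.std(y - X @ beta) + 0.1)
        sigma_u2 = 25.0
        lam = np.ones(p)  # local scales of the Cauchy slab (index 0 unused)

        for it in range(iterations):
            # local Cauchy scales: lambda_k | beta_k ~ Inv-Gamma(1, .)
            lam[1:] = (0.5 * (1.0 + beta[1:] ** 2 / cauchy_s2)) / rng.gamma(
                1.0, size=p - 1
            )
            prior_prec = np.empty(p)
            prior_prec[0] = 1.0 / spec.intercept_prior_sd**2
            prior_prec[1:] = 1.0 / (cauchy_s2 * lam[1:])

            # fixed effects: joint multivariate-normal draw
            A = XtX / sigma**2 + np.diag(prior_prec)
            b = (Xty - G.T @ u) / sigma**2
            L = np.linalg.cholesky(A)
            mean = np.linalg.solve(A, b)
            z = rng.standard_normal(p)
            beta = mean + np.linalg.solve(L.T, z)

            # subject intercepts: conjugate normal
            resid_sums = Sy - G @ beta
            post_var = 1.0 / (counts / sigma**2 + 1.0 / sigma_u2)
            post_mean = post_var * resid_sums / sigma**2
            u = rng.normal(post_mean, np.sqrt(post_var))

            # random-intercept variance: half-Cauchy via inverse-gamma auxiliary
            a_u = (1.0 / spec.ranef_cauchy_scale**2 + 1.0 / sigma_u2) / rng.gamma(1.0)
            sigma_u2 = (1.0 / a_u + 0.5 * float(u @ u)) / rng.gamma(
                (n_groups + 1) / 2.0
            )

            # residual SD: flat positive prior -> inverse-gamma draw
            r = y - X @ beta - u[group_idx]
            ssr = float(r @ r)
            v = ssr / 2.0 / rng.gamma((n - 1) / 2.0)
            sigma = float(np.sqrt(v))

            if it >= warmup:
                pos = it - warmup
                for k, t in enumerate(terms):
                    store[t][c, pos] = beta[k]
                store["sigma"][c, pos] = sigma
                store["sigma_subject"][c, pos] = float(np.sqrt(sigma_u2))

    idata = az.from_dict(posterior={t: v for t, v in store.items()})
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rows = []
    for t, arr in store.items():
        flat = arr.reshape(-1)
        lo, hi = hpdi(flat, 0.95)
        rows.append(
            {
                "term": t,
                "mean": float(flat.mean()),
                "hpdi_lo": lo,
                "hpdi_hi": hi,
                "rhat": float(np.asarray(rhat[t])),
                "ess_bulk": float(np.asarray(ess[t])),
            }
        )
    summary = pd.DataFrame(rows)
    converged = bool((summary["rhat"] < 1.01).all())
    if not converged:
        warnings.warn("mixed-model fit flagged: split-R-hat >= 1.01")
    return LmmResult(summary=summary, draws=store, converged=converged)


def _condition_design(
    df: pd.DataFrame, baseline: str
) -> tuple[np.ndarray, list[str]]:
    conds = [c for c in ("C", "P", "U") if c != baseline]
    cols = [(df["condition"] == c).to_numpy(dtype=float) for c in conds]
    return np.column_stack(cols), conds


def fit_rating_lmm(
    data: Dataset,
    spec: LmmSpec | None = None,
    seed: int = 0,
    chains: int = 4,
    iterations: int = 4000,
    warmup: int = 1000,
) -> pd.DataFrame:
    """Condition-by-intensity mixed model on trial-level ratings.

    Fixed effects: linear intensity (VAS units, anchored at the pain
    threshold VAS 0), condition dummies against the baseline, their
    interactions, trial and session number; random intercept per subject.
    Interaction terms are named ``<condition>:intensity``; refitting with
    the other baselines yields the remaining pairwise interactions.
    Returns the coefficient summary (the full result with draws is in
    ``attrs['result']``).
    """
    spec = spec or LmmSpec()
    df = data.df[data.df["rating"].notna()].reset_index(drop=True)
    if df["condition"].nunique() < 2:
        raise ValueError("need at least 2 conditions for the rating LMM")
    intensity = df["intensity_level"].to_numpy(dtype=float)
    cond_mat, conds = _condition_design(df, spec.baseline)
    X = np.column_stack(
        [
            np.ones(len(df)),
            intensity,
            cond_mat,
            cond_mat * intensity[:, None],
            df["trial"].to_numpy(dtype=float),
            df["session"].to_numpy(dtype=float),
        ]
    )
    terms = (
        ["intercept", "intensity"]
        + conds
        + [f"{c}:intensity" for c in conds]
        + ["trial", "session"]
    )
    subjects = pd.Categorical(df["subject_id"])
    res = _gibbs_lmm(
        df["rating"].to_numpy(dtype=float),
        X,
        terms,
        subjects.codes.astype(int),
        len(subjects.categories),
        spec,
        seed,
        chains,
        iterations,
        warmup,
    )
    out = res.summary.copy()
    out.attrs["result"] = res
    return out


def fit_sd_lmm(
    sd_table: pd.DataFrame,
    spec: LmmSpec | None = None,
    seed: int = 0,
    chains: int = 4,
    iterations: int = 4000,
    warmup: int = 1000,
) -> pd.DataFrame:
    """Condition + intensity-factor mixed model on within-subject SDs.

    Input is the subject x condition x intensity SD table.  Intensity
    enters as a 3-level factor (dummies ``int<level>`` against
    ``baseline_intensity``) because the SDs peak at the medium level; the
    two stated baseline parameterizations together give every pairwise
    condition and intensity contrast.
    """
    spec = spec or LmmSpec(outcome="sd", baseline="U", baseline_intensity=30)
    df = sd_table[sd_table["sd"].notna()].reset_index(drop=True)
    cond_mat, conds = _condition_design(df, spec.baseline)
    other_levels = [l for l in LEVELS if l != spec.baseline_intensity]
    int_mat = np.column_stack(
        [(df["intensity_level"] == l).to_numpy(dtype=float) for l in other_levels]
    )
    X = np.column_stack([np.ones(len(df)), cond_mat, int_mat])
    terms = ["intercept"] + conds + [f"int{l}" for l in other_levels]
    subjects = pd.Categorical(df["subject"])
    res = _gibbs_lmm(
        df["sd"].to_numpy(dtype=float),
        X,
        terms,
        subjects.codes.astype(int),
        len(subjects.categories),
        spec,
        seed,
        chains,
        iterations,
        warmup,
    )
    out = res.summary.copy()
    out.attrs["result"] = res
    return out


@dataclasses.dataclass
class ChoiceFreqResult:
    """Polynomial fit of choice percentages over trial position."""

    level: int
    degree: int
    summary: pd.DataFrame
    draws: dict[str, np.ndarray]       # term -> flat draws
    elpd: ElpdResult


def fit_choice_freq(
    table: pd.DataFrame,
    level: int,
    degree: int = 1,
    seed: int = 0,
    n_draws: int = 4000,
) -> ChoiceFreqResult:
    """Bayesian regression of group-level choice percentages on trial.

    Flat priors on the coefficients and the (positive) error SD make the
    posterior conjugate, so it is sampled exactly: sigma^2 from its
    inverse-gamma marginal, coefficients from the conditional normal.
    ``degree=2`` adds the quadratic term used for the medium level's
    inverted-U; the attached PSIS-LOO ELPD supports the degree comparison.
    """
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    sub = table[table["intensity_level"] == level].sort_values("trial")
    t = sub["trial"].to_numpy(dtype=float)
    y = sub["percent"].to_numpy(dtype=float)
    if len(t) == 0:
        raise ValueError(f"no rows for level {level}")
    cols = [np.ones_like(t), t] + ([t**2] if degree == 2 else [])
    X = np.column_stack(cols)
    terms = ["intercept", "slope"] + (["quadratic"] if degree == 2 else [])
    n, p = X.shape
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    beta_hat = XtX_inv @ X.T @ y
    ssr = max(float((y - X @ beta_hat) @ (y - X @ beta_hat)), 1e-9)
    rng = np.random.default_rng(seed)
    # sigma^2 | y ~ Inv-Gamma((n - p - 1)/2, SSR/2) under flat priors
    a = (n - p - 1) / 2.0
    sig2 = ssr / 2.0 / rng.gamma(a, size=n_draws)
    chol = np.linalg.cholesky(XtX_inv)
    z = rng.standard_normal((n_draws, p))
    betas = beta_hat[None, :] + np.sqrt(sig2)[:, None] * (z @ chol.T)

    loglik = (
        -0.5 * ((y[None, :] - betas @ X.T) ** 2) / sig2[:, None]
        - 0.5 * np.log(2 * np.pi * sig2)[:, None]
    )
    elpd = psis_loo(loglik)

    draws = {term: betas[:, k] for k, term in enumerate(terms)}
    draws["sigma"] = np.sqrt(sig2)
    rows = []
    for term, arr in draws.items():
        lo, hi = hpdi(arr, 0.95)
        rows.append({"term": term, "mean": float(arr.mean()), "hpdi_lo": lo, "hpdi_hi": hi})
    return ChoiceFreqResult(
        level=level,
        degree=degree,
        summary=pd.DataFrame(rows),
        draws=draws,
        elpd=elpd,
    )


def within_subject_sem(cell_means: pd.DataFrame) -> pd.Series:
    """SEM corrected for within-subject designs (subject-mean centering).

    ``cell_means`` is wide: one row per subject, one column per cell.
    Each subject's profile is centered on its own mean and shifted to the
    grand mean, removing between-subject offsets; the SEM of the centered
    values is inflated by sqrt(M/(M-1)) for M cells to correct the
    variance bias of the centering.  Subjects with missing cells are
    excluded with a warning.
    """
    complete = cell_means.dropna(axis=0)
    if len(complete) < len(cell_means):
        warnings.warn(
            f"{len(cell_means) - len(complete)} subject(s) with missing cells excluded"
        )
    if complete.empty:
        raise ValueError("no complete subjects")
    values = complete.to_numpy(dtype=float)
    n, m = values.shape
    if m == 1:
        # no within-subject structure to remove: plain SEM
        sem = values.std(axis=0, ddof=1) / np.sqrt(n)
        return pd.Series(sem, index=complete.columns, name="sem")
    centered = values - values.mean(axis=1, keepdims=True) + values.mean()
    sem = centered.std(axis=0, ddof=1) / np.sqrt(n) * np.sqrt(m / (m - 1))
    return pd.Series(sem, index=complete.columns, name="sem")
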
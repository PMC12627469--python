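"""The suite of expectation-integration model variants and their fits.

Eight generative accounts of trial-level pain ratings are implemented.  All
model the rating as a draw from a [0,100]-truncated normal whose location
and spread depend on condition:

``null_hab``
    habituation only: ratings around the (habituated) VAS target with
    subject-specific noise in every condition.
``null_means``
    free prior means for the controllable (C) and predictable (P)
    condition, but no expectation bias in the unpredictable (U) condition.
``mean_shift_fixed`` / ``mean_shift_dynamic``
    separate C and P prior means, shared prior SD tau0; U trials integrate
    a central prior (fixed at a subject constant, or dynamically updated
    from the remaining stimulus counts) with the habituated input via the
    likelihood weight alpha.
``precision_change_fixed`` / ``precision_change_dynamic``
    shared C/P prior means but condition-specific prior SDs tau0_C and
    tau0_P; U trials as above.
``two_alpha`` / ``three_alpha``
    shrinkage in every condition with a condition-specific likelihood
    weight (alpha_U + shared alpha_CP, or alpha_U / alpha_P / alpha_C) and
    a common posterior SD tau1.

In C and P trials of the mean-shift / precision-change / null-means models
the rating is sampled directly from the (habituated) prior — the cue makes
the prior and the input coincide, so prediction errors are absent and the
prior SD is the rating SD.

Fitting is hierarchical: subject-level prior means are partially pooled
around group-level means (one per intensity, hyperpriors centred on the
VAS targets) with pooling SD sigma_mu0; SD-type parameters are sampled on
the log scale, alpha on its truncated [0,1] scale, all with the group-level
priors of the study design.  Sampling uses seeded slice-within-Gibbs
updates with conjugate draws for the group means; convergence is gated at
split-R-hat < 1.01.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping, Sequence

import arviz as az
import numpy as np
import pandas as pd

from .bayes_core import sample_trunc_normal, trunc_normal_logpdf
from .sampler import slice_sample
from .trial_data import Dataset, LEVELS, PER_LEVEL, TRIALS_PER_RUN, TrialRecord

__all__ = [
    "VARIANTS",
    "MCMC_PROFILES",
    "Hyperpriors",
    "ModelSpec",
    "SubjectParameters",
    "FitResult",
    "RecoveryReport",
    "trial_predictive_params",
    "log_likelihood",
    "fit_hierarchical",
    "hpdi",
    "posterior_predict",
    "parameter_recovery",
]

VARIANTS = (
    "null_hab",
    "null_means",
    "mean_shift_fixed",
    "mean_shift_dynamic",
    "precision_change_fixed",
    "precision_change_dynamic",
    "two_alpha",
    "three_alpha",
)

#: (chains, total iterations incl. warmup, warmup)
MCMC_PROFILES = {
    "paper": (4, 4000, 1000),
    "recovery": (4, 1000, 500),
    "smoke": (2, 500, 250),
}

def _fast_trunc_ll(x: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """[0,100]-truncated normal log density, sampler hot path.

    Same values as :func:`paincontrol.bayes_core.trunc_normal_logpdf` for
    ratings already validated to lie in [0,100]; skips the domain checks.
    """
    from scipy.special import log_ndtr

    a = (0.0 - mu) / sd
    b = (100.0 - mu) / sd
    flip = a > 0
    if flip.any():
        a, b = np.where(flip, -b, a), np.where(flip, -a, b)
    lb = log_ndtr(b)
    logz = lb + np.log1p(-np.exp(log_ndtr(a) - lb))
    z = (x - mu) / sd
    return -0.5 * z * z - np.log(sd) - 0.9189385332046727 - logz


_LEVEL_ARR = np.asarray(LEVELS, dtype=float)
_LEVEL_INDEX = {lvl: i for i, lvl in enumerate(LEVELS)}
_COND_CODE = {"C": 0, "P": 1, "U": 2}


@dataclasses.dataclass(frozen=True)
class Hyperpriors:
    """Group-level priors of the study design.

    Second arguments of the normal distributions are standard deviations.
    SD-type parameters (tau0, tau1, noise, sigma_mu0) have normal priors on
    the log scale; alpha has a [0,1]-truncated normal prior.
    """

    mu0_mean: tuple[float, float, float] = (30.0, 50.0, 70.0)
    mu0_sd: float = 100.0
    mu0_u_mean: float = 50.0
    mu0_u_sd: float = 100.0
    log_sd_mean: float = 1.5
    log_sd_sd: float = 0.5
    log_sigma_mu0_mean: float = 1.5
    log_sigma_mu0_sd: float = 0.5
    alpha_mean: float = 0.5
    alpha_sd: float = 0.3
    h_mean: float = 0.0
    h_sd: float = 1.0


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """A model variant plus its hyperpriors and MCMC settings."""

    variant: str
    chains: int = 4
    iterations: int = 4000
    warmup: int = 1000
    hyperpriors: Hyperpriors = Hyperpriors()

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown model variant {self.variant!r}")
        if not 0 < self.warmup < self.iterations:
            raise ValueError("need 0 < warmup < iterations")

    @classmethod
    def with_profile(cls, variant: str, profile: str = "paper", **kw) -> "ModelSpec":
        chains, iterations, warmup = MCMC_PROFILES[profile]
        return cls(variant=variant, chains=chains, iterations=iterations, warmup=warmup, **kw)

    @property
    def kept(self) -> int:
        return self.iterations - self.warmup


# --------------------------------------------------------------------------
# parameter layout per variant
# --------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class _Entry:
    name: str   # storage name, e.g. "mu0_C_30", "tau0_P", "alpha_U", "h"
    kind: str   # "mu0" | "mu0_U" | "log_sd" | "alpha" | "h"
    group: str | None = None  # group-mean key for hierarchical entries


def _mu0_entries(tag: str) -> list[_Entry]:
    return [_Entry(f"mu0_{tag}_{lvl}", "mu0", f"m_{lvl}") for lvl in LEVELS]


_SCHEMAS: dict[str, list[_Entry]] = {
    "null_hab": [_Entry("h", "h"), _Entry("noise", "log_sd")],
    "null_means": (
        _mu0_entries("C")
        + _mu0_entries("P")
        + [_Entry("tau0", "log_sd"), _Entry("h", "h"), _Entry("noise", "log_sd")]
    ),
    "mean_shift_fixed": (
        _mu0_entries("C")
        + _mu0_entries("P")
        + [
            _Entry("mu0_U", "mu0_U", "m_U"),
            _Entry("tau0", "log_sd"),
            _Entry("tau1", "log_sd"),
            _Entry("alpha", "alpha"),
            _Entry("h", "h"),
        ]
    ),
    "mean_shift_dynamic": (
        _mu0_entries("C")
        + _mu0_entries("P")
        + [
            _Entry("tau0", "log_sd"),
            _Entry("tau1", "log_sd"),
            _Entry("alpha", "alpha"),
            _Entry("h", "h"),
        ]
    ),
    "precision_change_fixed": (
        _mu0_entries("S")
        + [
            _Entry("mu0_U", "mu0_U", "m_U"),
            _Entry("tau0_C", "log_sd"),
            _Entry("tau0_P", "log_sd"),
            _Entry("tau1", "log_sd"),
            _Entry("alpha", "alpha"),
            _Entry("h", "h"),
        ]
    ),
    "precision_change_dynamic": (
        _mu0_entries("S")
        + [
            _Entry("tau0_C", "log_sd"),
            _Entry("tau0_P", "log_sd"),
            _Entry("tau1", "log_sd"),
            _Entry("alpha", "alpha"),
            _Entry("h", "h"),
        ]
    ),
    "two_alpha": (
        _mu0_entries("S")
        + [
            _Entry("tau1", "log_sd"),
            _Entry("alpha_U", "alpha"),
            _Entry("alpha_CP", "alpha"),
            _Entry("h", "h"),
        ]
    ),
    "three_alpha": (
        _mu0_entries("S")
        + [
            _Entry("tau1", "log_sd"),
            _Entry("alpha_U", "alpha"),
            _Entry("alpha_P", "alpha"),
            _Entry("alpha_C", "alpha"),
            _Entry("h", "h"),
        ]
    ),
}


class _Layout:
    """Index bookkeeping between a flat parameter vector and a variant."""

    def __init__(self, variant: str) -> None:
        if variant not in _SCHEMAS:
            raise ValueError(f"unknown model variant {variant!r}")
        self.variant = variant
        self.entries: list[_Entry] = list(_SCHEMAS[variant])
        self.names = [e.name for e in self.entries]
        self.idx = {e.name: k for k, e in enumerate(self.entries)}
        self.n = len(self.entries)
        self.hierarchical = any(e.kind in ("mu0", "mu0_U") for e in self.entries)
        self.dynamic_u = variant in (
            "mean_shift_dynamic",
            "precision_change_dynamic",
            "two_alpha",
            "three_alpha",
        )
        idx = self.idx
        self.i_h = idx["h"]
        self.i_mu0_C = (
            np.array([idx[f"mu0_C_{l}"] for l in LEVELS]) if "mu0_C_30" in idx else None
        )
        self.i_mu0_P = (
            np.array([idx[f"mu0_P_{l}"] for l in LEVELS]) if "mu0_P_30" in idx else None
        )
        self.i_mu0_S = (
            np.array([idx[f"mu0_S_{l}"] for l in LEVELS]) if "mu0_S_30" in idx else None
        )
        #: group-mean key -> vector positions pooled around it
        self.group_cols: dict[str, list[int]] = {}
        for k, e in enumerate(self.entries):
            if e.group is not None:
                self.group_cols.setdefault(e.group, []).append(k)

    # -- vector <-> predictive arrays -------------------------------------
    def predict(self, vec: np.ndarray, d: "_SubjectDesign"):
        """Trial-level (mu, sd) for one subject.  Internal hot path."""
        v = self.variant
        idx = self.idx
        h = vec[self.i_h]
        y_t = d.y - h * d.t
        mu = np.empty_like(y_t)
        sd = np.empty_like(y_t)

        if v == "null_hab":
            mu[:] = y_t
            sd[:] = np.exp(vec[idx["noise"]])
            return mu, sd

        if v in ("null_means", "mean_shift_fixed", "mean_shift_dynamic"):
            mu0_C = vec[self.i_mu0_C]
            mu0_P = vec[self.i_mu0_P]
            tau0 = np.exp(vec[idx["tau0"]])
            mu[d.iC] = mu0_C[d.lvlC] - h * d.tC
            mu[d.iP] = mu0_P[d.lvlP] - h * d.tP
            sd[d.iC] = tau0
            sd[d.iP] = tau0
            if v == "null_means":
                mu[d.iU] = y_t[d.iU]
                sd[d.iU] = np.exp(vec[idx["noise"]])
            else:
                if v == "mean_shift_fixed":
                    mu0_u = vec[idx["mu0_U"]]
                else:
                    mu0_u = d.WU @ ((mu0_C + mu0_P) / 2.0)
                alpha = vec[idx["alpha"]]
                mu[d.iU] = mu0_u + alpha * (y_t[d.iU] - mu0_u)
                sd[d.iU] = np.exp(vec[idx["tau1"]])
            return mu, sd

        mu0 = vec[self.i_mu0_S]
        if v in ("precision_change_fixed", "precision_change_dynamic"):
            mu[d.iC] = mu0[d.lvlC] - h * d.tC
            mu[d.iP] = mu0[d.lvlP] - h * d.tP
            sd[d.iC] = np.exp(vec[idx["tau0_C"]])
            sd[d.iP] = np.exp(vec[idx["tau0_P"]])
            if v == "precision_change_fixed":
                mu0_u = vec[idx["mu0_U"]]
            else:
                mu0_u = d.WU @ mu0
            alpha = vec[idx["alpha"]]
            mu[d.iU] = mu0_u + alpha * (y_t[d.iU] - mu0_u)
            sd[d.iU] = np.exp(vec[idx["tau1"]])
            return mu, sd

        # multi-alpha variants: shrinkage with condition-specific alpha,
        # common posterior SD tau1, dynamic U prior
        sd[:] = np.exp(vec[idx["tau1"]])
        if v == "two_alpha":
            a_C = a_P = vec[idx["alpha_CP"]]
        else:
            a_C = vec[idx["alpha_C"]]
            a_P = vec[idx["alpha_P"]]
        a_U = vec[idx["alpha_U"]]
        prior_C = mu0[d.lvlC]
        prior_P = mu0[d.lvlP]
        mu[d.iC] = prior_C + a_C * (y_t[d.iC] - prior_C)
        mu[d.iP] = prior_P + a_P * (y_t[d.iP] - prior_P)
        mu0_u = d.WU @ mu0
        mu[d.iU] = mu0_u + a_U * (y_t[d.iU] - mu0_u)
        return mu, sd


# --------------------------------------------------------------------------
# public parameter container
# --------------------------------------------------------------------------

@dataclasses.dataclass
class SubjectParameters:
    """Per-subject parameter values of one model variant.

    ``mu0_C`` / ``mu0_P`` map intensity level to prior mean and are the
    same mapping when the variant ties them; likewise ``tau0_C`` /
    ``tau0_P``.  Only the alpha fields used by the variant are set.
    """

    mu0_C: dict[int, float] | None = None
    mu0_P: dict[int, float] | None = None
    tau0_C: float | None = None
    tau0_P: float | None = None
    tau1: float | None = None
    alpha: float | None = None
    alpha_U: float | None = None
    alpha_CP: float | None = None
    alpha_P: float | None = None
    alpha_C: float | None = None
    h: float = 0.0
    mu0_U_fixed: float | None = None
    noise: float | None = None

    def to_vector(self, variant: str) -> np.ndarray:
        layout = _Layout(variant)
        vec = np.empty(layout.n)
        for k, e in enumerate(layout.entries):
            vec[k] = self._entry_value(e)
        return vec

    def _entry_value(self, e: _Entry) -> float:
        name = e.name
        if e.kind == "mu0":
            tag, lvl = name.split("_")[1], int(name.split("_")[2])
            source = self.mu0_C if tag in ("C", "S") else self.mu0_P
            if source is None:
                raise ValueError(f"{name} required but mu0 mapping missing")
            return float(source[lvl])
        if e.kind == "mu0_U":
            if self.mu0_U_fixed is None:
                raise ValueError("mu0_U_fixed required for fixed-prior variant")
            return float(self.mu0_U_fixed)
        if e.kind == "log_sd":
            val = getattr(self, name if name != "tau0" else "tau0_C")
            if val is None or val <= 0:
                raise ValueError(f"positive {name} required, got {val}")
            return float(np.log(val))
        if e.kind == "alpha":
            val = getattr(self, name)
            if val is None or not 0 <= val <= 1:
                raise ValueError(f"{name} must be in [0,1], got {val}")
            return float(val)
        return float(self.h)

    @classmethod
    def from_vector(cls, vec: np.ndarray, variant: str) -> "SubjectParameters":
        layout = _Layout(variant)
        p = cls()
        mu0_first: dict[int, float] = {}
        mu0_second: dict[int, float] = {}
        for k, e in enumerate(layout.entries):
            val = float(vec[k])
            if e.kind == "mu0":
                tag, lvl = e.name.split("_")[1], int(e.name.split("_")[2])
                (mu0_first if tag in ("C", "S") else mu0_second)[lvl] = val
            elif e.kind == "mu0_U":
                p.mu0_U_fixed = val
            elif e.kind == "log_sd":
                target = "tau0_C" if e.name == "tau0" else e.name
                setattr(p, target, float(np.exp(val)))
            else:
                setattr(p, e.name, val)
        if mu0_first:
            p.mu0_C = mu0_first
            p.mu0_P = mu0_second if mu0_second else dict(mu0_first)
        if p.tau0_C is not None and p.tau0_P is None and "tau0_P" not in layout.idx:
            p.tau0_P = p.tau0_C
        return p


# --------------------------------------------------------------------------
# designs
# --------------------------------------------------------------------------

@dataclasses.dataclass
class _SubjectDesign:
    subject_id: str
    rating: np.ndarray
    y: np.ndarray          # VAS target per trial
    t: np.ndarray          # 1-based trial index within run
    cond: np.ndarray       # 0=C 1=P 2=U
    level_idx: np.ndarray  # 0/1/2
    iC: np.ndarray
    iP: np.ndarray
    iU: np.ndarray
    lvlC: np.ndarray
    lvlP: np.ndarray
    tC: np.ndarray
    tP: np.ndarray
    WU: np.ndarray         # (n_U, 3) dynamic-prior weights
    meta: pd.DataFrame     # subject/run/trial/condition/level/rating rows used


def _dynamic_weights(levels: Sequence[int]) -> np.ndarray:
    """Remaining-count weights before each trial of one run's sequence."""
    remaining = {lvl: PER_LEVEL for lvl in LEVELS}
    out = np.zeros((len(levels), 3))
    for i, lvl in enumerate(levels):
        total = sum(remaining.values())
        out[i] = [remaining[l] / total for l in LEVELS]
        remaining[lvl] -= 1
    return out


def build_designs(data: Dataset) -> list[_SubjectDesign]:
    """Per-subject prediction designs; missing-rating trials are dropped
    from the likelihood but still count for the dynamic-prior weights."""
    designs = []
    df = data.df
    for subj in data.subjects:
        sub = df[df["subject_id"] == subj].sort_values(["run", "trial"])
        weights = np.zeros((len(sub), 3))
        pos = 0
        for _, run_df in sub.groupby("run", sort=True):
            n = len(run_df)
            if run_df["condition"].iloc[0] == "U":
                weights[pos : pos + n] = _dynamic_weights(
                    run_df["intensity_level"].tolist()
                )
            pos += n
        keep = sub["rating"].notna().to_numpy()
        sub_kept = sub[keep]
        cond = sub_kept["condition"].map(_COND_CODE).to_numpy()
        level_idx = sub_kept["intensity_level"].map(_LEVEL_INDEX).to_numpy()
        iC = np.flatnonzero(cond == 0)
        iP = np.flatnonzero(cond == 1)
        iU = np.flatnonzero(cond == 2)
        t = sub_kept["trial"].to_numpy(dtype=float)
        designs.append(
            _SubjectDesign(
                subject_id=subj,
                rating=sub_kept["rating"].to_numpy(dtype=float),
                y=sub_kept["intensity_level"].to_numpy(dtype=float),
                t=t,
                cond=cond,
                level_idx=level_idx,
                iC=iC,
                iP=iP,
                iU=iU,
                lvlC=level_idx[iC],
                lvlP=level_idx[iP],
                tC=t[iC],
                tP=t[iP],
                WU=weights[keep][cond == 2],
                meta=sub_kept.reset_index(drop=True),
            )
        )
    return designs


# --------------------------------------------------------------------------
# public single-trial / pointwise operations
# --------------------------------------------------------------------------

def _single_trial_design(trial: TrialRecord, history: Iterable[int]) -> _SubjectDesign:
    hist = list(history)
    remaining = {lvl: PER_LEVEL for lvl in LEVELS}
    for lvl in hist:
        remaining[lvl] -= 1
    total = sum(remaining.values())
    if total <= 0:
        raise ValueError("history exhausts the run")
    W = np.array([[remaining[l] / total for l in LEVELS]])
    cond = np.array([_COND_CODE[trial.condition]])
    level_idx = np.array([_LEVEL_INDEX[trial.intensity_level]])
    iC = np.flatnonzero(cond == 0)
    iP = np.flatnonzero(cond == 1)
    iU = np.flatnonzero(cond == 2)
    t = np.array([float(trial.trial)])
    return _SubjectDesign(
        subject_id=trial.subject_id,
        rating=np.array([np.nan]),
        y=np.array([float(trial.intensity_level)]),
        t=t,
        cond=cond,
        level_idx=level_idx,
        iC=iC,
        iP=iP,
        iU=iU,
        lvlC=level_idx[iC],
        lvlP=level_idx[iP],
        tC=t[iC],
        tP=t[iP],
        WU=W[cond == 2],
        meta=pd.DataFrame(),
    )


def trial_predictive_params(
    spec: ModelSpec,
    params: SubjectParameters,
    trial: TrialRecord,
    history: Iterable[int] = (),
) -> tuple[float, float]:
    """Location and SD of the truncated-normal rating distribution for one
    trial.  ``history`` lists the intensities already applied in the run
    before this trial (needed for the dynamic unpredictable prior)."""
    layout = _Layout(spec.variant)
    d = _single_trial_design(trial, history)
    mu, sd = layout.predict(params.to_vector(spec.variant), d)
    return float(mu[0]), float(sd[0])


def log_likelihood(
    data: Dataset,
    params: Mapping[str, SubjectParameters],
    spec: ModelSpec,
) -> np.ndarray:
    """Pointwise log truncated-normal density of every observed rating,
    ordered subject-major as in :func:`build_designs`."""
    layout = _Layout(spec.variant)
    out = []
    for d in build_designs(data):
        vec = params[d.subject_id].to_vector(spec.variant)
        mu, sd = layout.predict(vec, d)
        out.append(trunc_normal_logpdf(d.rating, mu, sd))
    return np.concatenate(out) if out else np.empty(0)


def hpdi(draws: Sequence[float], mass: float = 0.95) -> tuple[float, float]:
    """Highest posterior density interval of a sample.

    The narrowest contiguous window over the sorted draws containing
    ``ceil(mass * n)`` draws; ties go to the earliest window.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError(f"mass must be in (0,1), got {mass}")
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 draws")
    k = int(np.ceil(mass * n))
    k = min(max(k, 2), n)
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


# --------------------------------------------------------------------------
# hierarchical fitting
# --------------------------------------------------------------------------

_WIDTHS = {"mu0": 4.0, "mu0_U": 4.0, "log_sd": 0.35, "alpha": 0.15, "h": 0.2}

_GROUP_PRIOR_MEAN = {"m_30": 30.0, "m_50": 50.0, "m_70": 70.0, "m_U": 50.0}


@dataclasses.dataclass
class FitResult:
    """Posterior draws, pointwise log-likelihood and diagnostics."""

    spec: ModelSpec
    seed: int
    subject_ids: list[str]
    draws: dict[str, np.ndarray]       # (chains, kept) or (chains, kept, n_subjects)
    subject_vecs: np.ndarray           # (chains, kept, n_subjects, n_params) internal scale
    loglik: np.ndarray                 # (n_loglik_draws, n_trials)
    diagnostics: pd.DataFrame          # parameter, rhat, ess_bulk
    converged: bool
    trial_meta: pd.DataFrame           # one row per loglik column

    def posterior_mean(self, name: str) -> float | np.ndarray:
        arr = self.draws[name]
        if arr.ndim == 3:
            return arr.mean(axis=(0, 1))
        return float(arr.mean())

    def subject_posterior_means(self) -> pd.DataFrame:
        rows = {"subject": self.subject_ids}
        for name, arr in self.draws.items():
            if arr.ndim == 3:
                rows[name] = arr.mean(axis=(0, 1))
        return pd.DataFrame(rows)

    def group_mean(self, name: str) -> float:
        """Posterior mean of a subject-level parameter averaged over the
        cohort (the group-level value for unpooled parameters)."""
        return float(np.asarray(self.posterior_mean(name)).mean())

    def hpdi(self, name: str, mass: float = 0.95) -> tuple[float, float]:
        return hpdi(self.draws[name].reshape(-1), mass)

    def to_draws_frame(self) -> pd.DataFrame:
        """Long table: chain, iteration, parameter, value (persistable)."""
        rows = []
        for name, arr in self.draws.items():
            chains, kept = arr.shape[:2]
            if arr.ndim == 3:
                for s, subj in enumerate(self.subject_ids):
                    for c in range(chains):
                        rows.append(
                            pd.DataFrame(
                                {
                                    "chain": c,
                                    "iteration": np.arange(kept),
                                    "parameter": f"{name}[{subj}]",
                                    "value": arr[c, :, s],
                                }
                            )
                        )
            else:
                for c in range(chains):
                    rows.append(
                        pd.DataFrame(
                            {
                                "chain": c,
                                "iteration": np.arange(kept),
                                "parameter": name,
                                "value": arr[c],
                            }
                        )
                    )
        return pd.concat(rows, ignore_index=True)


def _storage_name(entry: _Entry) -> str:
    return entry.name


def _init_subject_vec(
    layout: _Layout, d: _SubjectDesign, rng: np.random.Generator
) -> np.ndarray:
    df = d.meta
    lvl_means = {}
    for tag, codes in (("C", (0,)), ("P", (1,)), ("S", (0, 1))):
        for lvl in LEVELS:
            sel = np.isin(d.cond, codes) & (d.y == lvl)
            lvl_means[(tag, lvl)] = d.rating[sel].mean() if sel.any() else float(lvl)
    cell_sds = []
    for code in (0, 1, 2):
        for lvl in LEVELS:
            sel = (d.cond == code) & (d.y == lvl)
            if sel.sum() >= 2:
                cell_sds.append(d.rating[sel].std(ddof=1))
    sd0 = float(np.clip(np.nanmean(cell_sds) if cell_sds else 8.0, 2.0, 20.0))
    vec = np.empty(layout.n)
    for k, e in enumerate(layout.entries):
        if e.kind == "mu0":
            tag, lvl = e.name.split("_")[1], int(e.name.split("_")[2])
            vec[k] = lvl_means[(tag, lvl)] + rng.normal(0, 2.0)
        elif e.kind == "mu0_U":
            vec[k] = 50.0 + rng.normal(0, 3.0)
        elif e.kind == "log_sd":
            vec[k] = np.log(sd0) + rng.normal(0, 0.15)
        elif e.kind == "alpha":
            vec[k] = float(np.clip(0.7 + rng.normal(0, 0.08), 0.02, 0.98))
        else:
            vec[k] = rng.normal(0, 0.1)
    return vec


def _run_chains(
    designs: list[_SubjectDesign],
    layout: _Layout,
    spec: ModelSpec,
    seed: int,
    mixture: bool = False,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Slice-within-Gibbs chains over the hierarchical posterior.

    With ``mixture=True`` the target is tilted by the mixture factor
    ``s(theta) = sum_i 1 / p(y_i | theta)`` used by the robust
    leave-one-out estimator; the factor depends only on subject-level
    parameters, so the conjugate group updates are unchanged.
    """
    hp = spec.hyperpriors
    nsub = len(designs)
    kept = spec.kept
    master = np.random.default_rng(seed)
    chain_seeds = master.integers(0, 2**31 - 1, size=spec.chains)

    group_keys = sorted(layout.group_cols) if layout.hierarchical else []
    store_subject = np.empty((spec.chains, kept, nsub, layout.n))
    store_group = {g: np.empty((spec.chains, kept)) for g in group_keys}
    if layout.hierarchical:
        store_group["sigma_mu0"] = np.empty((spec.chains, kept))

    prior_mu0_entry_cols = [
        k for k, e in enumerate(layout.entries) if e.kind in ("mu0", "mu0_U")
    ]
    entry_group_key = {k: layout.entries[k].group for k in prior_mu0_entry_cols}

    # joint move along the h <-> prior-mean correlation: raising h by delta
    # and every prior mean by delta * mean(t) leaves mid-run predictions
    # nearly unchanged, so this linear coordinate mixes what the
    # one-at-a-time updates cannot
    line_dir = None
    if prior_mu0_entry_cols and "h" in layout.idx:
        line_dir = np.zeros(layout.n)
        line_dir[layout.i_h] = 1.0
        mean_t = (TRIALS_PER_RUN + 1) / 2.0
        line_dir[prior_mu0_entry_cols] = mean_t

    def entry_logprior(entry: _Entry, x: float, group_state) -> float:
        kind = entry.kind
        if kind in ("mu0", "mu0_U"):
            m = group_state[entry.group]
            s = group_state["sigma_mu0"]
            return -0.5 * ((x - m) / s) ** 2 - np.log(s)
        if kind == "log_sd":
            return -0.5 * ((x - hp.log_sd_mean) / hp.log_sd_sd) ** 2
        if kind == "alpha":
            return -0.5 * ((x - hp.alpha_mean) / hp.alpha_sd) ** 2
        return -0.5 * ((x - hp.h_mean) / hp.h_sd) ** 2

    for c in range(spec.chains):
        rng = np.random.default_rng(int(chain_seeds[c]))
        vecs = np.stack([_init_subject_vec(layout, d, rng) for d in designs])
        group_state: dict[str, float] = {}
        if layout.hierarchical:
            for g in group_keys:
                cols = layout.group_cols[g]
                group_state[g] = float(vecs[:, cols].mean())
            spread = float(np.std(vecs[:, prior_mu0_entry_cols])) if nsub > 1 else 4.0
            group_state["sigma_mu0"] = float(np.clip(spread, 1.0, 10.0))

        # per-subject logsumexp of -loglik, cached for the mixture factor
        if mixture:
            neg_ll_lse = np.empty(nsub)
            for j, d in enumerate(designs):
                mu, sd = layout.predict(vecs[j], d)
                neg_ll_lse[j] = _logsumexp(-_fast_trunc_ll(d.rating, mu, sd))

        for it in range(spec.iterations):
            if layout.hierarchical:
                sig = group_state["sigma_mu0"]
                for g in group_keys:
                    cols = layout.group_cols[g]
                    vals = vecs[:, cols].ravel()
                    prior_m = _GROUP_PRIOR_MEAN[g]
                    prior_sd = hp.mu0_sd if g != "m_U" else hp.mu0_u_sd
                    prec = 1.0 / prior_sd**2 + vals.size / sig**2
                    mean = (prior_m / prior_sd**2 + vals.sum() / sig**2) / prec
                    group_state[g] = float(rng.normal(mean, np.sqrt(1.0 / prec)))
                resid = np.concatenate(
                    [
                        (vecs[:, k] - group_state[entry_group_key[k]])
                        for k in prior_mu0_entry_cols
                    ]
                )
                nres = resid.size
                ssq = float(resid @ resid)

                def sig_target(ls: float) -> float:
                    s2 = np.exp(2.0 * ls)
                    return (
                        -nres * ls
                        - 0.5 * ssq / s2
                        - 0.5
                        * ((ls - hp.log_sigma_mu0_mean) / hp.log_sigma_mu0_sd) ** 2
                    )

                new_ls = slice_sample(sig_target, float(np.log(sig)), rng, w=0.35)
                group_state["sigma_mu0"] = float(np.exp(new_ls))

            for j, d in enumerate(designs):
                vec = vecs[j]
                if mixture:
                    others = np.delete(neg_ll_lse, j)
                    lse_other = _logsumexp(others) if others.size else -np.inf

                for k, entry in enumerate(layout.entries):
                    lo, hi = (0.0, 1.0) if entry.kind == "alpha" else (-np.inf, np.inf)

                    if mixture:

                        def target(x: float, _k=k, _e=entry) -> float:
                            vec[_k] = x
                            mu, sd = layout.predict(vec, d)
                            ll_vec = _fast_trunc_ll(d.rating, mu, sd)
                            tilt = np.logaddexp(lse_other, _logsumexp(-ll_vec))
                            return (
                                ll_vec.sum()
                                + entry_logprior(_e, x, group_state)
                                + tilt
                            )

                    else:

                        def target(x: float, _k=k, _e=entry) -> float:
                            vec[_k] = x
                            mu, sd = layout.predict(vec, d)
                            return _fast_trunc_ll(d.rating, mu, sd).sum() + (
                                entry_logprior(_e, x, group_state)
                            )

                    vec[k] = slice_sample(
                        target, vec[k], rng, w=_WIDTHS[entry.kind], lo=lo, hi=hi
                    )

                if line_dir is not None:
                    base = vec.copy()

                    def line_target(delta: float) -> float:
                        cand = base + delta * line_dir
                        mu, sd = layout.predict(cand, d)
                        ll_vec = _fast_trunc_ll(d.rating, mu, sd)
                        lp = entry_logprior(
                            layout.entries[layout.i_h], cand[layout.i_h], group_state
                        )
                        for k2 in prior_mu0_entry_cols:
                            lp += entry_logprior(
                                layout.entries[k2], cand[k2], group_state
                            )
                        out = ll_vec.sum() + lp
                        if mixture:
                            out += np.logaddexp(lse_other, _logsumexp(-ll_vec))
                        return out

                    delta = slice_sample(line_target, 0.0, rng, w=0.2)
                    vec[:] = base + delta * line_dir

                if mixture:
                    mu, sd = layout.predict(vec, d)
                    neg_ll_lse[j] = _logsumexp(-_fast_trunc_ll(d.rating, mu, sd))

            if it >= spec.warmup:
                pos = it - spec.warmup
                store_subject[c, pos] = vecs
                for g in group_state:
                    store_group[g][c, pos] = group_state[g]

    return store_subject, store_group


def _logsumexp(x: np.ndarray) -> float:
    m = np.max(x)
    if not np.isfinite(m):
        return float(m)
    return float(m + np.log(np.sum(np.exp(x - m))))


def pointwise_loglik(
    designs: list[_SubjectDesign],
    layout: _Layout,
    subject_vecs: np.ndarray,
    max_draws: int | None = None,
) -> np.ndarray:
    """Draws-by-trials log-likelihood matrix from stored chain states."""
    chains, kept, nsub, _ = subject_vecs.shape
    total = chains * kept
    n_ll = total if max_draws is None else min(max_draws, total)
    sel = np.linspace(0, total - 1, n_ll).astype(int)
    flat_vecs = subject_vecs.reshape(total, nsub, layout.n)[sel]
    n_trials = sum(len(d.rating) for d in designs)
    loglik = np.empty((n_ll, n_trials))
    for s in range(n_ll):
        col = 0
        for j, d in enumerate(designs):
            mu, sd = layout.predict(flat_vecs[s, j], d)
            n = len(d.rating)
            loglik[s, col : col + n] = _fast_trunc_ll(d.rating, mu, sd)
            col += n
    return loglik


def fit_hierarchical(
    data: Dataset,
    spec: ModelSpec,
    seed: int = 0,
    n_loglik_draws: int = 2000,
) -> FitResult:
    """Fit one model variant to a trial dataset by slice-within-Gibbs MCMC.

    Subject-level prior means are partially pooled around group means with
    pooling SD sigma_mu0 (conjugate group-mean updates); all other subject
    parameters carry the group-level priors directly.  Draws after warmup
    are returned together with a pointwise log-likelihood matrix (thinned
    to at most ``n_loglik_draws`` rows) and split-R-hat / ESS diagnostics;
    the fit is flagged unconverged when any split-R-hat >= 1.01.
    """
    designs = build_designs(data)
    if not designs:
        raise ValueError("empty dataset")
    layout = _Layout(spec.variant)
    nsub = len(designs)
    kept = spec.kept
    store_subject, store_group = _run_chains(designs, layout, spec, seed)

    # natural-scale draws for reporting
    draws: dict[str, np.ndarray] = {}
    for k, e in enumerate(layout.entries):
        arr = store_subject[:, :, :, k]
        draws[e.name] = np.exp(arr) if e.kind == "log_sd" else arr.copy()
    for g, arr in store_group.items():
        draws[g] = arr

    diagnostics, converged = _diagnostics(draws, [d.subject_id for d in designs])
    if not converged:
        warnings.warn(
            f"fit of {spec.variant!r} flagged: split-R-hat >= 1.01 for "
            + ", ".join(
                diagnostics.loc[diagnostics["rhat"] >= 1.01, "parameter"]
            )
        )

    loglik = pointwise_loglik(designs, layout, store_subject, n_loglik_draws)
    trial_meta = pd.concat([d.meta for d in designs], ignore_index=True)

    return FitResult(
        spec=spec,
        seed=seed,
        subject_ids=[d.subject_id for d in designs],
        draws=draws,
        subject_vecs=store_subject,
        loglik=loglik,
        diagnostics=diagnostics,
        converged=converged,
        trial_meta=trial_meta,
    )


def _diagnostics(
    draws: dict[str, np.ndarray], subject_ids: list[str]
) -> tuple[pd.DataFrame, bool]:
    posterior = {}
    for name, arr in draws.items():
        posterior[name] = arr
    idata = az.from_dict(posterior=posterior)
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rows = []
    for name in draws:
        r = np.asarray(rhat[name]).max()
        e = np.asarray(ess[name]).min()
        rows.append({"parameter": name, "rhat": float(r), "ess_bulk": float(e)})
    table = pd.DataFrame(rows)
    converged = bool((table["rhat"] < 1.01).all())
    return table, converged


# --------------------------------------------------------------------------
# posterior prediction & recovery
# --------------------------------------------------------------------------

def posterior_predict(
    fit: FitResult,
    data: Dataset,
    seed: int = 0,
    n_draws: int = 200,
) -> pd.DataFrame:
    """Sample ratings from the posterior predictive for every trial.

    Each predictive draw picks one joint posterior draw and samples a
    rating from the trial's truncated normal.  Returns the trial metadata
    with columns ``pred_mean`` and ``pred_sd`` plus the raw draw matrix in
    ``attrs['draws']`` (n_draws x n_trials).
    """
    rng = np.random.default_rng(seed)
    layout = _Layout(fit.spec.variant)
    designs = build_designs(data)
    order = {d.subject_id: j for j, d in enumerate(designs)}
    chains, kept = fit.subject_vecs.shape[:2]
    total = chains * kept
    flat = fit.subject_vecs.reshape(total, len(fit.subject_ids), layout.n)
    sel = rng.integers(0, total, size=n_draws)
    n_trials = sum(len(d.rating) for d in designs)
    preds = np.empty((n_draws, n_trials))
    fit_order = {s: j for j, s in enumerate(fit.subject_ids)}
    for i, s in enumerate(sel):
        col = 0
        for d in designs:
            vec = flat[s, fit_order[d.subject_id]]
            mu, sd = layout.predict(vec, d)
            n = len(d.rating)
            preds[i, col : col + n] = sample_trunc_normal(mu, sd, rng=rng, size=n)
            col += n
    meta = pd.concat([d.meta for d in designs], ignore_index=True).copy()
    meta["pred_mean"] = preds.mean(axis=0)
    meta["pred_sd"] = preds.std(axis=0, ddof=1)
    meta.attrs["draws"] = preds
    return meta


@dataclasses.dataclass
class RecoveryReport:
    """Simulate-fit-recover outcome for one variant."""

    variant: str
    n_subjects: int
    threshold: float
    correlations: dict[str, float]
    true_values: pd.DataFrame
    recovered_values: pd.DataFrame
    flagged: list[str]
    converged: bool

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": list(self.correlations),
                "r": list(self.correlations.values()),
                "recovered": [
                    name not in self.flagged for name in self.correlations
                ],
            }
        )


def parameter_recovery(
    spec: ModelSpec,
    n_subjects: int = 60,
    seed: int = 0,
    threshold: float = 0.7,
    mcmc_profile: str = "recovery",
    group_params: Mapping[str, tuple[float, float]] | None = None,
) -> RecoveryReport:
    """Simulate a cohort from the variant, refit it, and correlate the
    generating subject-level parameter values with the posterior means.

    Parameters whose generating values have (near-)zero spread across
    subjects are skipped (the correlation is undefined); parameters with
    r below ``threshold`` are flagged.
    """
    from .synthetic import GeneratorConfig, ScheduleConfig, simulate_dataset

    fit_spec = ModelSpec.with_profile(
        spec.variant, mcmc_profile, hyperpriors=spec.hyperpriors
    )
    gen_cfg = GeneratorConfig(
        model=spec.variant,
        n_subjects=n_subjects,
        seed=seed,
        group_params=dict(group_params) if group_params else None,
    )
    data, true_params = simulate_dataset(gen_cfg, ScheduleConfig(seed=seed))
    fit = fit_hierarchical(data, fit_spec, seed=seed + 1)

    layout = _Layout(spec.variant)
    true_rows = {
        subj: p.to_vector(spec.variant) for subj, p in true_params.items()
    }
    true_df = pd.DataFrame(
        [true_rows[s] for s in fit.subject_ids],
        columns=layout.names,
        index=fit.subject_ids,
    )
    # natural scale for SD-type entries
    for k, e in enumerate(layout.entries):
        if e.kind == "log_sd":
            true_df[e.name] = np.exp(true_df[e.name])
    rec_df = fit.subject_posterior_means().set_index("subject")[layout.names]

    correlations: dict[str, float] = {}
    flagged: list[str] = []
    for name in layout.names:
        tv = true_df[name].to_numpy()
        rv = rec_df[name].to_numpy()
        if np.std(tv) < 1e-8:
            continue
        r = float(np.corrcoef(tv, rv)[0, 1])
        correlations[name] = r
        if not np.isfinite(r) or r < threshold:
            flagged.append(name)
    return RecoveryReport(
        variant=spec.variant,
        n_subjects=n_subjects,
        threshold=threshold,
        correlations=correlations,
        true_values=true_df,
        recovered_values=rec_df,
        flagged=flagged,
        converged=fit.converged,
    )
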
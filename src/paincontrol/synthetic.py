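"""Synthetic cohorts for the three-condition heat-pain rating task.

Generates everything the downstream analyses need without any external
data: choice-driven controllable stimulus schedules (with the early-high /
late-low preference and the mid-run peak for the medium level), predictable
and unpredictable schedules matched to them (yoked copies or
probability-matched draws under the 5-per-level cap), subject-level model
parameters drawn from the group-level distributions of the study design,
ratings drawn through the exact trial-level predictive distributions of the
model variants, and a simulation-based power analysis for the
condition-by-intensity rating effect.

The rating generator and the model likelihood share one code path
(`models._Layout.predict`), so data simulated from a variant are by
construction distributed as that variant's likelihood assumes.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import models as _models
from .bayes_core import sample_trunc_normal
from .trial_data import COLUMNS, Dataset, LEVELS, PER_LEVEL, TRIALS_PER_RUN

__all__ = [
    "ScheduleConfig",
    "GeneratorConfig",
    "generate_controllable_sequence",
    "generate_matched_sequences",
    "sample_group_parameters",
    "simulate_dataset",
    "simulate_power",
]

#: mean/SD of the condition reaction-time toy model (seconds); the choice
#: task is slower than the two color-matching tasks.
_RT_PARAMS = {"C": (1.72, 0.66), "P": (1.09, 0.47), "U": (1.02, 0.45)}


@dataclasses.dataclass(frozen=True)
class ScheduleConfig:
    """How stimulus sequences are built.

    ``choice_bias`` scales the softmax utilities of the controllable-choice
    model (0 = uniform over feasible levels); ``method`` fixes how the
    predictable/unpredictable sequences are matched to the controllable
    ones (``yoked`` copies a donor sequence verbatim, the study's final
    approach; ``probability_matched`` samples from donor per-trial
    frequencies under the 5-per-level cap; ``free_random`` shuffles).
    """

    n_trials_per_run: int = TRIALS_PER_RUN
    n_per_level: int = PER_LEVEL
    method: str = "yoked"
    choice_bias: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_level * len(LEVELS) != self.n_trials_per_run:
            raise ValueError("need n_per_level * 3 == n_trials_per_run")
        if self.method not in ("free_random", "probability_matched", "yoked"):
            raise ValueError(f"unknown matching method {self.method!r}")
        if self.choice_bias < 0:
            raise ValueError("choice_bias must be >= 0")


@dataclasses.dataclass(frozen=True)
class GeneratorConfig:
    """Which model variant generates ratings, for how many subjects.

    ``group_params`` overrides the group-level generating distributions;
    scalar values fix a parameter for every subject, pairs are
    (mean, SD) — for SD-type parameters (median, log-scale SD).
    """

    model: str
    n_subjects: int
    seed: int = 0
    group_params: Mapping[str, float | tuple[float, float]] | None = None
    timeout_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in _models.VARIANTS:
            raise ValueError(f"unknown model variant {self.model!r}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.0 <= self.timeout_rate < 1.0:
            raise ValueError("timeout_rate must be in [0, 1)")


# --------------------------------------------------------------------------
# schedules
# --------------------------------------------------------------------------

def _choice_utilities(t: int, n_trials: int) -> dict[int, float]:
    # normalized trial position in [-1, 1]
    x = (t - (n_trials + 1) / 2.0) / ((n_trials - 1) / 2.0)
    return {30: x, 50: 0.5 - abs(x), 70: -x}


def generate_controllable_sequence(
    cfg: ScheduleConfig, rng: np.random.Generator | None = None
) -> list[int]:
    """One self-chosen 15-trial intensity sequence.

    Choices follow a softmax over the levels that still have stimuli left,
    with trial-dependent utilities: the high level is preferred early, the
    low level late, the medium level mid-run — scaled by ``choice_bias``.
    Every sequence contains exactly 5 stimuli of each level.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    remaining = {lvl: cfg.n_per_level for lvl in LEVELS}
    seq: list[int] = []
    for t in range(1, cfg.n_trials_per_run + 1):
        feasible = [lvl for lvl in LEVELS if remaining[lvl] > 0]
        util = _choice_utilities(t, cfg.n_trials_per_run)
        logits = np.array([cfg.choice_bias * util[lvl] for lvl in feasible])
        p = np.exp(logits - logits.max())
        p /= p.sum()
        lvl = int(rng.choice(feasible, p=p))
        seq.append(lvl)
        remaining[lvl] -= 1
    return seq


def _sequence_frequencies(sequences: Sequence[Sequence[int]]) -> np.ndarray:
    freq = np.zeros((TRIALS_PER_RUN, len(LEVELS)))
    for seq in sequences:
        for t, lvl in enumerate(seq):
            freq[t, LEVELS.index(lvl)] += 1
    return freq / len(sequences)


def generate_matched_sequences(
    donor,
    method: str = "yoked",
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> dict[str, list[int]]:
    """Predictable and unpredictable sequences matched to controllable ones.

    ``donor`` is either one controllable sequence (for ``yoked``, returned
    verbatim for both conditions) or a (15, 3) per-trial frequency matrix
    (for ``probability_matched``: per-trial draws from those frequencies,
    renormalized over levels that still have occurrences left).
    ``free_random`` ignores the donor and shuffles a balanced multiset.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    if method == "yoked":
        seq = [int(v) for v in donor]
        _check_balanced(seq)
        return {"P": list(seq), "U": list(seq)}
    if method == "free_random":
        base = [lvl for lvl in LEVELS for _ in range(PER_LEVEL)]
        out = {}
        for cond in ("P", "U"):
            seq = list(rng.permutation(base))
            out[cond] = [int(v) for v in seq]
        return out
    if method != "probability_matched":
        raise ValueError(f"unknown matching method {method!r}")
    freq = np.asarray(donor, dtype=float)
    if freq.ndim != 2 or freq.shape != (TRIALS_PER_RUN, len(LEVELS)):
        # allow a list of donor sequences as convenience input
        freq = _sequence_frequencies(donor)
    if not np.allclose(freq.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("per-trial frequencies must sum to 1")
    out = {}
    for cond in ("P", "U"):
        remaining = np.full(len(LEVELS), PER_LEVEL, dtype=float)
        seq = []
        for t in range(TRIALS_PER_RUN):
            p = freq[t] * (remaining > 0)
            if p.sum() <= 0:
                p = (remaining > 0).astype(float)
            p = p / p.sum()
            k = int(rng.choice(len(LEVELS), p=p))
            seq.append(LEVELS[k])
            remaining[k] -= 1
        _check_balanced(seq)
        out[cond] = seq
    return out


def _check_balanced(seq: Sequence[int]) -> None:
    counts = {lvl: 0 for lvl in LEVELS}
    for lvl in seq:
        counts[int(lvl)] += 1
    if any(counts[lvl] != PER_LEVEL for lvl in LEVELS):
        raise ValueError(f"sequence violates 5-per-level constraint: {counts}")


# --------------------------------------------------------------------------
# subject parameters
# --------------------------------------------------------------------------

_SD_MEDIAN = float(np.exp(1.5))  # median of the log-normal SD-type priors


def sample_group_parameters(
    spec: "_models.ModelSpec | str",
    n_subjects: int,
    seed: int = 0,
    group_params: Mapping[str, float | tuple[float, float]] | None = None,
    subject_ids: Sequence[str] | None = None,
) -> dict[str, "_models.SubjectParameters"]:
    """Draw per-subject parameters from the group-level distributions.

    Defaults follow the study's group-level design: prior means per level
    around the VAS targets with spread sigma_mu0 (median of its log-normal
    prior), SD-type parameters log-normal with log-mean 1.5 and log-SD 0.5,
    alpha from a [0,1]-truncated normal(0.5, 0.3), h from normal(0, 1).
    ``group_params`` overrides per parameter name; a scalar fixes the value
    for every subject (so recovery runs can pin group values).
    """
    variant = spec.variant if isinstance(spec, _models.ModelSpec) else spec
    layout = _models._Layout(variant)
    rng = np.random.default_rng(seed)
    over = dict(group_params or {})
    sigma_mu0 = float(over.pop("sigma_mu0", _SD_MEDIAN))
    if subject_ids is None:
        subject_ids = [f"sub{j + 1:03d}" for j in range(n_subjects)]

    def draw(name: str, kind: str, center: float) -> np.ndarray:
        spec_over = over.get(name)
        if np.isscalar(spec_over):
            # fixed natural-scale value for every subject; the internal
            # vector keeps SD-type entries on the log scale
            val = float(spec_over)
            if kind == "log_sd":
                if val <= 0:
                    raise ValueError(f"{name} must be positive, got {val}")
                val = float(np.log(val))
            return np.full(n_subjects, val)
        if kind == "mu0" or kind == "mu0_U":
            m, s = spec_over if spec_over else (center, sigma_mu0)
            return rng.normal(m, s, size=n_subjects)
        if kind == "log_sd":
            m, s = spec_over if spec_over else (_SD_MEDIAN, 0.5)
            return np.log(m) + rng.normal(0.0, s, size=n_subjects)
        if kind == "alpha":
            m, s = spec_over if spec_over else (0.5, 0.3)
            return np.asarray(
                sample_trunc_normal(
                    np.full(n_subjects, m), np.full(n_subjects, s),
                    lo=0.0, hi=1.0, rng=rng, size=n_subjects,
                )
            )
        m, s = spec_over if spec_over else (0.0, 1.0)
        return rng.normal(m, s, size=n_subjects)

    columns = {}
    for e in layout.entries:
        if e.kind == "mu0":
            center = float(e.name.split("_")[2])
        elif e.kind == "mu0_U":
            center = 50.0
        else:
            center = 0.0
        columns[e.name] = draw(e.name, e.kind, center)

    out = {}
    for j, subj in enumerate(subject_ids):
        vec = np.array([columns[e.name][j] for e in layout.entries])
        out[subj] = _models.SubjectParameters.from_vector(vec, variant)
    return out


# --------------------------------------------------------------------------
# full datasets
# --------------------------------------------------------------------------

def _condition_order(rng: np.random.Generator) -> list[str]:
    # each condition once per experiment half, order pseudo-randomized
    half1 = list(rng.permutation(["C", "P", "U"]))
    half2 = list(rng.permutation(["C", "P", "U"]))
    return half1 + half2


def simulate_dataset(
    cfg: GeneratorConfig,
    schedules: ScheduleConfig | None = None,
) -> tuple[Dataset, dict[str, "_models.SubjectParameters"]]:
    """Simulate a full cohort: schedules, choices, ratings, reaction times.

    For every subject, two controllable runs are built from the choice
    model, and matched predictable/unpredictable runs per the schedule
    method; each rating is then drawn from the model variant's trial-level
    truncated normal.  Returns the Dataset plus the generating parameters
    (for recovery scoring).  Fully reproducible from ``cfg.seed``.
    """
    schedules = schedules or ScheduleConfig(seed=cfg.seed)
    params = sample_group_parameters(
        cfg.model, cfg.n_subjects, seed=cfg.seed, group_params=cfg.group_params
    )
    layout = _models._Layout(cfg.model)
    ss = np.random.SeedSequence(cfg.seed)
    subject_rngs = [np.random.default_rng(s) for s in ss.spawn(cfg.n_subjects)]

    rows = []
    for j, (subj, p) in enumerate(params.items()):
        rng = subject_rngs[j]
        order = _condition_order(rng)
        # first build the controllable sequences, then match the others
        c_seqs = [
            generate_controllable_sequence(schedules, rng=rng)
            for cond in order
            if cond == "C"
        ]
        session_count = {"C": 0, "P": 0, "U": 0}
        matched_pool: dict[str, list[list[int]]] = {"P": [], "U": []}
        if schedules.method == "yoked":
            for seq in c_seqs:
                m = generate_matched_sequences(seq, "yoked", rng=rng)
                matched_pool["P"].append(m["P"])
                matched_pool["U"].append(m["U"])
        elif schedules.method == "probability_matched":
            freq = _sequence_frequencies(c_seqs)
            for _ in c_seqs:
                m = generate_matched_sequences(freq, "probability_matched", rng=rng)
                matched_pool["P"].append(m["P"])
                matched_pool["U"].append(m["U"])
        else:
            for _ in c_seqs:
                m = generate_matched_sequences(None, "free_random", rng=rng)
                matched_pool["P"].append(m["P"])
                matched_pool["U"].append(m["U"])

        c_iter = iter(c_seqs)
        for run_no, cond in enumerate(order, start=1):
            session_count[cond] += 1
            if cond == "C":
                seq = next(c_iter)
            else:
                seq = matched_pool[cond][session_count[cond] - 1]
            for t, lvl in enumerate(seq, start=1):
                rt_m, rt_s = _RT_PARAMS[cond]
                rt = float(sample_trunc_normal(rt_m, rt_s, lo=0.2, hi=8.0, rng=rng))
                rows.append(
                    {
                        "subject_id": subj,
                        "session": session_count[cond],
                        "run": run_no,
                        "trial": t,
                        "condition": cond,
                        "intensity_level": lvl,
                        "rating": 0.0,  # placeholder, filled below
                        "reaction_time": rt,
                        "chosen": cond == "C",
                    }
                )

    df = pd.DataFrame(rows, columns=list(COLUMNS))
    data = Dataset(df=df, provenance=f"synthetic model={cfg.model} seed={cfg.seed}")

    # draw ratings through the shared predictive code path
    designs = _models.build_designs(data)
    rating_rng = np.random.default_rng(ss.spawn(1)[0])
    filled = []
    for d in designs:
        vec = params[d.subject_id].to_vector(cfg.model)
        mu, sd = layout.predict(vec, d)
        ratings = sample_trunc_normal(mu, sd, rng=rating_rng, size=len(mu))
        meta = d.meta.copy()
        meta["rating"] = ratings
        filled.append(meta)
    df = pd.concat(filled, ignore_index=True)

    if cfg.timeout_rate > 0:
        timeout = rating_rng.uniform(size=len(df)) < cfg.timeout_rate
        df.loc[timeout, ["rating", "reaction_time"]] = np.nan

    data = Dataset(df=df, provenance=f"synthetic model={cfg.model} seed={cfg.seed}")
    data.validate(strict=True)
    return data, params


# --------------------------------------------------------------------------
# power analysis
# --------------------------------------------------------------------------

def _simulate_lmm_cohort(
    n_subjects: int, effect: float, rng: np.random.Generator
) -> Dataset:
    """Rating generator with a built-in condition-by-intensity interaction.

    Linear in intensity with condition-specific slope offsets of +/-
    ``effect``/2 for C and U around P, a subject random intercept, and
    residual noise at the scale of the observed rating SDs; ratings drawn
    on the truncated VAS.
    """
    cfg = GeneratorConfig(model="null_hab", n_subjects=n_subjects, seed=int(rng.integers(2**31)))
    sched = ScheduleConfig(seed=cfg.seed)
    data, _ = simulate_dataset(cfg, sched)
    df = data.df.copy()
    u = {s: rng.normal(0.0, 6.0) for s in data.subjects}
    slope_offset = {"C": effect / 2.0, "P": 0.0, "U": -effect / 2.0}
    x = df["intensity_level"].to_numpy(dtype=float)
    mean = (
        -15.0
        + 1.3 * x
        + np.array([slope_offset[c] for c in df["condition"]]) * (x - 50.0)
        + np.array([u[s] for s in df["subject_id"]])
    )
    df["rating"] = sample_trunc_normal(
        mean, np.full_like(mean, 12.0), rng=rng, size=len(mean)
    )
    return Dataset(df=df, provenance=f"lmm-power effect={effect}")


def simulate_power(
    n_grid: Sequence[int],
    effect: float,
    reps: int = 20,
    seed: int = 0,
    mcmc: tuple[int, int, int] = (2, 800, 300),
) -> pd.DataFrame:
    """Power of the rating mixed model to detect the C-vs-U interaction.

    For each sample size, simulates ``reps`` cohorts with the given
    condition-by-intensity interaction magnitude, fits the Bayesian rating
    LMM, and reports the fraction of replicates whose 95% HPDI for the
    C-by-U interaction excludes zero.
    """
    from .descriptive import LmmSpec, fit_rating_lmm

    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    chains, iterations, warmup = mcmc
    rows = []
    for n in n_grid:
        hits = 0
        for _ in range(reps):
            data = _simulate_lmm_cohort(n, effect, rng)
            res = fit_rating_lmm(
                data,
                LmmSpec(baseline="U"),
                seed=int(rng.integers(2**31)),
                chains=chains,
                iterations=iterations,
                warmup=warmup,
            )
            row = res.loc[res["term"] == "C:intensity"]
            lo, hi = float(row["hpdi_lo"].iloc[0]), float(row["hpdi_hi"].iloc[0])
            if lo > 0 or hi < 0:
                hits += 1
        rows.append({"n": int(n), "power": hits / reps})
    return pd.DataFrame(rows)
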
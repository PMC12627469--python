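"""Long-format trial tables for the three-condition heat-pain rating task.

One row per trial.  Conditions: C (controllable, self-chosen intensity),
P (predictable, cued computer-chosen intensity), U (unpredictable, uncued).
Each run holds 15 trials with exactly 5 stimuli per intensity level
(VAS targets 30 / 50 / 70); each condition is run twice, giving 6 runs and
90 trials per subject.  Ratings live on the 0-100 VAS; timeouts are missing.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "CONDITIONS",
    "LEVELS",
    "TRIALS_PER_RUN",
    "PER_LEVEL",
    "TrialRecord",
    "Dataset",
    "ValidationError",
    "read_trials",
    "write_trials",
    "within_subject_sd_table",
    "choice_percentages",
    "rt_summary",
]

#: fixed column order of the on-disk TSV
COLUMNS = (
    "subject_id",
    "session",
    "run",
    "trial",
    "condition",
    "intensity_level",
    "rating",
    "reaction_time",
    "chosen",
)

CONDITIONS = ("C", "P", "U")
LEVELS = (30, 50, 70)
TRIALS_PER_RUN = 15
PER_LEVEL = 5
MISSING_TOKEN = "NA"


class ValidationError(ValueError):
    """A trial table violates the task structure."""


@dataclasses.dataclass(frozen=True)
class TrialRecord:
    """One behavioral trial.

    ``session`` is the per-condition repetition (1st or 2nd run of that
    condition), ``trial`` the 1-based position within the run.  ``rating``
    and ``reaction_time`` are None on timeout; ``chosen`` is True only in
    the controllable condition where the subject picked the level.
    """

    subject_id: str
    session: int
    run: int
    trial: int
    condition: str
    intensity_level: int
    rating: float | None
    reaction_time: float | None
    chosen: bool

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.intensity_level not in LEVELS:
            raise ValidationError(f"unknown intensity level {self.intensity_level}")
        if not 1 <= self.trial <= TRIALS_PER_RUN:
            raise ValidationError(f"trial {self.trial} outside 1..{TRIALS_PER_RUN}")
        if self.rating is not None and not 0.0 <= self.rating <= 100.0:
            raise ValidationError(f"rating out of [0,100]: {self.rating}")
        if self.reaction_time is not None and self.reaction_time < 0:
            raise ValidationError(f"negative reaction time {self.reaction_time}")


@dataclasses.dataclass
class Dataset:
    """Ordered collection of trials as a typed DataFrame plus provenance."""

    df: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"missing columns: {missing}")
        df = self.df.loc[:, list(COLUMNS)].reset_index(drop=True)
        df = df.astype(
            {
                "subject_id": str,
                "session": np.int64,
                "run": np.int64,
                "trial": np.int64,
                "condition": str,
                "intensity_level": np.int64,
                "rating": float,
                "reaction_time": float,
                "chosen": bool,
            }
        )
        self.df = df

    # -- basic protocol ----------------------------------------------------
    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.df["subject_id"]))

    @property
    def records(self) -> list[TrialRecord]:
        out = []
        for row in self.df.itertuples(index=False):
            out.append(
                TrialRecord(
                    subject_id=row.subject_id,
                    session=int(row.session),
                    run=int(row.run),
                    trial=int(row.trial),
                    condition=row.condition,
                    intensity_level=int(row.intensity_level),
                    rating=None if pd.isna(row.rating) else float(row.rating),
                    reaction_time=(
                        None if pd.isna(row.reaction_time) else float(row.reaction_time)
                    ),
                    chosen=bool(row.chosen),
                )
            )
        return out

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(self.df, other.df, check_exact=False)
        except AssertionError:
            return False
        return True

    @classmethod
    def from_records(cls, records: Iterable[TrialRecord], provenance: str = "") -> "Dataset":
        rows = [dataclasses.asdict(r) for r in records]
        df = pd.DataFrame(rows, columns=list(COLUMNS))
        if df.empty:
            df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in _EMPTY_DTYPES.items()})
        return cls(df=df, provenance=provenance)

    def validate(self, strict: bool = True) -> list[str]:
        """Check task-structure invariants; return the list of breaches.

        With ``strict=True`` any breach raises :class:`ValidationError`.
        Row-level bounds (rating range, known condition/level labels) are
        always enforced; the run/subject structure may be relaxed for
        partial data, in which case a warning is emitted.
        """
        df = self.df
        breaches: list[str] = []
        bad = df["rating"].dropna()
        bad = bad[(bad < 0) | (bad > 100)]
        for idx, val in bad.items():
            raise ValidationError(f"rating out of [0,100] at row {idx}: {val}")
        unknown = set(df["condition"]) - set(CONDITIONS)
        if unknown:
            raise ValidationError(f"unknown conditions {sorted(unknown)}")
        unknown_lvl = set(df["intensity_level"]) - set(LEVELS)
        if unknown_lvl:
            raise ValidationError(f"unknown intensity levels {sorted(unknown_lvl)}")
        if ((df["trial"] < 1) | (df["trial"] > TRIALS_PER_RUN)).any():
            raise ValidationError(f"trial index outside 1..{TRIALS_PER_RUN}")

        for (subj, run), grp in df.groupby(["subject_id", "run"], sort=False):
            if grp["condition"].nunique() > 1:
                breaches.append(f"{subj} run {run}: condition not constant within run")
            counts = grp["intensity_level"].value_counts()
            if len(grp) == TRIALS_PER_RUN and any(
                counts.get(lvl, 0) != PER_LEVEL for lvl in LEVELS
            ):
                breaches.append(
                    f"{subj} run {run}: levels {dict(counts)} != 5 per level"
                )
        for subj, grp in df.groupby("subject_id", sort=False):
            n_runs = grp["run"].nunique()
            cond_runs = grp.groupby("condition")["run"].nunique()
            if n_runs != 6 or len(grp) != 90 or any(
                cond_runs.get(c, 0) != 2 for c in CONDITIONS
            ):
                breaches.append(
                    f"{subj}: expected 6 runs (2 per condition, 90 trials), "
                    f"got {n_runs} runs / {len(grp)} trials"
                )
        if breaches:
            if strict:
                raise ValidationError("; ".join(breaches))
            warnings.warn("partial/irregular dataset: " + "; ".join(breaches))
        return breaches


_EMPTY_DTYPES = {
    "subject_id": str,
    "session": np.int64,
    "run": np.int64,
    "trial": np.int64,
    "condition": str,
    "intensity_level": np.int64,
    "rating": float,
    "reaction_time": float,
    "chosen": bool,
}


def read_trials(path: str | Path, strict: bool = False) -> Dataset:
    """Read a long-format tab-separated trial table.

    Missing ratings / reaction times are encoded as ``NA`` and preserved as
    missing.  Malformed rows raise a parse error naming the line; with
    ``strict=True`` structural invariants are enforced as well.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            na_values=[MISSING_TOKEN],
            keep_default_na=False,
            dtype={"subject_id": str, "condition": str},
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if df.empty:
        df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in _EMPTY_DTYPES.items()})
    for col in ("session", "run", "trial", "intensity_level"):
        try:
            df[col] = df[col].astype(np.int64)
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise ValidationError(f"{path} line {line}: bad integer in {col!r}") from exc
    for col in ("rating", "reaction_time"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            line = int(df.index[bad][0]) + 2 if bad.any() else "?"
            raise ValidationError(f"{path} line {line}: bad number in {col!r}") from exc
    df["chosen"] = df["chosen"].map(
        {True: True, False: False, "True": True, "False": False, 1: True, 0: False}
    )
    if df["chosen"].isna().any():
        raise ValidationError(f"{path}: unparseable 'chosen' entries")
    data = Dataset(df=df, provenance=str(path))
    data.validate(strict=strict)
    return data


def write_trials(data: Dataset, path: str | Path) -> None:
    """Write the fixed-column-order TSV with ``NA`` as the missing token."""
    df = data.df.loc[:, list(COLUMNS)]
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN)


def within_subject_sd_table(data: Dataset) -> pd.DataFrame:
    """Sample SD of ratings per subject x condition x intensity cell.

    Uses the n-1 denominator over non-missing ratings (nominally 10 per
    cell: 5 per level x 2 runs of the condition); cells with fewer than two
    ratings get a missing SD.  Columns: subject, condition, intensity_level,
    sd, n.
    """
    df = data.df
    grouped = df.groupby(["subject_id", "condition", "intensity_level"], sort=True)[
        "rating"
    ]
    out = grouped.agg(sd="std", n="count").reset_index()
    out.loc[out["n"] < 2, "sd"] = np.nan
    return out.rename(columns={"subject_id": "subject"})


def choice_percentages(data: Dataset) -> pd.DataFrame:
    """Percent of controllable-condition choices per trial position and level.

    For each trial position 1..15 the percents across the three levels sum
    to 100 (of all condition-C chosen trials at that position).  Returns an
    empty table when no such trials exist.
    """
    df = data.df
    chosen = df[(df["condition"] == "C") & df["chosen"]]
    if chosen.empty:
        return pd.DataFrame(columns=["trial", "intensity_level", "percent"])
    counts = (
        chosen.groupby(["trial", "intensity_level"]).size().rename("count").reset_index()
    )
    full = pd.MultiIndex.from_product(
        [range(1, TRIALS_PER_RUN + 1), LEVELS], names=["trial", "intensity_level"]
    )
    counts = counts.set_index(["trial", "intensity_level"]).reindex(full, fill_value=0)
    totals = counts.groupby(level="trial")["count"].transform("sum")
    counts["percent"] = np.where(totals > 0, 100.0 * counts["count"] / totals, np.nan)
    return counts.reset_index().drop(columns="count")


def rt_summary(data: Dataset) -> pd.DataFrame:
    """Mean and SD of non-missing reaction times per condition."""
    out = (
        data.df.groupby("condition")["reaction_time"]
        .agg(mean_rt="mean", sd_rt="std")
        .reset_index()
    )
    return out
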
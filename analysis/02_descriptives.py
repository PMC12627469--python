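#!/usr/bin/env python
"""Descriptive summaries of the simulated cohort.

Reproduces the descriptive layer of the behavioral analysis: condition by
intensity rating means with within-subject-corrected SEMs, within-subject
rating SDs per cell, reaction-time means per condition, and the percentage
of self-chosen intensities per trial position.
"""

import argparse
from pathlib import Path

from paincontrol.descriptive import within_subject_sem
from paincontrol.trial_data import (
    choice_percentages,
    read_trials,
    rt_summary,
    within_subject_sd_table,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--trials", type=Path, default=Path("results/trials.tsv"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    data = read_trials(args.trials, strict=True)

    cell = data.df.pivot_table(
        index="subject_id", columns=["condition", "intensity_level"], values="rating"
    )
    means = cell.mean().rename("mean_rating").reset_index()
    means["sem_corrected"] = within_subject_sem(cell).to_numpy()
    means.to_csv(args.out / "rating_means.tsv", sep="\t", index=False)

    sd_tab = within_subject_sd_table(data)
    sd_tab.to_csv(args.out / "within_subject_sds.tsv", sep="\t", index=False)
    rt = rt_summary(data)
    rt.to_csv(args.out / "rt_summary.tsv", sep="\t", index=False)
    cp = choice_percentages(data)
    cp.to_csv(args.out / "choice_percentages.tsv", sep="\t", index=False)

    by_cond = sd_tab.groupby("condition")["sd"].mean()
    print("mean rating per condition x intensity:")
    print(means.pivot_table(index="condition", columns="intensity_level",
                            values="mean_rating").round(1).to_string())
    print("\nmean within-subject SD per condition (expect C < P):")
    print(by_cond.round(2).to_string())
    print("\nmean RT per condition (expect C slowest):")
    print(rt.round(2).to_string(index=False))


if __name__ == "__main__":
    main()
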
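#!/usr/bin/env python
"""Bayesian regressions of choice frequency on trial position.

For each intensity level, regresses the group-level percentage of chosen
stimuli on the trial position (flat priors, exact conjugate posterior).
The high level should fall over the run and the low level rise; the medium
level shows an inverted U, so a quadratic model should earn a higher
leave-one-out ELPD than the linear one.
"""

import argparse
from pathlib import Path

import pandas as pd

from paincontrol.descriptive import fit_choice_freq
from paincontrol.trial_data import read_trials, choice_percentages


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--trials", type=Path, default=Path("results/trials.tsv"))
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    data = read_trials(args.trials, strict=True)
    table = choice_percentages(data)

    rows = []
    for level in (30, 50, 70):
        for degree in (1, 2) if level == 50 else (1,):
            res = fit_choice_freq(table, level, degree=degree, seed=args.seed)
            for _, r in res.summary.iterrows():
                rows.append(
                    {
                        "level": level,
                        "degree": degree,
                        "term": r["term"],
                        "mean": r["mean"],
                        "hpdi_lo": r["hpdi_lo"],
                        "hpdi_hi": r["hpdi_hi"],
                        "elpd": res.elpd.elpd_total,
                    }
                )
    out = pd.DataFrame(rows)
    out.to_csv(args.out / "choice_models.tsv", sep="\t", index=False)

    slopes = out[(out.term == "slope") & (out.degree == 1)].set_index("level")
    print("linear slopes of choice percentage over trials:")
    print(slopes[["mean", "hpdi_lo", "hpdi_hi"]].round(2).to_string())
    med = out[out.level == 50].groupby("degree")["elpd"].first()
    print(
        f"\nmedium level: ELPD linear {med[1]:.1f} vs quadratic {med[2]:.1f} "
        f"({'quadratic preferred' if med[2] > med[1] else 'linear preferred'})"
    )


if __name__ == "__main__":
    main()
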
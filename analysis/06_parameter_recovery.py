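#!/usr/bin/env python
"""Simulate-fit-recover check of the integration models.

Simulates a cohort from a variant with subject-level parameter spread,
refits it at the recovery MCMC profile, and correlates generating with
recovered (posterior-mean) values per parameter.  The mean-shift and
precision-change parameters should all be recoverable; in the three-alpha
variant the predictable-condition weight is not identifiable (the cue makes
prior and input coincide, so shrinkage has nothing to act on), which is the
reason the leaner single-alpha models are the ones compared.
"""

import argparse
from pathlib import Path

import pandas as pd

from paincontrol.models import ModelSpec, parameter_recovery


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-subjects", type=int, default=12)
    parser.add_argument(
        "--variants", nargs="+",
        default=["precision_change_dynamic", "mean_shift_dynamic"],
    )
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    frames = []
    for variant in args.variants:
        spec = ModelSpec.with_profile(variant, "recovery")
        rep = parameter_recovery(
            spec, n_subjects=args.n_subjects, seed=args.seed,
            mcmc_profile="recovery",
        )
        tab = rep.summary()
        tab.insert(0, "variant", variant)
        frames.append(tab)
        flagged = ", ".join(rep.flagged) if rep.flagged else "none"
        print(f"{variant}: parameters below r=0.7: {flagged}")
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(args.out / "parameter_recovery.tsv", sep="\t", index=False)
    print(out.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
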
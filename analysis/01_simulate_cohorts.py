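#!/usr/bin/env python
"""Simulate the three study cohorts and write their raw gaze + design tables.

Generates webcam-style gaze recordings for an adult group (36 subjects), a
typically developing child group (21) and a Down-syndrome-profile group (21),
using each group's default time-course parameters (adults and TD anticipate
in CV and MV; the DS profile anticipates in CV only, ~200 ms later).  Raw
gaze logs are large and go to scratch/; design tables go to results/.
"""

import argparse
from pathlib import Path

from preflook.design import write_gaze_table
from preflook.simulate import generate_cohort

GROUPS = {"adult": 36, "TD": 21, "DS": 21}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--scratch", type=Path, default=Path("scratch"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.scratch.mkdir(parents=True, exist_ok=True)
    args.results.mkdir(parents=True, exist_ok=True)

    for group, n in GROUPS.items():
        trials, design = generate_cohort(n, group, seed=args.seed)
        gaze_path = args.scratch / f"gaze_{group}.csv"
        design_path = args.results / f"design_{group}.csv"
        write_gaze_table(gaze_path, trials)
        design.to_csv(design_path, index=False)
        print(
            f"{group}: {n} subjects, {len(design)} trials -> "
            f"{gaze_path.name}, {design_path.name}"
        )


if __name__ == "__main__":
    main()
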
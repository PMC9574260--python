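#!/usr/bin/env python
"""Cluster-mass permutation tests of the fixation time courses per cohort.

For each group, paired contrasts (CV vs UV, MV vs UV) and one-sample tests
against chance (0.5) per condition over 0-6000 ms relative to picture onset,
with 100,000 permutations and the group's critical t (df = n - 1).  Writes a
cluster report CSV per group in the (start, end, mass, t_max, p) format.
"""

import argparse
from pathlib import Path

import pandas as pd

from preflook.cluster import (
    cluster_report,
    critical_t_for,
    permutation_test,
    subject_condition_curves,
)
from preflook.design import read_bins

GROUPS = ("adult", "TD", "DS")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-perm", type=int, default=100_000)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    for group in GROUPS:
        bins = read_bins(args.results / f"bins_{group}.csv")
        curves, subjects, starts = subject_condition_curves(bins)
        crit = critical_t_for(len(subjects))
        reports = []
        for cond in ("CV", "MV"):
            cl = permutation_test(
                curves[cond], curves["UV"], contrast="paired", n_perm=args.n_perm,
                critical_t=crit, seed=args.seed, t_start=starts,
            )
            reports.append(cluster_report(cl, group=group, contrast=f"{cond}-UV"))
        for cond in ("CV", "MV", "UV"):
            cl = permutation_test(
                curves[cond], contrast="one_sample", mu=0.5, n_perm=args.n_perm,
                critical_t=crit, seed=args.seed, t_start=starts,
            )
            reports.append(cluster_report(cl, group=group, contrast=f"{cond}-chance"))
        out = pd.concat(reports, ignore_index=True)
        out.to_csv(args.results / f"clusters_{group}.csv", index=False)
        sig = out[out["p"] < 0.05]
        print(f"\n{group} (critical t = {crit:.3f}, {len(subjects)} subjects): "
              f"{len(sig)} significant clusters")
        if not sig.empty:
            print(sig.to_string(index=False, float_format=lambda v: f"{v: .3f}"))


if __name__ == "__main__":
    main()
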
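#!/usr/bin/env python
"""Stimulus-norming statistics on the packaged association-strength table.

Kruskal-Wallis across the three sentence conditions' verb-target association
strengths, Mann-Whitney post-hoc contrasts (continuity + tie correction),
and the same tests on the verb-distractor strengths, which should show no
condition differences in a well-constructed stimulus set.
"""

import argparse
from pathlib import Path

import pandas as pd

from preflook.norming import kruskal_wallis, load_association_table, mann_whitney


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.results.mkdir(parents=True, exist_ok=True)

    tab = load_association_table()
    cv = tab.loc[tab["condition"] == "CV", "target_strength"]
    mv = tab.loc[tab["condition"] == "MV", "target_strength"]
    uv = tab["uv_target_strength"]

    rows = []
    h, p = kruskal_wallis([cv, mv, uv])
    rows.append({"contrast": "target strength across conditions", "stat": "H", "value": h, "p": p})
    for name, (a, b) in {
        "CV vs MV (target)": (cv, mv),
        "CV vs UV (target)": (cv, uv),
        "MV vs UV (target)": (mv, uv),
    }.items():
        _, z, p = mann_whitney(a, b, continuity=True, tie_correction=True)
        rows.append({"contrast": name, "stat": "z", "value": z, "p": p})

    d_cv = tab.loc[tab["condition"] == "CV", "distractor_strength"]
    d_mv = tab.loc[tab["condition"] == "MV", "distractor_strength"]
    d_uv = tab["uv_distractor_strength"]
    h, p = kruskal_wallis([d_cv, d_mv, d_uv])
    rows.append({"contrast": "distractor strength across conditions", "stat": "H", "value": h, "p": p})

    out = pd.DataFrame(rows)
    out.to_csv(args.results / "norming_stats.csv", index=False)
    print(out.to_string(index=False, float_format=lambda v: f"{v: .4f}"))


if __name__ == "__main__":
    main()
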
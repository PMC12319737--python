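"""Descriptive behavioral analysis of the simulated cohort.

Computes thirds-binned accuracy and correct-RT summaries per task and the
cumulative per-sound learning curves, and prints the group table (the layout
used for cohort descriptives: thirds 1-3 and totals per task).
"""

from pathlib import Path

import pandas as pd

from fbl_rlddm.behavior import bin_thirds, cumulative_curve, summarize_cohort

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "behavior"


def main() -> None:
    log = pd.read_csv(BASE / "cohort" / "cohort_log.tsv", sep="\t")
    OUT.mkdir(parents=True, exist_ok=True)
    thirds = bin_thirds(log)
    thirds.to_csv(OUT / "thirds.csv", index=False)
    curves = cumulative_curve(log)
    curves.to_csv(OUT / "curves.csv", index=False)
    table = summarize_cohort(thirds)
    table.to_csv(OUT / "group_table.csv", index=False)
    print(table.round(3).to_string(index=False))
    finals = (curves.groupby(["task", "sound_id"])["cumsum"].last()
              .groupby("task").mean())
    print("\nmean final cumulative learning score per task:")
    print(finals.round(2).to_string())


if __name__ == "__main__":
    main()
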
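"""Descriptive behavioral summaries of the feedback-learning task.

Accuracy and correct-response RT are averaged over thirds of 16 trials within
each 48-trial block; per-sound learning trajectories are cumulative sums of
+1 (correct), -1 (incorrect), 0 (missing) over that sound's 8 presentations.
Missing trials count against accuracy by default (denominator = all trials in
the bin), consistent with the 0-coding of the trajectories; pass
``drop_missing=True`` to use responded trials as the denominator instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .task_design import TRIALS_PER_BLOCK

__all__ = ["bin_thirds", "cumulative_curve", "summarize_cohort"]

THIRD_SIZE = TRIALS_PER_BLOCK // 3  # 16 trials


def _third_of(trial_index: pd.Series) -> pd.Series:
    return ((trial_index - 1) // THIRD_SIZE + 1).astype(int)


def bin_thirds(trial_log: pd.DataFrame, drop_missing: bool = False,
               allow_partial_blocks: bool = False) -> pd.DataFrame:
    """Per (subject, task, block, third): accuracy, mean correct RT, counts.

    Thirds are the consecutive windows of trials 1-16, 17-32, 33-48.  RT is
    averaged over correct responded trials only and reported in ms.
    """
    log = trial_log.copy()
    if "subject" not in log:
        log["subject"] = 1
    log = log.sort_values(["subject", "task", "block", "trial"], kind="stable")
    if not allow_partial_blocks:
        sizes = log.groupby(["subject", "task", "block"]).size()
        if (sizes != TRIALS_PER_BLOCK).any():
            bad = sizes[sizes != TRIALS_PER_BLOCK]
            raise ValueError(
                f"blocks without {TRIALS_PER_BLOCK} trials: {bad.to_dict()}; "
                "pass allow_partial_blocks=True to override"
            )
    log["third"] = _third_of(log["trial"])
    missing = log["missing"].astype(bool) if "missing" in log \
        else log["rt_s"].isna()
    correct = log["correct"].fillna(0).astype(float)
    correct = correct.where(~missing, 0.0)
    log["_correct"] = correct
    log["_missing"] = missing
    log["_rt_ms_correct"] = np.where(
        (correct == 1.0) & ~missing, log["rt_s"] * 1000.0, np.nan)

    def agg(g: pd.DataFrame) -> pd.Series:
        n = len(g)
        n_missing = int(g["_missing"].sum())
        denom = n - n_missing if drop_missing else n
        acc = g["_correct"].sum() / denom if denom else np.nan
        return pd.Series({
            "accuracy": acc,
            "rt_ms": g["_rt_ms_correct"].mean(),
            "n_trials": n,
            "n_missing": n_missing,
        })

    out = (log.groupby(["subject", "task", "block", "third"])
              .apply(agg, include_groups=False).reset_index())
    out["n_trials"] = out["n_trials"].astype(int)
    out["n_missing"] = out["n_missing"].astype(int)
    return out


def cumulative_curve(trial_log: pd.DataFrame) -> pd.DataFrame:
    """Per (subject, task, block, sound): cumulative +1/-1/0 learning curve.

    Rows are ordered by presentation; ``presentation`` is 1-based within the
    sound and ``cumsum`` is the running total.
    """
    log = trial_log.copy()
    if "subject" not in log:
        log["subject"] = 1
    log = log.sort_values(["subject", "task", "block", "trial"], kind="stable")
    missing = log["missing"].astype(bool) if "missing" in log \
        else log["rt_s"].isna()
    correct = log["correct"].fillna(0).astype(float)
    incr = np.where(missing, 0.0, np.where(correct == 1.0, 1.0, -1.0))
    log["increment"] = incr.astype(int)
    keys = ["subject", "task", "block", "sound_id"]
    log["presentation"] = log.groupby(keys).cumcount() + 1
    log["cumsum"] = log.groupby(keys)["increment"].cumsum()
    return log[keys + ["trial", "presentation", "increment", "cumsum"]] \
        .reset_index(drop=True)


def summarize_cohort(thirds: pd.DataFrame) -> pd.DataFrame:
    """Group means and SDs per task x third, plus per-task totals.

    Mirrors the familiar descriptive layout: accuracy and correct-RT rows for
    thirds 1-3 and an overall row per task (subject-level values averaged
    over blocks first, then across subjects).
    """
    if thirds.empty:
        raise ValueError("no thirds summaries given")
    per_subj = (thirds.groupby(["subject", "task", "third"])
                [["accuracy", "rt_ms"]].mean().reset_index())
    rows = []
    for task, g in per_subj.groupby("task"):
        for third, gg in g.groupby("third"):
            rows.append({"task": task, "third": str(third),
                         "accuracy_mean": gg["accuracy"].mean(),
                         "accuracy_sd": gg["accuracy"].std(ddof=1),
                         "rt_ms_mean": gg["rt_ms"].mean(),
                         "rt_ms_sd": gg["rt_ms"].std(ddof=1),
                         "n_subjects": gg["subject"].nunique()})
        total = g.groupby("subject")[["accuracy", "rt_ms"]].mean()
        rows.append({"task": task, "third": "total",
                     "accuracy_mean": total["accuracy"].mean(),
                     "accuracy_sd": total["accuracy"].std(ddof=1),
                     "rt_ms_mean": total["rt_ms"].mean(),
                     "rt_ms_sd": total["rt_ms"].std(ddof=1),
                     "n_subjects": len(total)})
    return pd.DataFrame(rows)
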
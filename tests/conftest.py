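import numpy as np
import pandas as pd
import pytest

from fbl_rlddm.simulate import (
    DEFAULT_GROUP_PARAMS,
    SimConfig,
    make_task_designs,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def stimulus_set():
    from fbl_rlddm.task_design import make_stimulus_set

    return make_stimulus_set("A", rng_seed=1)


@pytest.fixture(scope="session")
def timed_designs():
    return make_task_designs("A", n_blocks=2, rng_seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """10 subjects x 2 blocks of task A at the default group parameters."""
    log, truth = simulate_cohort(
        DEFAULT_GROUP_PARAMS, SimConfig(n_subjects=10, rng_seed=11))
    return log[log["task"] == "A"].reset_index(drop=True), truth


def toy_block_log(correct_flags, missing_flags=None, rts=None,
                  sounds=None, task="A", block=1) -> pd.DataFrame:
    """Hand-built single-subject block log for descriptive-statistic tests."""
    n = len(correct_flags)
    missing_flags = missing_flags or [False] * n
    rts = rts if rts is not None else [1.0] * n
    sounds = sounds or [f"s{i % 6}" for i in range(n)]
    correct = [np.nan if m else float(c)
               for c, m in zip(correct_flags, missing_flags)]
    return pd.DataFrame({
        "subject": 1,
        "task": task,
        "block": block,
        "trial": np.arange(1, n + 1),
        "sound_id": sounds,
        "symbol_id": ["x"] * n,
        "is_match": [True] * n,
        "correct": correct,
        "rt_s": [np.nan if m else r for r, m in zip(rts, missing_flags)],
        "missing": missing_flags,
    })
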
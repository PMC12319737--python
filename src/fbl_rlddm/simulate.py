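"""Generative side of the RLDDM: synthetic cohorts for the FBL task.

Subjects are drawn from group distributions on the unconstrained scale
(Normal(mu, sigma) pushed through the same link functions the inference
module uses), then run generatively through the task: each trial's drift
comes from the current association state, the diffusion path is simulated by
Euler-Maruyama (unit diffusion coefficient, first-order scheme with the usual
O(sqrt(dt)) boundary-overshoot bias), feedback follows the correctness of the
absorbed boundary, and the association state is updated before the next
trial.  Paths still unabsorbed at the 2.5 s response deadline are recorded as
missing: no feedback, no update, onsets keep the deadline as the stimulus
time.

The default group parameters are synthetic study conditions, chosen to
produce guess-level accuracy in the first third of a block rising to roughly
0.85 by the last third; they are not fitted values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from . import task_design as td
from .rlddm import SubjectParams
from .inference_links import constrain

__all__ = [
    "GroupParams",
    "SimConfig",
    "DEFAULT_GROUP_PARAMS",
    "sample_subject_params",
    "simulate_trial_rt",
    "simulate_fpt_batch",
    "simulate_subject",
    "simulate_cohort",
]

PARAM_NAMES = ("a", "tau", "v_mod", "eta_pos", "eta_neg")


@dataclass
class GroupParams:
    """Group-level means/sds on the unconstrained scale, per parameter."""

    mu: dict[str, float]
    sigma: dict[str, float]

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            if name not in self.mu or name not in self.sigma:
                raise ValueError(f"missing group-level entry for {name}")
            if self.sigma[name] < 0:
                raise ValueError(f"sigma[{name}] must be >= 0")

    @classmethod
    def from_natural_means(cls, a: float, tau: float, v_mod: float,
                           eta_pos: float, eta_neg: float,
                           sigma: dict[str, float]) -> "GroupParams":
        """Convenience: specify means on the natural scale (inverted links)."""
        from .inference_links import unconstrain
        mu = {
            "a": unconstrain("a", a),
            "tau": unconstrain("tau", tau),
            "v_mod": unconstrain("v_mod", v_mod),
            "eta_pos": unconstrain("eta_pos", eta_pos),
            "eta_neg": unconstrain("eta_neg", eta_neg),
        }
        return cls(mu=mu, sigma=dict(sigma))


#: synthetic defaults (see module docstring); sds are on unconstrained scales
DEFAULT_GROUP_PARAMS = GroupParams.from_natural_means(
    a=1.8, tau=0.45, v_mod=2.2, eta_pos=0.5, eta_neg=0.2,
    sigma={"a": 0.2, "tau": 0.15, "v_mod": 0.3, "eta_pos": 0.5, "eta_neg": 0.5},
)


@dataclass
class SimConfig:
    n_subjects: int = 10
    tasks: tuple[str, ...] = ("A",)
    blocks_per_task: int = 2
    deadline_s: float = td.DEADLINE_S
    dt: float = 1e-3
    t_max: float = 10.0
    rng_seed: int = 0
    as0: float = 0.0
    reset_per_block: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.deadline_s > self.t_max:
            raise ValueError("deadline must not exceed t_max")


def sample_subject_params(group_params: GroupParams, n: int,
                          rng_seed: int) -> list[SubjectParams]:
    """Draw n subjects: Normal(mu, sigma) per parameter, then the link maps."""
    rng = np.random.default_rng(rng_seed)
    out = []
    for _ in range(n):
        natural = {
            name: constrain(name, rng.normal(group_params.mu[name],
                                             group_params.sigma[name]))
            for name in PARAM_NAMES
        }
        out.append(SubjectParams(**natural))
    return out


@njit(cache=True)
def _fpt_euler(a: float, v: float, w: float, dt: float, t_max: float) -> tuple:
    """One first-passage simulation; returns (boundary 1 up/0 down/-1 none, t)."""
    x = w * a
    t = 0.0
    sqdt = np.sqrt(dt)
    while t < t_max:
        x += v * dt + sqdt * np.random.standard_normal()
        t += dt
        if x >= a:
            return 1, t
        if x <= 0.0:
            return 0, t
    return -1, t


@njit(cache=True)
def _fpt_batch(a: float, v: float, w: float, dt: float, t_max: float,
               n: int, seed: int) -> tuple:
    np.random.seed(seed)
    boundary = np.empty(n, dtype=np.int64)
    fpt = np.empty(n)
    for i in range(n):
        b, t = _fpt_euler(a, v, w, dt, t_max)
        boundary[i] = b
        fpt[i] = t
    return boundary, fpt


def simulate_fpt_batch(a: float, v: float, w: float, dt: float, t_max: float,
                       n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """n independent first-passage simulations (decision times, no tau)."""
    return _fpt_batch(a, v, w, dt, t_max, n, int(seed) % 2**31)


def simulate_trial_rt(a: float, v: float, w: float, tau: float, dt: float,
                      t_max: float, rng_seed: int,
                      deadline_s: float = td.DEADLINE_S,
                      ) -> tuple[str | None, float | None]:
    """Single-trial generative draw.

    Returns (boundary, rt) with boundary in {"upper", "lower"} and
    rt = first-passage time + tau, or (None, None) when the response would
    land beyond the deadline (missing trial).
    """
    b, t = _fpt_batch(a, v, w, dt, t_max, 1, int(rng_seed) % 2**31)
    rt = t[0] + tau
    if b[0] == -1 or rt > deadline_s:
        return None, None
    return ("upper" if b[0] == 1 else "lower"), float(rt)


LOG_COLUMNS = td.DESIGN_COLUMNS + [
    "response", "correct", "rt_s", "missing", "feedback",
    "as_cor", "as_inc", "v_t", "pe",
]


def simulate_subject(params: SubjectParams, block_designs: list[td.BlockDesign],
                     config: SimConfig, rng_seed: int) -> pd.DataFrame:
    """Run one subject generatively over prepared block designs.

    Designs must carry jittered durations (see ``assign_timings``); onsets are
    recomputed from realized RTs (deadline stands in on missing trials).
    """
    rng = np.random.default_rng(rng_seed)
    frames = []
    for design in block_designs:
        sset = design.stimulus_set
        if sset is None:
            raise ValueError("block design must carry its stimulus set")
        state = {s: [config.as0, config.as0] for s in sset.sound_ids}
        t = design.trials.copy()
        n = len(t)
        resp = np.empty(n, dtype=object)
        correct = np.full(n, np.nan)
        rt = np.full(n, np.nan)
        missing = np.zeros(n, dtype=bool)
        feedback = np.full(n, np.nan)
        as_cor = np.empty(n)
        as_inc = np.empty(n)
        v_t = np.empty(n)
        pe = np.full(n, np.nan)
        for i in range(n):
            snd = t["sound_id"].iat[i]
            is_match = bool(t["is_match"].iat[i])
            ac, ai = state[snd]
            as_cor[i], as_inc[i] = ac, ai
            v = params.v_mod * 0.5 * (ac + ai)
            v_t[i] = v
            boundary, rti = simulate_trial_rt(
                params.a, v, params.z, params.tau, config.dt, config.t_max,
                int(rng.integers(2**31)), deadline_s=config.deadline_s)
            if boundary is None:
                resp[i] = "missing"
                missing[i] = True
                continue
            is_correct = boundary == "upper"
            # upper boundary = correct response; map back to match/nomatch
            resp[i] = ("match" if is_match else "nomatch") if is_correct \
                else ("nomatch" if is_match else "match")
            correct[i] = float(is_correct)
            rt[i] = rti
            f = 1.0 if is_correct else 0.0
            feedback[i] = f
            col = 0 if is_match else 1
            err = f - state[snd][col]
            pe[i] = err
            eta = params.eta_pos if err > 0 else params.eta_neg
            state[snd][col] += eta * err
        t["response"] = resp
        t["correct"] = correct
        t["rt_s"] = rt
        t["missing"] = missing
        t["feedback"] = feedback
        t["as_cor"] = as_cor
        t["as_inc"] = as_inc
        t["v_t"] = v_t
        t["pe"] = pe
        # realized onsets: missing trials occupy the full deadline window
        realized = np.where(missing, config.deadline_s, np.nan_to_num(rt))
        block = td.BlockDesign(design.task_id, design.block, t, design.rng_seed,
                               stimulus_set=sset)
        td.compute_onsets(block, realized)
        frames.append(block.trials)
    return pd.concat(frames, ignore_index=True)


def make_task_designs(task_id: str, n_blocks: int, rng_seed: int,
                      ) -> list[td.BlockDesign]:
    """Stimulus set plus ``n_blocks`` pseudorandomized, timed block designs."""
    sset = td.make_stimulus_set(task_id, rng_seed)
    designs = []
    for b in range(1, n_blocks + 1):
        d = td.generate_block(sset, b, rng_seed + 1000 * b)
        designs.append(td.assign_timings(d, rng_seed + 1000 * b + 1))
    return designs


def simulate_cohort(group_params: GroupParams, config: SimConfig,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort; returns (event log, ground-truth parameter table).

    Every subject of a task sees the same pseudorandomized designs (as in a
    fixed stimulus-protocol study; pair assignment differs only by task),
    which keeps cohort-level trial bookkeeping simple.
    """
    subjects = sample_subject_params(group_params, config.n_subjects,
                                     config.rng_seed)
    rng = np.random.default_rng(config.rng_seed + 1)
    logs = []
    truth_rows = []
    for task in config.tasks:
        task_offset = {"A": 0, "B": 1}.get(task, 2)
        designs = make_task_designs(task, config.blocks_per_task,
                                    config.rng_seed + 17 * task_offset)
        for sidx, params in enumerate(subjects, start=1):
            log = simulate_subject(params, designs, config,
                                   int(rng.integers(2**31)))
            log.insert(0, "subject", sidx)
            logs.append(log)
    for sidx, params in enumerate(subjects, start=1):
        truth_rows.append({"subject": sidx, "a": params.a, "tau": params.tau,
                           "v_mod": params.v_mod, "eta_pos": params.eta_pos,
                           "eta_neg": params.eta_neg, "z": params.z})
    return (pd.concat(logs, ignore_index=True),
            pd.DataFrame(truth_rows))
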
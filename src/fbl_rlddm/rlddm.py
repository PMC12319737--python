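"""Reinforcement-learning drift-diffusion model (RLDDM) of feedback learning.

The learning component is a delta rule on the association strength (AS) of
each presented (sound, symbol) pair:

    AS_t = AS_{t-1} + eta * (f_t - AS_{t-1}),   f in {1 correct, 0 incorrect}

with separate learning rates for positive and negative prediction errors
(PE = f - AS_pre) in the dual-rate variant.  AS acts as the expected value of
being correct about that pair, so with consistent correct feedback it rises
geometrically toward 1 regardless of whether the pair is a true match or a
foil (knowing a foil *is* a foil is also knowledge).

The decision component is a two-boundary diffusion in accuracy coding (upper
boundary = correct response, relative start fixed at z = 0.5).  The trial
drift is the scaled mean of the two associations a sound can evoke — its
match pair and its foil pair:

    v_t = v_mod * (AS_cor + AS_inc) / 2

highest when both associations are known, zero for a naive subject.  Choice
and RT enter the likelihood jointly through the WFPT density.

AS state is keyed by (sound, symbol) pair and, by default, reset at each
block boundary (each block re-randomizes the sequence over the same pairs);
``reset_per_block=False`` carries state across blocks of a task.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .task_design import StimulusSet
from .wfpt import wfpt_logpdf

__all__ = [
    "SubjectParams",
    "AssociationState",
    "prediction_error",
    "update_association",
    "trial_drift",
    "initial_state",
    "sequence_loglik",
    "pack_trials",
    "PackedTrials",
]


@dataclass
class SubjectParams:
    """Natural-scale RLDDM parameters for one subject.

    a      boundary separation (evidence units, > 0)
    tau    nondecision time (s, >= 0)
    v_mod  drift scaling factor (> 0)
    eta_pos / eta_neg   learning rates for positive / negative PE, in [0, 1]
    z      relative starting point, fixed at 0.5 (unbiased)
    """

    a: float
    tau: float
    v_mod: float
    eta_pos: float
    eta_neg: float
    z: float = 0.5

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("boundary separation a must be > 0")
        if self.tau < 0:
            raise ValueError("nondecision time tau must be >= 0")
        if self.v_mod <= 0:
            raise ValueError("drift scaling v_mod must be > 0")
        for name in ("eta_pos", "eta_neg"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {val}")
        if not 0.0 < self.z < 1.0:
            raise ValueError("starting point z must lie in (0, 1)")


@dataclass
class AssociationState:
    """Association strengths keyed by (sound_id, symbol_id)."""

    as_values: dict[tuple[str, str], float] = field(default_factory=dict)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        return self.as_values[pair]


def initial_state(stimulus_set: StimulusSet, as0: float = 0.0) -> AssociationState:
    """All tracked pairs (6 match + 6 foil) initialized to ``as0``."""
    if not 0.0 <= as0 <= 1.0:
        raise ValueError(f"initial association strength must lie in [0, 1], got {as0}")
    vals: dict[tuple[str, str], float] = {}
    for snd in stimulus_set.sound_ids:
        vals[(snd, stimulus_set.match_map[snd])] = as0
        vals[(snd, stimulus_set.foil_map[snd])] = as0
    return AssociationState(vals)


def prediction_error(f: int, as_pre: float) -> float:
    """PE = feedback minus the pair's pre-update association strength."""
    return float(f) - as_pre


def update_association(state: AssociationState, pair: tuple[str, str], f: int,
                       eta_pos: float, eta_neg: float,
                       ) -> tuple[AssociationState, dict[str, float]]:
    """Delta-rule update of the presented pair; other pairs untouched.

    Returns the (mutated) state and a fragment with the pre-update AS, the PE
    and the applied learning rate.  At PE exactly 0 no update occurs (both
    rates give the identical result).
    """
    if pair not in state.as_values:
        raise KeyError(f"pair {pair} is not tracked in this association state")
    as_pre = state.as_values[pair]
    pe = prediction_error(f, as_pre)
    eta = eta_pos if pe > 0 else eta_neg
    if pe != 0.0:
        state.as_values[pair] = as_pre + eta * pe
    return state, {"as_pre": as_pre, "pe": pe, "eta": eta if pe != 0.0 else 0.0}


def trial_drift(state: AssociationState, sound_id: str,
                match_pair: tuple[str, str], foil_pair: tuple[str, str],
                v_mod: float) -> float:
    """v_t = v_mod * mean(AS of match pair, AS of foil pair); signed toward
    the correct-response (upper) boundary."""
    as_cor = state.as_values[match_pair]
    as_inc = state.as_values[foil_pair]
    return v_mod * 0.5 * (as_cor + as_inc)


# ---------------------------------------------------------------------------
# packed representation for fast likelihood evaluation

@dataclass
class PackedTrials:
    """Cohort log columns as flat arrays for the numba likelihood kernel."""

    sound: np.ndarray        # int, 0..5 within task
    is_match: np.ndarray     # bool: presented pair is the sound's match pair
    missing: np.ndarray      # bool
    correct: np.ndarray      # bool (False where missing)
    rt_s: np.ndarray         # float (nan where missing)
    block_start: np.ndarray  # bool: state reset boundary
    n_trials: int


def pack_trials(log: pd.DataFrame, reset_per_block: bool = True) -> PackedTrials:
    """Pack one subject's (single-task) trial log in presentation order.

    Requires the fixed-foil design representation: each sound contributes one
    match and one foil pair, so (sound, is_match) identifies the pair.
    """
    log = log.sort_values(["block", "trial"], kind="stable").reset_index(drop=True)
    for snd, grp in log.groupby("sound_id"):
        if grp.loc[~grp["is_match"], "symbol_id"].nunique() > 1:
            raise ValueError(
                f"sound {snd!r} has multiple foil symbols; the RLDDM state "
                "requires the fixed-foil design mode"
            )
    sound_codes = pd.Categorical(log["sound_id"]).codes.astype(np.int64)
    block = log["block"].to_numpy()
    block_start = np.zeros(len(log), dtype=bool)
    block_start[0] = True
    if reset_per_block:
        block_start[1:] = block[1:] != block[:-1]
    missing = log["missing"].to_numpy(dtype=bool) if "missing" in log else np.zeros(len(log), bool)
    correct = np.nan_to_num(log["correct"].to_numpy(dtype=float)).astype(bool) \
        if "correct" in log else np.zeros(len(log), bool)
    rt = log["rt_s"].to_numpy(dtype=float) if "rt_s" in log else np.full(len(log), np.nan)
    return PackedTrials(
        sound=sound_codes,
        is_match=log["is_match"].to_numpy(dtype=bool),
        missing=missing,
        correct=correct,
        rt_s=rt,
        block_start=block_start,
        n_trials=len(log),
    )


@njit(cache=True)
def _seq_loglik_core(a, tau, v_mod, eta_pos, eta_neg, z,
                     sound, is_match, missing, correct, rt_s, block_start,
                     as0):
    n = sound.shape[0]
    state = np.full((6, 2), as0)  # columns: match pair, foil pair
    ll = np.zeros(n)
    as_cor = np.empty(n)
    as_inc = np.empty(n)
    v_t = np.empty(n)
    pe = np.full(n, np.nan)
    total = 0.0
    for i in range(n):
        if block_start[i]:
            state[:, :] = as0
        s = sound[i]
        ac, ai = state[s, 0], state[s, 1]
        as_cor[i] = ac
        as_inc[i] = ai
        v = v_mod * 0.5 * (ac + ai)
        v_t[i] = v
        if missing[i]:
            continue  # no likelihood term, no update
        lp = wfpt_logpdf(rt_s[i], bool(correct[i]), a, v, z, tau)
        ll[i] = lp
        total += lp
        f = 1.0 if correct[i] else 0.0
        col = 0 if is_match[i] else 1
        err = f - state[s, col]
        pe[i] = err
        if err > 0.0:
            state[s, col] += eta_pos * err
        elif err < 0.0:
            state[s, col] += eta_neg * err
    return total, ll, as_cor, as_inc, v_t, pe


def sequence_loglik(params: SubjectParams, trials: PackedTrials | pd.DataFrame,
                    as0: float = 0.0, reset_per_block: bool = True,
                    ) -> tuple[float, dict[str, np.ndarray]]:
    """Joint log likelihood of a subject's choice/RT sequence.

    Iterates trials in order: drift from the pre-update state, a WFPT term at
    the correct (upper) or incorrect (lower) boundary for responded trials,
    then the delta-rule update of the presented pair.  Missing trials
    contribute no likelihood term and trigger no update.  Returns the total
    plus per-trial series (log-density vector for WAIC, as_cor, as_inc, v_t,
    pe); a responded RT <= tau yields -inf (infeasible nondecision time).
    """
    if isinstance(trials, pd.DataFrame):
        trials = pack_trials(trials, reset_per_block=reset_per_block)
    total, ll, as_cor, as_inc, v_t, pe = _seq_loglik_core(
        params.a, params.tau, params.v_mod, params.eta_pos, params.eta_neg,
        params.z, trials.sound, trials.is_match, trials.missing,
        trials.correct, trials.rt_s, trials.block_start, as0,
    )
    series = {"loglik": ll, "as_cor": as_cor, "as_inc": as_inc,
              "v_t": v_t, "pe": pe, "responded": ~trials.missing}
    return float(total), series
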
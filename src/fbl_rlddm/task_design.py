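"""Structure of the audiovisual feedback-learning (FBL) task.

Each block presents 6 speech sounds 8 times each (48 trials): 4 presentations
with the sound's correct symbol ("match") and 4 with an incorrect symbol
("foil").  Sequences are pseudorandomized so that no two consecutive trials
share the same sound, and a fortiori the same (sound, symbol) pair.  Feedback
and fixation durations are jittered draws from Normal(2.0 s, 0.5 s) and
Normal(2.5 s, 0.5 s) respectively, truncated below at a floor.

By default each sound has one fixed foil symbol for the whole block (the foil
map is a derangement of the match map), so a block exposes 12 distinct pairs:
6 match + 6 foil.  A random-foil-per-trial mode is available for design
export, but the learning model operates on the fixed-foil representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StimulusSet",
    "BlockDesign",
    "TRIALS_PER_BLOCK",
    "N_SOUNDS",
    "REPS_PER_SOUND",
    "DEADLINE_S",
    "make_stimulus_set",
    "generate_block",
    "assign_timings",
    "validate_design",
    "write_design_tsv",
    "read_design_tsv",
]

TRIALS_PER_BLOCK = 48
N_SOUNDS = 6
REPS_PER_SOUND = 8
MATCH_PER_SOUND = 4
DEADLINE_S = 2.5

#: schema of the design TSV (the cohort log extends it)
DESIGN_COLUMNS = [
    "task", "block", "trial", "sound_id", "symbol_id", "is_match",
    "stim_onset_s", "feedback_duration_s", "fixation_duration_s",
]


@dataclass(frozen=True)
class StimulusSet:
    """Abstract identities of one task's sounds/symbols and their pairings."""

    task_id: str
    sound_ids: tuple[str, ...]
    symbol_ids: tuple[str, ...]
    match_map: dict[str, str]
    foil_map: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.sound_ids) != N_SOUNDS or len(self.symbol_ids) != N_SOUNDS:
            raise ValueError("a stimulus set has exactly 6 sounds and 6 symbols")
        if sorted(self.match_map.values()) != sorted(self.symbol_ids):
            raise ValueError("match_map must be a bijection onto the symbols")
        for s in self.sound_ids:
            if self.foil_map[s] == self.match_map[s]:
                raise ValueError(f"foil symbol equals match symbol for sound {s}")


@dataclass
class BlockDesign:
    """Ordered trial plan for one 48-trial block (timings optional)."""

    task_id: str
    block: int
    trials: pd.DataFrame  # DESIGN_COLUMNS schema
    rng_seed: int
    stimulus_set: StimulusSet | None = None
    constraint_report: dict[str, bool] = field(default_factory=dict)


def _derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random permutation of range(n) with no fixed point."""
    while True:
        p = rng.permutation(n)
        if not np.any(p == np.arange(n)):
            return p


def make_stimulus_set(task_id: str, rng_seed: int) -> StimulusSet:
    """Randomly assign match and foil symbols for one task's stimulus pool."""
    if task_id not in ("A", "B"):
        raise ValueError(f"task_id must be 'A' or 'B', got {task_id!r}")
    rng = np.random.default_rng(rng_seed)
    sounds = tuple(f"{task_id}_snd{i}" for i in range(1, N_SOUNDS + 1))
    symbols = tuple(f"{task_id}_sym{i}" for i in range(1, N_SOUNDS + 1))
    match_perm = rng.permutation(N_SOUNDS)
    match_map = {sounds[i]: symbols[match_perm[i]] for i in range(N_SOUNDS)}
    foil_perm = _derangement(N_SOUNDS, rng)
    foil_map = {sounds[i]: symbols[match_perm[foil_perm[i]]] for i in range(N_SOUNDS)}
    return StimulusSet(task_id, sounds, symbols, match_map, foil_map)


def generate_block(stimulus_set: StimulusSet, block: int, rng_seed: int,
                   max_attempts: int = 10_000,
                   random_foils: bool = False) -> BlockDesign:
    """Pseudorandomize one block by rejection sampling.

    Permutes the 48 (sound, is_match) slots until no two consecutive trials
    share a sound (which also rules out consecutive identical pairs).  Raises
    RuntimeError after ``max_attempts`` permutations, which signals an
    over-constrained configuration rather than a programming error.
    """
    rng = np.random.default_rng(rng_seed)
    sound_idx = np.repeat(np.arange(N_SOUNDS), REPS_PER_SOUND)
    is_match = np.tile(
        np.r_[np.ones(MATCH_PER_SOUND, bool), np.zeros(MATCH_PER_SOUND, bool)],
        N_SOUNDS,
    )
    for _ in range(max_attempts):
        order = rng.permutation(TRIALS_PER_BLOCK)
        s, m = sound_idx[order], is_match[order]
        # no-consecutive-sound implies no-consecutive-pair, so the cheap
        # integer check decides acceptance (~e^-7 of permutations pass)
        if np.any(s[1:] == s[:-1]):
            continue
        sounds = np.array([stimulus_set.sound_ids[i] for i in s])
        if random_foils:
            symbols = np.array([
                stimulus_set.match_map[snd] if mm else _random_foil(stimulus_set, snd, rng)
                for snd, mm in zip(sounds, m)
            ])
        else:
            symbols = np.array([
                stimulus_set.match_map[snd] if mm else stimulus_set.foil_map[snd]
                for snd, mm in zip(sounds, m)
            ])
        trials = pd.DataFrame({
            "task": stimulus_set.task_id,
            "block": block,
            "trial": np.arange(1, TRIALS_PER_BLOCK + 1),
            "sound_id": sounds,
            "symbol_id": symbols,
            "is_match": m,
            "stim_onset_s": np.nan,
            "feedback_duration_s": np.nan,
            "fixation_duration_s": np.nan,
        })
        design = BlockDesign(stimulus_set.task_id, block, trials, rng_seed,
                             stimulus_set=stimulus_set)
        design.constraint_report = validate_design(design)
        return design
    raise RuntimeError(
        f"no valid pseudorandomization found in {max_attempts} attempts"
    )


def _random_foil(stimulus_set: StimulusSet, sound: str,
                 rng: np.random.Generator) -> str:
    match = stimulus_set.match_map[sound]
    others = [sym for sym in stimulus_set.symbol_ids if sym != match]
    return others[rng.integers(len(others))]


def assign_timings(design: BlockDesign, rng_seed: int,
                   feedback_mean_s: float = 2.0, feedback_sd_s: float = 0.5,
                   fixation_mean_s: float = 2.5, fixation_sd_s: float = 0.5,
                   floor_s: float = 0.5,
                   rt_placeholder_s: float = 1.25) -> BlockDesign:
    """Draw jittered feedback/fixation durations and provisional onsets.

    Onsets accumulate previous onset + RT + feedback + fixation; until real or
    simulated RTs exist, a fixed placeholder RT stands in (the simulator
    recomputes onsets from realized RTs via :func:`compute_onsets`).
    """
    rng = np.random.default_rng(rng_seed)
    n = len(design.trials)
    fb = _truncated_normal(rng, feedback_mean_s, feedback_sd_s, floor_s, n)
    fx = _truncated_normal(rng, fixation_mean_s, fixation_sd_s, floor_s, n)
    trials = design.trials.copy()
    trials["feedback_duration_s"] = fb
    trials["fixation_duration_s"] = fx
    out = BlockDesign(design.task_id, design.block, trials, design.rng_seed,
                      stimulus_set=design.stimulus_set,
                      constraint_report=dict(design.constraint_report))
    compute_onsets(out, np.full(n, rt_placeholder_s))
    return out


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      floor: float, n: int) -> np.ndarray:
    out = rng.normal(mean, sd, size=n)
    while True:  # redraw below-floor values; keeps the mean honest vs clipping
        bad = out < floor
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))


def compute_onsets(design: BlockDesign, rts_s: np.ndarray) -> BlockDesign:
    """Fill stimulus onsets in place from per-trial response times (seconds)."""
    t = design.trials
    onsets = np.empty(len(t))
    clock = 0.0
    for i in range(len(t)):
        onsets[i] = clock
        clock += rts_s[i] + t["feedback_duration_s"].iat[i] + t["fixation_duration_s"].iat[i]
    design.trials["stim_onset_s"] = onsets
    return design


def validate_design(design: BlockDesign) -> dict[str, bool]:
    """Per-rule pass/fail report for the pseudorandomization constraints."""
    t = design.trials
    sounds = t["sound_id"].to_numpy()
    pairs = (t["sound_id"] + "\x00" + t["symbol_id"]).to_numpy()
    counts = t.groupby("sound_id").size()
    match_counts = t[t["is_match"]].groupby("sound_id").size()
    report = {
        "n_trials_48": len(t) == TRIALS_PER_BLOCK,
        "each_sound_8": bool((counts == REPS_PER_SOUND).all()) and len(counts) == N_SOUNDS,
        "match_per_sound_4": bool((match_counts == MATCH_PER_SOUND).all())
                             and len(match_counts) == N_SOUNDS,
        "no_consecutive_sound": not bool(np.any(sounds[1:] == sounds[:-1])),
        "no_consecutive_pair": not bool(np.any(pairs[1:] == pairs[:-1])),
        "trial_index_unique": t["trial"].is_unique,
    }
    return report


def write_design_tsv(designs: list[BlockDesign], path: str | Path) -> None:
    frames = [d.trials[DESIGN_COLUMNS] for d in designs]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_design_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
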
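"""Trial-sequence construction for the three inhibition paradigms.

Builds the complete, deterministic trial sequences of the Stroop,
negative-priming (NP) and flanker tasks used during EEG recording:

* Stroop — 8 blocks of 36 trials, alternating congruent/incongruent;
  word/display-color combinations exactly balanced within each block.
* NP — 4 blocks of 56 trials, alternating np/control; in np blocks the
  distractor of trial *n* becomes the target of trial *n + 1*; control
  blocks contain zero such carry-over.
* Flanker — 4 blocks of 72 trials, compatible/incompatible exactly
  balanced and shuffled within each block.

"Equal probability" of stimulus combinations is implemented as exact
balanced counts per block with seeded shuffling, so the design
invariants hold deterministically for every seed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Task",
    "TrialSpec",
    "Block",
    "TaskDesign",
    "build_stroop_design",
    "build_negative_priming_design",
    "build_flanker_design",
    "build_design",
    "design_to_frame",
    "design_from_frame",
]


class Task(str, enum.Enum):
    STROOP = "stroop"
    NEGATIVE_PRIMING = "np"
    FLANKER = "flanker"


#: display colors / color-word vocabulary of the Stroop task
STROOP_COLORS = ("red", "green", "yellow", "blue")
#: localized color words shown on screen (German defaults)
STROOP_WORDS = {"red": "ROT", "green": "GRÜN", "yellow": "GELB", "blue": "BLAU"}

NP_VOWELS = ("A", "E", "O", "U")
NP_CONSONANTS = ("H", "K", "N", "R")

FLANKER_COMPATIBLE = ("‹‹‹‹‹", "›››››")
FLANKER_INCOMPATIBLE = ("››‹››", "‹‹›‹‹")

#: condition labels per task: (inhibition condition, neutral condition)
CONDITIONS = {
    Task.STROOP: ("incongruent", "congruent"),
    Task.NEGATIVE_PRIMING: ("np", "control"),
    Task.FLANKER: ("incompatible", "compatible"),
}

STROOP_BLOCKS, STROOP_TRIALS_PER_BLOCK = 8, 36
NP_BLOCKS, NP_TRIALS_PER_BLOCK = 4, 56
FLANKER_BLOCKS, FLANKER_TRIALS_PER_BLOCK = 4, 72


@dataclass(frozen=True)
class TrialSpec:
    """One planned trial: stimulus, condition and timing."""

    task: Task
    block_index: int
    trial_index: int
    condition: str
    stimulus: str
    correct_response: str
    fixation_duration: float
    max_presentation: float

    def __post_init__(self) -> None:
        if self.block_index < 0 or self.trial_index < 0:
            raise ValueError("block_index and trial_index must be >= 0")
        if self.fixation_duration <= 0 or self.max_presentation <= 0:
            raise ValueError("durations must be positive")


@dataclass(frozen=True)
class Block:
    condition: str
    trials: tuple[TrialSpec, ...]


@dataclass(frozen=True)
class TaskDesign:
    task: Task
    blocks: tuple[Block, ...]
    seed: int
    start_block: str

    @property
    def trials(self) -> list[TrialSpec]:
        """All trials in presentation order."""
        return [t for b in self.blocks for t in b.trials]

    @property
    def n_trials(self) -> int:
        return sum(len(b.trials) for b in self.blocks)


def _alternating(first: str, second: str, n: int) -> list[str]:
    return [first if i % 2 == 0 else second for i in range(n)]


def build_stroop_design(seed: int, start_block: str = "congruent") -> TaskDesign:
    """Eight alternating 36-trial blocks of congruent/incongruent trials.

    Congruent blocks contain each of the 4 matching word-color pairs 9
    times; incongruent blocks each of the 12 mismatching pairs 3 times,
    shuffled by ``seed``.  Fixation crosses are uniform in [1.0, 1.5] s;
    the response deadline is 3 s.
    """
    if start_block not in ("congruent", "incongruent"):
        raise ValueError(f"invalid Stroop start_block: {start_block!r}")
    rng = np.random.default_rng(seed)
    other = "incongruent" if start_block == "congruent" else "congruent"

    congruent_pairs = [(c, c) for c in STROOP_COLORS]
    incongruent_pairs = [
        (w, c) for w in STROOP_COLORS for c in STROOP_COLORS if w != c
    ]

    blocks = []
    for b, cond in enumerate(_alternating(start_block, other, STROOP_BLOCKS)):
        if cond == "congruent":
            pairs = congruent_pairs * (STROOP_TRIALS_PER_BLOCK // len(congruent_pairs))
        else:
            pairs = incongruent_pairs * (
                STROOP_TRIALS_PER_BLOCK // len(incongruent_pairs)
            )
        order = rng.permutation(len(pairs))
        trials = []
        for i, j in enumerate(order):
            word, color = pairs[j]
            trials.append(
                TrialSpec(
                    task=Task.STROOP,
                    block_index=b,
                    trial_index=i,
                    condition=cond,
                    stimulus=f"{STROOP_WORDS[word]}/{color}",
                    correct_response=color,
                    fixation_duration=float(rng.uniform(1.0, 1.5)),
                    max_presentation=3.0,
                )
            )
        blocks.append(Block(condition=cond, trials=tuple(trials)))
    return TaskDesign(Task.STROOP, tuple(blocks), seed, start_block)


def _np_response(target: str) -> str:
    return "vowel" if target in NP_VOWELS else "consonant"


def _np_distractor(target: str, rng: np.random.Generator) -> str:
    pool = NP_CONSONANTS if target in NP_VOWELS else NP_VOWELS
    return pool[rng.integers(len(pool))]


def build_negative_priming_design(seed: int, start_block: str = "np") -> TaskDesign:
    """Four alternating 56-trial blocks of np/control trials.

    Each stimulus overlays a red target letter and a green distractor,
    one vowel and one consonant.  In np blocks the distractor of trial
    *n* is the target of trial *n + 1*; in control blocks the target of
    trial *n + 1* differs from both letters of trial *n*, so no
    carry-over priming occurs.  Stimulus 0.5 s, response window up to
    the 2.3-2.5 s post-stimulus blank, fixation 0.3-0.5 s.
    """
    if start_block not in ("np", "control"):
        raise ValueError(f"invalid NP start_block: {start_block!r}")
    rng = np.random.default_rng(seed)
    other = "control" if start_block == "np" else "np"
    letters = NP_VOWELS + NP_CONSONANTS

    blocks = []
    for b, cond in enumerate(_alternating(start_block, other, NP_BLOCKS)):
        trials = []
        target = letters[rng.integers(len(letters))]
        distractor = _np_distractor(target, rng)
        for i in range(NP_TRIALS_PER_BLOCK):
            if i > 0:
                prev_t, prev_d = target, distractor
                if cond == "np":
                    target = prev_d
                else:
                    candidates = [x for x in letters if x not in (prev_t, prev_d)]
                    target = candidates[rng.integers(len(candidates))]
                distractor = _np_distractor(target, rng)
            # response window: 0.5 s stimulus + post-stimulus blank
            blank = float(rng.uniform(2.3, 2.5))
            trials.append(
                TrialSpec(
                    task=Task.NEGATIVE_PRIMING,
                    block_index=b,
                    trial_index=i,
                    condition=cond,
                    stimulus=f"{target}(red)+{distractor}(green)",
                    correct_response=_np_response(target),
                    fixation_duration=float(rng.uniform(0.3, 0.5)),
                    max_presentation=0.5 + blank,
                )
            )
        blocks.append(Block(condition=cond, trials=tuple(trials)))
    return TaskDesign(Task.NEGATIVE_PRIMING, tuple(blocks), seed, start_block)


def build_flanker_design(seed: int, start_block: str = "mixed") -> TaskDesign:
    """Four 72-trial blocks with compatible/incompatible mixed within block.

    Each block holds exactly 18 instances of each of the four arrow
    strings (36 compatible, 36 incompatible), shuffled by ``seed``.  The
    correct response is the direction of the central arrow.
    """
    rng = np.random.default_rng(seed)
    stimuli = FLANKER_COMPATIBLE + FLANKER_INCOMPATIBLE
    per_stimulus = FLANKER_TRIALS_PER_BLOCK // len(stimuli)

    blocks = []
    for b in range(FLANKER_BLOCKS):
        pool = [s for s in stimuli for _ in range(per_stimulus)]
        order = rng.permutation(len(pool))
        trials = []
        for i, j in enumerate(order):
            stim = pool[j]
            central = stim[len(stim) // 2]
            trials.append(
                TrialSpec(
                    task=Task.FLANKER,
                    block_index=b,
                    trial_index=i,
                    condition=(
                        "compatible" if stim in FLANKER_COMPATIBLE else "incompatible"
                    ),
                    stimulus=stim,
                    correct_response="left" if central == "‹" else "right",
                    fixation_duration=float(rng.uniform(1.0, 1.5)),
                    max_presentation=3.0,
                )
            )
        blocks.append(Block(condition="mixed", trials=tuple(trials)))
    return TaskDesign(Task.FLANKER, tuple(blocks), seed, "mixed")


_BUILDERS = {
    Task.STROOP: build_stroop_design,
    Task.NEGATIVE_PRIMING: build_negative_priming_design,
    Task.FLANKER: build_flanker_design,
}

#: default starting-block labels per task for the (pre, post) phases;
#: the starting condition alternates between measurement occasions
START_BLOCKS = {
    Task.STROOP: ("congruent", "incongruent"),
    Task.NEGATIVE_PRIMING: ("np", "control"),
    Task.FLANKER: ("mixed", "mixed"),
}


def build_design(task: Task | str, seed: int, start_block: str | None = None) -> TaskDesign:
    """Dispatch to the paradigm-specific builder."""
    task = Task(task)
    builder = _BUILDERS[task]
    if start_block is None:
        return builder(seed)
    return builder(seed, start_block)


_COLUMNS = [
    "task",
    "block_index",
    "trial_index",
    "block_condition",
    "condition",
    "stimulus",
    "correct_response",
    "fixation_duration",
    "max_presentation",
]


def design_to_frame(design: TaskDesign) -> pd.DataFrame:
    """One row per trial, columns as in :data:`_COLUMNS`."""
    rows = []
    for block in design.blocks:
        for t in block.trials:
            rows.append(
                (
                    t.task.value,
                    t.block_index,
                    t.trial_index,
                    block.condition,
                    t.condition,
                    t.stimulus,
                    t.correct_response,
                    t.fixation_duration,
                    t.max_presentation,
                )
            )
    frame = pd.DataFrame(rows, columns=_COLUMNS)
    frame.attrs["seed"] = design.seed
    frame.attrs["start_block"] = design.start_block
    return frame


def design_from_frame(
    frame: pd.DataFrame, seed: int = -1, start_block: str | None = None
) -> TaskDesign:
    """Rebuild a :class:`TaskDesign` from its trial table."""
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    task = Task(frame["task"].iloc[0])
    seed = frame.attrs.get("seed", seed)
    start_block = frame.attrs.get("start_block", start_block)
    blocks = []
    for b, sub in frame.groupby("block_index", sort=True):
        trials = tuple(
            TrialSpec(
                task=task,
                block_index=int(r.block_index),
                trial_index=int(r.trial_index),
                condition=str(r.condition),
                stimulus=str(r.stimulus),
                correct_response=str(r.correct_response),
                fixation_duration=float(r.fixation_duration),
                max_presentation=float(r.max_presentation),
            )
            for r in sub.sort_values("trial_index").itertuples()
        )
        blocks.append(Block(condition=str(sub["block_condition"].iloc[0]), trials=trials))
    if start_block is None:
        start_block = blocks[0].condition
    return TaskDesign(task, tuple(blocks), seed, start_block)
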
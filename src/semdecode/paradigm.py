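"""Symbol-vocabulary learning paradigm: block schedule and behavior simulation.

Participants learn an arbitrary mapping from symbols to English words through
trial and error.  Each block cycles through six active symbols; on every trial
one symbol is shown, followed by four candidate words (the mapped word plus
three distractors drawn from the other five block words), and the participant
receives feedback.  A block ends once rolling response accuracy over the last
``mastery_window`` trials reaches ``mastery_threshold``.  The first block
introduces six symbols; every later block introduces three new symbols paired
with three previously seen ones, for ``initial + (n_blocks - 1) * added`` total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd

__all__ = [
    "ParadigmConfig",
    "BlockSchedule",
    "LearnerModel",
    "TrialRecord",
    "build_schedule",
    "simulate_behavior",
    "perfect_learner_first_trial_accuracy",
    "trials_to_frame",
]


@dataclass(frozen=True)
class ParadigmConfig:
    """Parameters of the vocabulary-learning schedule.

    Defaults reproduce the study design: 19 blocks, 6 initial symbols,
    3 added per block (60 symbols total), 4 response choices, blocks
    mastered at 90% accuracy over a rolling window of 10 trials, and at
    most 20 exposures per symbol.
    """

    n_blocks: int = 19
    initial_symbols: int = 6
    added_per_block: int = 3
    n_choices: int = 4
    mastery_threshold: float = 0.90
    mastery_window: int = 10
    max_exposures: int = 20
    choice_onset_ms: float = 500.0
    block_trial_limit: int = 300

    @property
    def block_size(self) -> int:
        return self.initial_symbols

    @property
    def n_symbols(self) -> int:
        return self.initial_symbols + (self.n_blocks - 1) * self.added_per_block

    def validate(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.added_per_block >= self.block_size:
            raise ValueError(
                "added_per_block must be smaller than the block size "
                f"({self.added_per_block} >= {self.block_size})"
            )
        if not (0 < self.mastery_threshold <= 1):
            raise ValueError("mastery_threshold must lie in (0, 1]")
        if self.n_choices > self.block_size:
            raise ValueError("n_choices cannot exceed the block size")
        if self.n_choices < 2:
            raise ValueError("n_choices must be >= 2")


@dataclass(frozen=True)
class BlockSchedule:
    """Per-block active symbol sets.

    ``blocks[b]`` lists the active symbol ids of block ``b``;
    ``new_flags[b][i]`` is True where ``blocks[b][i]`` is introduced in
    that block.  Symbol ids are 0..n_symbols-1 in order of introduction.
    """

    blocks: tuple[tuple[int, ...], ...]
    new_flags: tuple[tuple[bool, ...], ...]

    @property
    def n_symbols(self) -> int:
        return max(max(b) for b in self.blocks) + 1

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


@dataclass(frozen=True)
class LearnerModel:
    """Idealized response model.

    kind:
      * ``perfect`` — knows a symbol's word from the trial after its
        ``exposures_to_acquire``-th exposure onward (default: after one
        exposure), regardless of whether the response on that exposure
        was correct (feedback idealization).
      * ``exposure_rate`` — acquires the mapping independently with
        probability ``acquisition_rate`` after each exposure.
      * ``random`` — never acquires any mapping.

    On trials of an unacquired symbol the learner eliminates displayed
    words already mapped to other acquired symbols and guesses uniformly
    among the remainder.
    """

    kind: str = "perfect"
    acquisition_rate: float | None = None
    exposures_to_acquire: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("perfect", "exposure_rate", "random"):
            raise ValueError(f"unknown learner kind: {self.kind!r}")
        if self.kind == "exposure_rate" and not (
            self.acquisition_rate is not None and 0 <= self.acquisition_rate <= 1
        ):
            raise ValueError("exposure_rate learner needs acquisition_rate in [0, 1]")
        if self.exposures_to_acquire < 1:
            raise ValueError("exposures_to_acquire must be >= 1")


@dataclass(frozen=True)
class TrialRecord:
    """One word-learning trial of one participant."""

    participant: int
    block: int
    symbol: int
    exposure_index: int  # 1-based count of presentations of this symbol
    choices: tuple[int, ...]  # word ids shown; word id == mapped symbol id
    response: int
    correct: bool
    acquired_before_trial: bool
    block_truncated: bool = False


def build_schedule(config: ParadigmConfig, seed: int) -> BlockSchedule:
    """Draw a block schedule: block 1 all new, later blocks 3 new + 3 carried.

    Carried symbols are drawn uniformly without replacement from all
    previously introduced symbols.  Deterministic given ``seed``.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    blocks: list[tuple[int, ...]] = []
    flags: list[tuple[bool, ...]] = []
    next_id = 0

    first = tuple(range(config.initial_symbols))
    next_id = config.initial_symbols
    blocks.append(first)
    flags.append((True,) * config.initial_symbols)

    for _ in range(1, config.n_blocks):
        new = tuple(range(next_id, next_id + config.added_per_block))
        next_id += config.added_per_block
        n_carry = config.block_size - config.added_per_block
        n_previous = next_id - config.added_per_block
        carried = tuple(int(s) for s in rng.choice(n_previous, size=n_carry, replace=False))
        block = new + carried
        blocks.append(block)
        flags.append((True,) * len(new) + (False,) * len(carried))

    return BlockSchedule(blocks=tuple(blocks), new_flags=tuple(flags))


def simulate_behavior(
    schedule: BlockSchedule,
    config: ParadigmConfig,
    learner: LearnerModel,
    seed: int,
    participant: int = 0,
) -> list[TrialRecord]:
    """Simulate one participant's trial-by-trial behavior over all blocks.

    Within a block, trial symbols are drawn uniformly from the active
    symbols that have not yet hit ``max_exposures``; the block ends once
    rolling accuracy over the last ``mastery_window`` trials reaches
    ``mastery_threshold``, or at ``block_trial_limit`` trials (the latter
    flagged via ``block_truncated``).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    exposures: dict[int, int] = {}
    acquired: set[int] = set()
    records: list[TrialRecord] = []

    for b, block in enumerate(schedule.blocks):
        recent: list[bool] = []
        n_block_trials = 0
        truncated = False
        while True:
            eligible = [s for s in block if exposures.get(s, 0) < config.max_exposures]
            if not eligible:
                break
            if n_block_trials >= config.block_trial_limit:
                truncated = True
                break
            symbol = int(rng.choice(eligible))
            exposures[symbol] = exposures.get(symbol, 0) + 1
            exp_idx = exposures[symbol]
            known = symbol in acquired

            others = [s for s in block if s != symbol]
            distractors = [int(s) for s in rng.choice(others, size=config.n_choices - 1, replace=False)]
            choices = distractors + [symbol]
            rng.shuffle(choices)
            choices = tuple(int(c) for c in choices)

            if known:
                response = symbol
            else:
                remaining = [c for c in choices if c == symbol or c not in acquired]
                response = int(remaining[rng.integers(len(remaining))])
            correct = response == symbol

            records.append(
                TrialRecord(
                    participant=participant,
                    block=b,
                    symbol=symbol,
                    exposure_index=exp_idx,
                    choices=choices,
                    response=response,
                    correct=correct,
                    acquired_before_trial=known,
                )
            )

            # post-trial acquisition update
            if learner.kind == "perfect":
                if exp_idx >= learner.exposures_to_acquire:
                    acquired.add(symbol)
            elif learner.kind == "exposure_rate":
                if symbol not in acquired and rng.random() < learner.acquisition_rate:
                    acquired.add(symbol)

            recent.append(correct)
            n_block_trials += 1
            if len(recent) >= config.mastery_window:
                window = recent[-config.mastery_window :]
                if sum(window) / len(window) >= config.mastery_threshold:
                    break
        if truncated and records:
            # flag every record of the truncated block
            records = [
                r if r.block != b else _with_truncated(r) for r in records
            ]

    return records


def _with_truncated(r: TrialRecord) -> TrialRecord:
    return TrialRecord(
        participant=r.participant,
        block=r.block,
        symbol=r.symbol,
        exposure_index=r.exposure_index,
        choices=r.choices,
        response=r.response,
        correct=r.correct,
        acquired_before_trial=r.acquired_before_trial,
        block_truncated=True,
    )


def perfect_learner_first_trial_accuracy(config: ParadigmConfig | None = None) -> float:
    """Expected first-exposure response accuracy of a perfect learner.

    A perfect learner knows every previously encountered symbol's word and
    eliminates displayed words mapped to known symbols, guessing uniformly
    among the remainder.  On a symbol's very first exposure the number of
    *unknown* words among the three distractors (drawn from the other five
    block words) is hypergeometric, and the success probability is
    E[1 / (1 + k_unknown)].  Averaging over first-encounter positions —
    first block positions 1..6 with 5,4,...,0 unknown others; later-block
    new-symbol positions 1..3 with 2,1,0 unknown others — and weighting
    every symbol equally gives ~0.712 under the default design (71%).
    """
    cfg = config or ParadigmConfig()
    cfg.validate()
    n_block = cfg.block_size
    n_new = cfg.added_per_block
    n_draw = cfg.n_choices - 1
    n_pool = n_block - 1  # candidate distractors

    def expected_success(n_unknown_others: int) -> Fraction:
        total = Fraction(0)
        for k in range(max(0, n_draw - (n_pool - n_unknown_others)), min(n_draw, n_unknown_others) + 1):
            p = Fraction(comb(n_unknown_others, k) * comb(n_pool - n_unknown_others, n_draw - k), comb(n_pool, n_draw))
            total += p * Fraction(1, 1 + k)
        return total

    # first block: the p-th distinct symbol encountered has block_size - p unknown others
    first_block = sum(expected_success(n_block - p) for p in range(1, n_block + 1))
    # later blocks: carried symbols are known; a new symbol first encountered
    # p-th among the new ones has added_per_block - p unknown others
    later_per_block = sum(expected_success(n_new - p) for p in range(1, n_new + 1))

    total = first_block + (cfg.n_blocks - 1) * later_per_block
    return float(total / cfg.n_symbols)


def trials_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Tabulate trial records (choices joined as comma-separated word ids)."""
    return pd.DataFrame(
        {
            "participant": [r.participant for r in records],
            "block": [r.block for r in records],
            "symbol": [r.symbol for r in records],
            "exposure_index": [r.exposure_index for r in records],
            "choices": [",".join(map(str, r.choices)) for r in records],
            "response": [r.response for r in records],
            "correct": [r.correct for r in records],
            "acquired_before_trial": [r.acquired_before_trial for r in records],
            "block_truncated": [r.block_truncated for r in records],
        }
    )
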
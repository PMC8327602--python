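"""Generative model of the information-selective symmetric reversal bandit task.

The task is a two-armed bandit in which, on every trial, a square and a
triangle are shown on opposite screen sides.  One shape is currently
*lucrative* (reward +1 with probability ``p_reward_lucrative``, -1 otherwise)
and the other *detrimental* (probabilities reversed); which shape is lucrative
reverses every ``block_length_min``..``block_length_max`` trials, unsignaled.
One screen side is *informative*: choosing the shape on that side reveals the
returned reward (moneybag / crossed-out moneybag), while choosing the shape on
the other side masks it (question-mark moneybag).

State coding
------------
``s1``: 1 if the square is lucrative, 2 if the triangle is lucrative (hidden).
``s2``: 1 if the square is on the informative side, 2 if the triangle is
(observable).  Actions: 1 = square/informative, 2 = square/non-informative,
3 = triangle/informative, 4 = triangle/non-informative.  Given ``s2`` only two
actions are available: {1, 4} for ``s2 = 1`` and {2, 3} for ``s2 = 2``.
Observations: 1 = crossed-out moneybag (loss revealed), 2 = moneybag (win
revealed), 3 = question-mark moneybag (reward masked).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TaskConfig",
    "StateSequence",
    "TrialOutcome",
    "ConfigurationError",
    "generate_state_sequence",
    "validate_state_sequence",
    "observation_function",
    "sample_reward",
    "available_actions",
    "INFORMATIVE_ACTIONS",
    "SQUARE_ACTIONS",
]

#: actions that reveal the returned reward (shape on the informative side)
INFORMATIVE_ACTIONS = frozenset({1, 3})
#: actions that select the square (regardless of side)
SQUARE_ACTIONS = frozenset({1, 2})


class ConfigurationError(ValueError):
    """Raised when a task configuration cannot produce a valid sequence."""


@dataclass(frozen=True)
class TaskConfig:
    """Generative constants of the task.

    Defaults reproduce the experimental design: two runs of 80 trials,
    reward probability 0.85 for the lucrative shape, three unsignaled
    reversals per run with 17-23 trials between reversals, and at most five
    consecutive repetitions of the same choice-option combination.
    """

    trials_per_run: int = 80
    n_runs: int = 2
    p_reward_lucrative: float = 0.85
    block_length_min: int = 17
    block_length_max: int = 23
    reversals_per_run: int = 3
    max_consecutive_same_option: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_reward_lucrative <= 1.0:
            raise ConfigurationError("p_reward_lucrative must lie in [0, 1]")
        if self.block_length_min > self.block_length_max:
            raise ConfigurationError("block_length_min must be <= block_length_max")
        if min(self.trials_per_run, self.n_runs, self.block_length_min) < 1:
            raise ConfigurationError("counts must be positive")
        if self.reversals_per_run < 0 or self.max_consecutive_same_option < 1:
            raise ConfigurationError("invalid reversal or repetition count")
        n_blocks = self.reversals_per_run + 1
        if not (
            n_blocks * self.block_length_min
            <= self.trials_per_run
            <= n_blocks * self.block_length_max
        ):
            raise ConfigurationError(
                f"{n_blocks} blocks of length "
                f"[{self.block_length_min}, {self.block_length_max}] cannot "
                f"sum to {self.trials_per_run} trials"
            )

    @property
    def n_trials(self) -> int:
        return self.n_runs * self.trials_per_run


@dataclass(frozen=True)
class TrialOutcome:
    """Reward and displayed outcome image of a single trial."""

    reward: int
    observation: int

    def __post_init__(self) -> None:
        if self.reward not in (-1, 1):
            raise ValueError("reward must be -1 or +1")
        if self.observation not in (1, 2, 3):
            raise ValueError("observation must be 1, 2 or 3")


@dataclass
class StateSequence:
    """Per-trial hidden lucrative shape (s1) and option layout (s2).

    ``s1`` is piecewise constant between reversals; ``s2`` is counterbalanced
    so that within the trials of a run sharing an s1 value each layout occurs
    equally often.  ``run`` holds the 1-based run index of each trial.
    """

    s1: np.ndarray
    s2: np.ndarray
    run: np.ndarray
    config: TaskConfig = field(default_factory=TaskConfig)

    def __len__(self) -> int:
        return len(self.s1)

    def trial_type(self) -> np.ndarray:
        """1 where the choice is L∧I vs D∧N (s1 == s2), else 2."""
        return np.where(self.s1 == self.s2, 1, 2)


def available_actions(s2: int) -> frozenset[int]:
    """Available action set for an option layout ``s2``."""
    if s2 == 1:
        return frozenset({1, 4})
    if s2 == 2:
        return frozenset({2, 3})
    raise ValueError(f"s2 must be 1 or 2, got {s2!r}")


def observation_function(action: int, reward: int) -> int:
    """Deterministic mapping from (action, reward) to the outcome image.

    Informative actions reveal the reward (-1 -> 1, +1 -> 2); non-informative
    actions mask it (both rewards -> 3).
    """
    if action not in (1, 2, 3, 4):
        raise ValueError(f"action must be in 1..4, got {action!r}")
    if reward not in (-1, 1):
        raise ValueError(f"reward must be -1 or +1, got {reward!r}")
    if action in INFORMATIVE_ACTIONS:
        return 1 if reward == -1 else 2
    return 3


def sample_reward(
    s1: int, action: int, config: TaskConfig, rng: np.random.Generator
) -> int:
    """Draw the trial reward given the hidden state and the chosen action.

    The chosen shape is lucrative iff it matches ``s1``; the lucrative choice
    wins (+1) with probability ``config.p_reward_lucrative``.
    """
    if s1 not in (1, 2):
        raise ValueError(f"s1 must be 1 or 2, got {s1!r}")
    if action not in (1, 2, 3, 4):
        raise ValueError(f"action must be in 1..4, got {action!r}")
    chose_square = action in SQUARE_ACTIONS
    chose_lucrative = chose_square == (s1 == 1)
    p_win = config.p_reward_lucrative if chose_lucrative else 1.0 - config.p_reward_lucrative
    return 1 if rng.random() < p_win else -1


def _sample_block_lengths(config: TaskConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniform rejection sampling of block lengths summing to trials_per_run.

    When the run length is even and the alternation allows it, the blocks with
    odd index and those with even index are additionally constrained to equal
    halves, so each shape is lucrative on exactly half of the run's trials.
    """
    n_blocks = config.reversals_per_run + 1
    lo, hi = config.block_length_min, config.block_length_max
    total = config.trials_per_run
    half = total // 2
    n_odd = (n_blocks + 1) // 2  # blocks 0, 2, 4, ...
    n_even = n_blocks // 2
    balance = (
        total % 2 == 0
        and n_even > 0
        and n_odd * lo <= half <= n_odd * hi
        and n_even * lo <= half <= n_even * hi
    )
    for _ in range(100_000):
        lengths = rng.integers(lo, hi + 1, size=n_blocks)
        if lengths.sum() != total:
            continue
        if balance and lengths[0::2].sum() != half:
            continue
        return lengths
    raise ConfigurationError("could not sample admissible block lengths")


def _assign_s2(
    s1_run: np.ndarray, config: TaskConfig, rng: np.random.Generator
) -> np.ndarray | None:
    """Counterbalanced s2 assignment for one run, or None if rejected.

    Within the trials sharing an s1 value, each s2 value is used on exactly
    half of them (odd group sizes split as evenly as integers allow); the
    shuffle is rejected when any (s1, s2) combination repeats more than
    ``max_consecutive_same_option`` times in a row.
    """
    s2 = np.empty_like(s1_run)
    for value in (1, 2):
        idx = np.flatnonzero(s1_run == value)
        half = len(idx) // 2
        labels = np.array([1] * half + [2] * (len(idx) - half))
        rng.shuffle(labels)
        s2[idx] = labels
    combo = s1_run * 10 + s2
    longest = run_count = 1
    for i in range(1, len(combo)):
        run_count = run_count + 1 if combo[i] == combo[i - 1] else 1
        longest = max(longest, run_count)
    if longest > config.max_consecutive_same_option:
        return None
    return s2


def generate_state_sequence(config: TaskConfig, seed: int) -> StateSequence:
    """Generate a full task state sequence (all runs) from a seed.

    Per run: block lengths are drawn uniformly by rejection from the
    admissible compositions, the initially lucrative shape is a fair draw,
    s1 alternates across blocks, and s2 is counterbalanced within each s1
    value under the consecutive-repetition constraint.  Deterministic given
    ``(config, seed)``.
    """
    rng = np.random.default_rng(seed)
    s1_parts, s2_parts, run_parts = [], [], []
    for run_idx in range(1, config.n_runs + 1):
        first = int(rng.integers(1, 3))  # fair draw of the first lucrative shape
        for _ in range(100_000):
            lengths = _sample_block_lengths(config, rng)
            s1_run = np.concatenate(
                [
                    np.full(n, first if i % 2 == 0 else 3 - first, dtype=np.int64)
                    for i, n in enumerate(lengths)
                ]
            )
            s2_run = _assign_s2(s1_run, config, rng)
            if s2_run is not None:
                break
        else:  # pragma: no cover - astronomically unlikely under defaults
            raise ConfigurationError("could not satisfy the s2 constraints")
        s1_parts.append(s1_run)
        s2_parts.append(s2_run)
        run_parts.append(np.full(config.trials_per_run, run_idx, dtype=np.int64))
    return StateSequence(
        s1=np.concatenate(s1_parts),
        s2=np.concatenate(s2_parts),
        run=np.concatenate(run_parts),
        config=config,
    )


def validate_state_sequence(sequence: StateSequence) -> None:
    """Re-check every StateSequence invariant; raises ValueError on violation.

    Independent of the generator: recounts block lengths, reversals, the
    consecutive-repetition bound and the within-s1 counterbalance.
    """
    cfg = sequence.config
    s1, s2, run = sequence.s1, sequence.s2, sequence.run
    if not (len(s1) == len(s2) == len(run) == cfg.n_trials):
        raise ValueError("sequence length does not match the configuration")
    if not (np.isin(s1, (1, 2)).all() and np.isin(s2, (1, 2)).all()):
        raise ValueError("state labels must be 1 or 2")
    for r in range(1, cfg.n_runs + 1):
        mask = run == r
        if mask.sum() != cfg.trials_per_run:
            raise ValueError(f"run {r} has the wrong number of trials")
        s1_r, s2_r = s1[mask], s2[mask]
        changes = np.flatnonzero(np.diff(s1_r) != 0)
        if len(changes) != cfg.reversals_per_run:
            raise ValueError(f"run {r}: expected {cfg.reversals_per_run} reversals")
        bounds = np.concatenate(([0], changes + 1, [cfg.trials_per_run]))
        lengths = np.diff(bounds)
        if ((lengths < cfg.block_length_min) | (lengths > cfg.block_length_max)).any():
            raise ValueError(f"run {r}: block length outside the allowed range")
        for value in (1, 2):
            group = s2_r[s1_r == value]
            if abs((group == 1).sum() - (group == 2).sum()) > len(group) % 2:
                raise ValueError(f"run {r}: s2 not counterbalanced within s1={value}")
        combo = s1_r * 10 + s2_r
        run_count = 1
        for i in range(1, len(combo)):
            run_count = run_count + 1 if combo[i] == combo[i - 1] else 1
            if run_count > cfg.max_consecutive_same_option:
                raise ValueError(f"run {r}: choice-option combination repeated too often")
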
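"""Shared fixtures: configurations, sequences and hand-built datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from revbandit import ChoiceDataset, StateSequence, TaskConfig, generate_state_sequence
from revbandit.task import observation_function


@pytest.fixture(scope="session")
def config() -> TaskConfig:
    return TaskConfig()


@pytest.fixture(scope="session")
def sequence(config) -> StateSequence:
    return generate_state_sequence(config, seed=1234)


@pytest.fixture(scope="session")
def small_config() -> TaskConfig:
    """One 40-trial run with a single reversal, for fast end-to-end tests."""
    return TaskConfig(trials_per_run=40, n_runs=1, reversals_per_run=1)


@pytest.fixture(scope="session")
def small_sequence(small_config) -> StateSequence:
    return generate_state_sequence(small_config, seed=99)


def lucrative_action(s1: int, s2: int) -> int:
    """The lucrative action available under (s1, s2)."""
    if s2 == 1:  # available {1, 4}
        return 1 if s1 == 1 else 4
    return 2 if s1 == 1 else 3  # available {2, 3}


def detrimental_action(s1: int, s2: int) -> int:
    pair = {1: {1, 4}, 2: {2, 3}}[s2]
    return (pair - {lucrative_action(s1, s2)}).pop()


def build_dataset(
    sequence: StateSequence,
    actions: list[int | None],
    participant_id: str = "toy-000",
    rewards: list[int] | None = None,
) -> ChoiceDataset:
    """Construct a ChoiceDataset from explicit per-trial actions.

    ``None`` marks an invalid (missed) trial.  Rewards default to +1; the
    observation is always derived from the observation function.
    """
    n = len(sequence)
    assert len(actions) == n
    trial_in_run = np.concatenate(
        [np.arange(1, (sequence.run == r).sum() + 1) for r in np.unique(sequence.run)]
    )
    action_col, reward_col, obs_col, valid_col = [], [], [], []
    for i, a in enumerate(actions):
        if a is None:
            action_col.append(pd.NA)
            reward_col.append(pd.NA)
            obs_col.append(pd.NA)
            valid_col.append(0)
        else:
            r = 1 if rewards is None else rewards[i]
            action_col.append(a)
            reward_col.append(r)
            obs_col.append(observation_function(a, r))
            valid_col.append(1)
    trials = pd.DataFrame(
        {
            "participant_id": participant_id,
            "run": sequence.run,
            "trial": trial_in_run,
            "s1": sequence.s1,
            "s2": sequence.s2,
            "action": pd.array(action_col, dtype="Int64"),
            "reward": pd.array(reward_col, dtype="Int64"),
            "observation": pd.array(obs_col, dtype="Int64"),
            "valid": valid_col,
        }
    )
    return ChoiceDataset(trials=trials)
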
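"""Closed-loop agent-task simulation producing synthetic choice datasets.

An agent interacts with a state sequence trial by trial: it evaluates its
valences, samples an action from the softmax policy at its noise temperature
(uniform for the random-choice control C1), receives a sampled reward, sees
the corresponding outcome image and updates its internal state.  Simulated
agents always respond, so every simulated trial is valid.

Seeds follow a spawn hierarchy (master seed -> per-dataset seeds -> per-trial
streams) so cohorts are reproducible as a whole and replayable individually.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .agents import AgentParams, AgentRuntime, TransitionModel
from .task import (
    StateSequence,
    TaskConfig,
    generate_state_sequence,
    observation_function,
    sample_reward,
)

__all__ = ["ChoiceDataset", "softmax_probabilities", "simulate_dataset", "simulate_cohort"]

#: column order of the canonical tidy representation
DATASET_COLUMNS = [
    "participant_id",
    "run",
    "trial",
    "s1",
    "s2",
    "action",
    "reward",
    "observation",
    "valid",
]


@dataclass
class ChoiceDataset:
    """Tidy per-trial choice records for one participant or agent.

    ``trials`` holds one row per trial sorted by (run, trial) with 1-based
    trial indices restarting per run; invalid trials have missing action,
    reward and observation.  ``meta`` carries generating provenance for
    synthetic data (agent kind, parameters, seeds).
    """

    trials: pd.DataFrame
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in DATASET_COLUMNS if c not in self.trials.columns and c != "s1"]
        if missing:
            raise ValueError(f"dataset is missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_valid(self) -> int:
        return int(self.trials["valid"].sum())

    def global_trial(self) -> np.ndarray:
        """1-based index over the concatenated runs."""
        return np.arange(1, len(self.trials) + 1)


def softmax_probabilities(valences: dict[int, float], tau: float) -> dict[int, float]:
    """Softmax policy with temperature ``tau`` over a valence map.

    Stabilized by subtracting the maximum valence before exponentiation, so
    arbitrarily small temperatures are safe.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    vmax = max(valences.values())
    weights = {a: math.exp((v - vmax) / tau) for a, v in valences.items()}
    total = sum(weights.values())
    return {a: w / total for a, w in weights.items()}


def _policy(kind: str, valences: dict[int, float], tau: float | None) -> dict[int, float]:
    if kind == "C1":
        return {a: 1.0 / len(valences) for a in valences}
    if tau is None:
        raise ValueError(f"agent kind {kind} requires a softmax temperature tau")
    return softmax_probabilities(valences, tau)


def simulate_dataset(
    params: AgentParams,
    sequence: StateSequence,
    config: TaskConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    participant_id: str = "sim-000",
) -> ChoiceDataset:
    """Simulate one agent playing the full task once.

    The agent's internal state is reset at every run boundary.  The hidden
    state column ``s1`` is retained in the output (synthetic data only).
    """
    config = config or sequence.config
    transition = TransitionModel.from_config(config)
    agent = AgentRuntime(params, transition, config.p_reward_lucrative)
    rng = np.random.default_rng(seed)

    n = len(sequence)
    actions = np.empty(n, dtype=np.int64)
    rewards = np.empty(n, dtype=np.int64)
    observations = np.empty(n, dtype=np.int64)
    trial_in_run = np.empty(n, dtype=np.int64)

    current_run = 0
    for i in range(n):
        if sequence.run[i] != current_run:
            current_run = int(sequence.run[i])
            trial = 0
            agent.reset()
        trial += 1
        trial_in_run[i] = trial
        s2 = int(sequence.s2[i])
        probs = _policy(params.kind, agent.valences(s2), params.tau)
        acts = sorted(probs)
        action = int(rng.choice(acts, p=[probs[a] for a in acts]))
        reward = sample_reward(int(sequence.s1[i]), action, config, rng)
        observation = observation_function(action, reward)
        agent.observe(action, observation)
        actions[i], rewards[i], observations[i] = action, reward, observation

    trials = pd.DataFrame(
        {
            "participant_id": participant_id,
            "run": sequence.run,
            "trial": trial_in_run,
            "s1": sequence.s1,
            "s2": sequence.s2,
            "action": actions,
            "reward": rewards,
            "observation": observations,
            "valid": 1,
        }
    )
    meta = {
        "kind": params.kind,
        "tau": params.tau,
        "lam": params.lam,
        "participant_id": participant_id,
    }
    return ChoiceDataset(trials=trials, meta=meta)


def simulate_cohort(
    params: AgentParams,
    config: TaskConfig | None = None,
    n_datasets: int = 24,
    seed: int = 0,
    sequence: StateSequence | None = None,
    shared_sequence: bool = True,
) -> list[ChoiceDataset]:
    """Simulate a cohort of independent agents.

    By default all agents play the same state sequence (mirroring an
    experiment in which every participant saw the identical trial sequence);
    with ``shared_sequence=False`` each dataset gets its own sequence drawn
    from the per-dataset seed.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    config = config or TaskConfig()
    master = np.random.SeedSequence(seed)
    seq_seed, *dataset_seeds = master.spawn(n_datasets + 1)
    if sequence is None and shared_sequence:
        sequence = generate_state_sequence(config, seq_seed.generate_state(1)[0] % 2**31)
    cohort = []
    for i, sub_seed in enumerate(dataset_seeds):
        seq_i = sequence
        if seq_i is None:
            seq_i = generate_state_sequence(
                config, sub_seed.generate_state(2)[1] % 2**31
            )
        cohort.append(
            simulate_dataset(
                params,
                seq_i,
                config,
                seed=sub_seed,
                participant_id=f"sim-{i:03d}",
            )
        )
    return cohort
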
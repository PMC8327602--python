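"""Belief-state filtering and the five agent valence functions.

The Bayesian agents track a single scalar belief ``b = p(s1 = 1 | history)``
— the probability that the square is currently the lucrative shape — via a
two-state hidden Markov filter: a Bayes step on the trial's outcome image
followed by mixing with the constant reversal probability.  Five agents map
that belief (or, for the belief-free controls, the raw outcome history) to
action valences:

* ``C1`` — random choice: every available action gets valence 0.5.
* ``C2`` — win-stay-lose-switch on signaled outcomes; masked outcomes carry
  the previous shape preference over.
* ``A1`` — exploitation: belief-weighted expected reward.
* ``A2`` — directed exploration: expected Bayesian surprise, the posterior-
  predictive-weighted KL divergence between next and current belief.
* ``A3`` — hybrid: convex combination ``lam * A1 + (1 - lam) * A2``.

All agents hand their valences to an argmax decision rule (ties broken by a
seeded fair draw); the stochastic softmax embedding lives in
:mod:`revbandit.likelihood`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .task import INFORMATIVE_ACTIONS, SQUARE_ACTIONS, TaskConfig, available_actions

__all__ = [
    "AGENT_KINDS",
    "TransitionModel",
    "AgentParams",
    "C2State",
    "belief_update",
    "transition_only_update",
    "posterior_predictive",
    "valence_C1",
    "valence_C2",
    "valence_A1",
    "expected_bayesian_surprise",
    "valence_A2",
    "valence_A3",
    "decide_argmax",
    "AgentRuntime",
]

AGENT_KINDS = ("C1", "C2", "A1", "A2", "A3")

_EPS = 1e-12  # belief clipping bound before logarithms


@dataclass(frozen=True)
class TransitionModel:
    """Symmetric between-trial reversal model of the hidden state.

    ``switch_prob`` is the agent's constant per-trial reversal probability
    (3 reversals / 80 trials = 0.0375 under the default design).
    """

    stay_prob: float = 0.9625
    switch_prob: float = 0.0375

    def __post_init__(self) -> None:
        if not math.isclose(self.stay_prob + self.switch_prob, 1.0, abs_tol=1e-12):
            raise ValueError("stay_prob + switch_prob must equal 1")
        if not 0.0 <= self.switch_prob <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")

    @classmethod
    def from_config(cls, config: TaskConfig) -> "TransitionModel":
        p = config.reversals_per_run / config.trials_per_run
        return cls(stay_prob=1.0 - p, switch_prob=p)


@dataclass(frozen=True)
class AgentParams:
    """Agent kind plus its free parameters.

    ``tau`` is the softmax post-decision noise temperature (used by the data
    analysis models and stochastic simulation; irrelevant for C1), ``lam``
    the A3 exploitation weight.
    """

    kind: str
    tau: float | None = None
    lam: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in AGENT_KINDS:
            raise ValueError(f"unknown agent kind {self.kind!r}")
        if self.kind == "A3":
            if self.lam is None or not 0.0 <= self.lam <= 1.0:
                raise ValueError("A3 requires lam in [0, 1]")
        elif self.lam is not None:
            raise ValueError(f"lam is only meaningful for A3, not {self.kind}")
        if self.tau is not None and self.tau <= 0:
            raise ValueError("tau must be positive")


def _validate_belief(b: float) -> float:
    if not 0.0 <= b <= 1.0:
        raise ValueError(f"belief must lie in [0, 1], got {b!r}")
    return float(b)


def _observation_likelihoods(
    action: int, observation: int, p_win: float
) -> tuple[float, float]:
    """p(o | s1 = 1, a) and p(o | s1 = 2, a) for a compatible pair."""
    if action in INFORMATIVE_ACTIONS:
        if observation not in (1, 2):
            raise ValueError(
                f"informative action {action} cannot yield observation {observation}"
            )
        # p(win | lucrative) = p_win; square actions win when s1 = 1
        p_rewarded_if_square_lucky = p_win if action in SQUARE_ACTIONS else 1.0 - p_win
        if observation == 2:  # win revealed
            return p_rewarded_if_square_lucky, 1.0 - p_rewarded_if_square_lucky
        return 1.0 - p_rewarded_if_square_lucky, p_rewarded_if_square_lucky
    if observation != 3:
        raise ValueError(
            f"non-informative action {action} cannot yield observation {observation}"
        )
    return 1.0, 1.0


def transition_only_update(
    b: float, transition: TransitionModel = TransitionModel()
) -> float:
    """Pure reversal-mixing step, used when no outcome was observed."""
    b = _validate_belief(b)
    return transition.stay_prob * b + transition.switch_prob * (1.0 - b)


def belief_update(
    b: float,
    action: int,
    observation: int,
    transition: TransitionModel = TransitionModel(),
    p_win: float = 0.85,
) -> float:
    """One filtering step: Bayes on the outcome image, then reversal mixing.

    For a masked outcome (observation 3) the likelihood is flat, so the update
    reduces to the pure transition.
    """
    b = _validate_belief(b)
    l1, l2 = _observation_likelihoods(action, observation, p_win)
    num = l1 * b
    den = num + l2 * (1.0 - b)
    posterior = num / den
    return transition.stay_prob * posterior + transition.switch_prob * (1.0 - posterior)


def posterior_predictive(b: float, action: int, p_win: float = 0.85) -> dict[int, float]:
    """Belief-weighted distribution over the next outcome image."""
    b = _validate_belief(b)
    if action not in (1, 2, 3, 4):
        raise ValueError(f"action must be in 1..4, got {action!r}")
    if action not in INFORMATIVE_ACTIONS:
        return {3: 1.0}
    p_r = p_win if action in SQUARE_ACTIONS else 1.0 - p_win
    p_win_obs = b * p_r + (1.0 - b) * (1.0 - p_r)
    return {1: 1.0 - p_win_obs, 2: p_win_obs}


def valence_C1(available: frozenset[int] | set[int]) -> dict[int, float]:
    """Random-choice control: equal valence for every available action."""
    if not available:
        raise ValueError("available action set must not be empty")
    return {a: 1.0 / len(available) for a in available}


@dataclass
class C2State:
    """Win-stay-lose-switch shape preference carried across trials.

    0.5/0.5 before any signaled outcome; after a revealed win the chosen
    shape goes to 1 and the other to 0 (revealed loss: the reverse); a masked
    outcome leaves the allocation untouched.
    """

    shape_valence: dict[str, float] = field(
        default_factory=lambda: {"square": 0.5, "triangle": 0.5}
    )

    def copy(self) -> "C2State":
        return C2State(dict(self.shape_valence))


def valence_C2(
    state: C2State,
    prev_observation: int | None,
    prev_action: int | None,
    available: frozenset[int] | set[int],
) -> tuple[dict[int, float], C2State]:
    """Win-stay-lose-switch valences and the updated shape preference."""
    if prev_observation is None:
        new_state = state.copy()
    elif prev_observation in (1, 2):
        if prev_action is None:
            raise ValueError("prev_action required when the outcome was revealed")
        chosen = "square" if prev_action in SQUARE_ACTIONS else "triangle"
        other = "triangle" if chosen == "square" else "square"
        stay = 1.0 if prev_observation == 2 else 0.0
        new_state = C2State({chosen: stay, other: 1.0 - stay})
    elif prev_observation == 3:
        new_state = state.copy()
    else:
        raise ValueError(f"observation must be 1, 2 or 3, got {prev_observation!r}")
    valences = {
        a: new_state.shape_valence["square" if a in SQUARE_ACTIONS else "triangle"]
        for a in available
    }
    return valences, new_state


def valence_A1(
    b: float, available: frozenset[int] | set[int], p_win: float = 0.85
) -> dict[int, float]:
    """Belief-weighted expected reward; ignores informativeness.

    Expected reward of the lucrative shape is ``2 p_win - 1`` (0.7 under the
    default design) and its negative for the detrimental shape, so square
    actions are worth ``(2 p_win - 1) (2 b - 1)`` and triangle actions the
    negative.
    """
    b = _validate_belief(b)
    er_lucky = 2.0 * p_win - 1.0
    v_square = er_lucky * (2.0 * b - 1.0)
    return {a: v_square if a in SQUARE_ACTIONS else -v_square for a in available}


def _kl_two_point(b_new: float, b_old: float) -> float:
    """KL divergence between two Bernoulli beliefs, 0 ln 0 := 0."""
    b_new = min(max(b_new, _EPS), 1.0 - _EPS)
    b_old = min(max(b_old, _EPS), 1.0 - _EPS)
    return (1.0 - b_new) * math.log((1.0 - b_new) / (1.0 - b_old)) + b_new * math.log(
        b_new / b_old
    )


def expected_bayesian_surprise(
    b: float,
    action: int,
    transition: TransitionModel = TransitionModel(),
    p_win: float = 0.85,
) -> float:
    """Expected KL divergence between the next and the current belief.

    For an informative action the two reveal outcomes are weighted by the
    posterior predictive; for a non-informative action the next belief is the
    deterministic transition of the current one.
    """
    b = _validate_belief(b)
    predictive = posterior_predictive(b, action, p_win)
    total = 0.0
    for obs, p_obs in predictive.items():
        if p_obs <= 0.0:
            continue
        b_next = belief_update(b, action, obs, transition, p_win)
        total += p_obs * _kl_two_point(b_next, b)
    return total


def valence_A2(
    b: float,
    available: frozenset[int] | set[int],
    transition: TransitionModel = TransitionModel(),
    p_win: float = 0.85,
) -> dict[int, float]:
    """Expected-Bayesian-surprise valence for each available action."""
    return {a: expected_bayesian_surprise(b, a, transition, p_win) for a in available}


def valence_A3(
    b: float,
    available: frozenset[int] | set[int],
    lam: float,
    transition: TransitionModel = TransitionModel(),
    p_win: float = 0.85,
) -> dict[int, float]:
    """Convex combination of exploitation (A1) and exploration (A2)."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lam must lie in [0, 1], got {lam!r}")
    v1 = valence_A1(b, available, p_win)
    v2 = valence_A2(b, available, transition, p_win)
    return {a: lam * v1[a] + (1.0 - lam) * v2[a] for a in available}


def decide_argmax(valences: dict[int, float], rng: np.random.Generator) -> int:
    """Deterministic decision rule; exact ties broken by a seeded fair draw."""
    if not valences:
        raise ValueError("valence map must not be empty")
    best = max(valences.values())
    winners = sorted(a for a, v in valences.items() if v == best)
    if len(winners) == 1:
        return winners[0]
    return int(winners[rng.integers(len(winners))])


class AgentRuntime:
    """Stateful trial-by-trial evaluator shared by simulation and likelihood.

    Maintains the belief state (Bayesian agents) or the shape preference (C2)
    over a run; :meth:`valences` evaluates the agent's valence function for
    the current trial, :meth:`observe` ingests the realized action and
    outcome, and :meth:`skip_trial` propagates the internal state across an
    invalid trial (transition-only belief update, C2 preference unchanged).

    The hot loops below use scalar math rather than the vocabulary functions
    above; the two routes are checked against each other in the test suite.
    """

    def __init__(
        self,
        params: AgentParams,
        transition: TransitionModel = TransitionModel(),
        p_win: float = 0.85,
    ) -> None:
        self.params = params
        self.kind = params.kind
        self.transition = transition
        self.p_win = p_win
        self.reset()

    def reset(self) -> None:
        """Start-of-run state: belief 0.5, flat shape preference."""
        self.b = 0.5
        self.v_square = 0.5
        self.v_triangle = 0.5

    # -- scalar helpers -------------------------------------------------
    def _transition(self, b: float) -> float:
        t = self.transition
        return t.stay_prob * b + t.switch_prob * (1.0 - b)

    def _surprise_pair(self) -> tuple[float, float]:
        """(informative, non-informative) expected Bayesian surprise at b."""
        b = self.b
        p = self.p_win
        # informative: two reveal branches; symmetric in the chosen shape
        p_hi = b * p + (1.0 - b) * (1.0 - p)  # prob. of the likelier reveal
        num = p * b
        post_hi = num / (num + (1.0 - p) * (1.0 - b))
        num = (1.0 - p) * b
        post_lo = num / (num + p * (1.0 - b))
        b_hi = self._transition(post_hi)
        b_lo = self._transition(post_lo)
        v_inf = p_hi * _kl_two_point(b_hi, b) + (1.0 - p_hi) * _kl_two_point(b_lo, b)
        v_non = _kl_two_point(self._transition(b), b)
        return v_inf, v_non

    def valences(self, s2: int) -> dict[int, float]:
        """Valence map over the two actions available under layout ``s2``."""
        acts = available_actions(s2)
        kind = self.kind
        if kind == "C1":
            return {a: 0.5 for a in acts}
        if kind == "C2":
            return {
                a: (self.v_square if a in SQUARE_ACTIONS else self.v_triangle)
                for a in acts
            }
        er = (2.0 * self.p_win - 1.0) * (2.0 * self.b - 1.0)
        if kind == "A1":
            return {a: (er if a in SQUARE_ACTIONS else -er) for a in acts}
        v_inf, v_non = self._surprise_pair()
        if kind == "A2":
            return {a: (v_inf if a in INFORMATIVE_ACTIONS else v_non) for a in acts}
        lam = self.params.lam
        out = {}
        for a in acts:
            v1 = er if a in SQUARE_ACTIONS else -er
            v2 = v_inf if a in INFORMATIVE_ACTIONS else v_non
            out[a] = lam * v1 + (1.0 - lam) * v2
        return out

    def observe(self, action: int, observation: int) -> None:
        """Update the internal state from the realized action and outcome."""
        if self.kind == "C2":
            if observation in (1, 2):
                stay = 1.0 if observation == 2 else 0.0
                if action in SQUARE_ACTIONS:
                    self.v_square, self.v_triangle = stay, 1.0 - stay
                else:
                    self.v_triangle, self.v_square = stay, 1.0 - stay
            return
        if self.kind == "C1":
            return
        b = self.b
        if observation == 3:
            self.b = self._transition(b)
            return
        p = self.p_win
        p_sq = p if action in SQUARE_ACTIONS else 1.0 - p
        l1 = p_sq if observation == 2 else 1.0 - p_sq
        num = l1 * b
        posterior = num / (num + (1.0 - l1) * (1.0 - b))
        self.b = self._transition(posterior)

    def skip_trial(self) -> None:
        """Propagate state across an invalid trial (no action, no outcome)."""
        if self.kind in ("A1", "A2", "A3"):
            self.b = self._transition(self.b)
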
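"""Softmax data-analysis models: conditional likelihood, ML fitting, BIC.

Each agent is embedded in a statistical observation model by passing its
action valences through a softmax with temperature ``tau`` (the random-choice
control C1 is parameter-free and uniform).  The conditional log likelihood of
a dataset replays the recorded actions and outcomes trial by trial,
maintaining the agent's internal state from the record, and sums the log
choice probabilities over valid trials only.  Invalid trials contribute
nothing to the likelihood; across them the belief state is propagated by a
transition-only update and the win-stay-lose-switch preference is carried
over unchanged.

Maximum-likelihood estimation uses bounded multi-start local optimization
(uniform random starts in the box tau in [0.01, 2.5], lam in [0, 1]); the
best restart is reported.  Model evidence is approximated by
``BIC = loglik - (k / 2) ln N`` with ``k`` free parameters and ``N`` valid
choices — a penalized log likelihood on the log-evidence scale (higher is
better; note this differs from the common deviance-scale BIC by a factor
of -2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import optimize

from .agents import AGENT_KINDS, AgentParams, AgentRuntime, TransitionModel
from .simulate import ChoiceDataset, softmax_probabilities
from .task import TaskConfig

__all__ = [
    "PARAM_BOUNDS",
    "FitResult",
    "FittingError",
    "choice_probability",
    "conditional_log_likelihood",
    "fit_ml",
    "bic_score",
    "n_free_params",
]

#: box constraints of the ML estimation
PARAM_BOUNDS = {"tau": (0.01, 2.5), "lam": (0.0, 1.0)}

_FREE_PARAMS = {"C1": 0, "C2": 1, "A1": 1, "A2": 1, "A3": 2}


class FittingError(RuntimeError):
    """Raised when every optimization restart fails."""


def n_free_params(kind: str) -> int:
    """Number of free parameters of a data-analysis model."""
    return _FREE_PARAMS[kind]


@dataclass
class FitResult:
    """Per-dataset, per-model maximum-likelihood fit summary."""

    kind: str
    tau: float | None
    lam: float | None
    log_likelihood: float
    k: int
    n_valid: int
    bic: float
    restarts: list[dict[str, Any]] = field(default_factory=list)

    @property
    def theta(self) -> tuple[float, ...]:
        if self.kind == "C1":
            return ()
        if self.kind == "A3":
            return (self.tau, self.lam)
        return (self.tau,)


def choice_probability(
    kind: str, valences: dict[int, float], tau: float | None
) -> dict[int, float]:
    """Softmax choice distribution over the available actions.

    C1 is uniform for any temperature; all other models require ``tau > 0``.
    """
    if kind not in AGENT_KINDS:
        raise ValueError(f"unknown agent kind {kind!r}")
    if kind == "C1":
        return {a: 1.0 / len(valences) for a in valences}
    if tau is None or tau <= 0:
        raise ValueError("tau must be positive")
    return softmax_probabilities(valences, tau)


def _replay_arrays(dataset: ChoiceDataset) -> tuple[np.ndarray, ...]:
    t = dataset.trials
    return (
        t["run"].to_numpy(np.int64),
        t["s2"].to_numpy(np.int64),
        t["action"].to_numpy(),
        t["observation"].to_numpy(),
        t["valid"].to_numpy(np.int64),
    )


def conditional_log_likelihood(
    dataset: ChoiceDataset,
    kind: str,
    theta: tuple[float, ...] | list[float] = (),
    config: TaskConfig | None = None,
) -> float:
    """Conditional log likelihood of the recorded valid choices under a model.

    ``theta`` is ``()`` for C1, ``(tau,)`` for C2/A1/A2 and ``(tau, lam)``
    for A3.  The agent's internal state is driven by the *recorded* actions
    and outcomes, so the likelihood factorizes over trials.
    """
    config = config or TaskConfig()
    if kind == "C1":
        params = AgentParams("C1")
        tau = None
    elif kind == "A3":
        tau, lam = theta
        params = AgentParams("A3", tau=float(tau), lam=float(lam))
    else:
        (tau,) = theta
        params = AgentParams(kind, tau=float(tau))
    agent = AgentRuntime(
        params, TransitionModel.from_config(config), config.p_reward_lucrative
    )
    run, s2, action, observation, valid = _replay_arrays(dataset)

    total = 0.0
    current_run = None
    for i in range(len(run)):
        if run[i] != current_run:
            current_run = run[i]
            agent.reset()
        if not valid[i]:
            agent.skip_trial()
            continue
        a = int(action[i])
        probs = choice_probability(kind, agent.valences(int(s2[i])), tau)
        p = probs.get(a)
        if p is None:
            raise ValueError(f"recorded action {a} unavailable on trial index {i}")
        if not p > 0.0:
            raise FloatingPointError(f"zero choice probability on trial index {i}")
        total += math.log(p)
        agent.observe(a, int(observation[i]))
    if not math.isfinite(total):
        raise FloatingPointError("non-finite log likelihood")
    return total


def fit_ml(
    dataset: ChoiceDataset,
    kind: str,
    n_restarts: int = 10,
    seed: int | np.random.SeedSequence = 0,
    config: TaskConfig | None = None,
) -> FitResult:
    """Multi-start bounded maximum-likelihood fit of one model to one dataset.

    Start points are sampled uniformly in the parameter box; each restart is
    a bounded L-BFGS-B minimization of the negative conditional log
    likelihood, and the best converged restart is returned.  C1 has no free
    parameter: its log likelihood is ``N ln 0.5`` in closed form.
    """
    config = config or TaskConfig()
    n_valid = dataset.n_valid
    if n_valid == 0:
        raise ValueError("dataset has no valid choices")
    if kind == "C1":
        ll = n_valid * math.log(0.5)
        return FitResult("C1", None, None, ll, 0, n_valid, bic_from(ll, 0, n_valid))

    rng = np.random.default_rng(seed)
    if kind == "A3":
        bounds = [PARAM_BOUNDS["tau"], PARAM_BOUNDS["lam"]]
    else:
        bounds = [PARAM_BOUNDS["tau"]]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def objective(theta: np.ndarray) -> float:
        return -conditional_log_likelihood(dataset, kind, tuple(theta), config)

    best = None
    restarts: list[dict[str, Any]] = []
    failures = []
    for _ in range(n_restarts):
        x0 = lo + rng.random(len(bounds)) * (hi - lo)
        try:
            res = optimize.minimize(
                objective,
                x0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": 1e-6, "gtol": 1e-6},
            )
        except (FloatingPointError, ValueError) as exc:  # pragma: no cover
            failures.append(str(exc))
            continue
        restarts.append(
            {"x0": x0.tolist(), "theta": res.x.tolist(), "loglik": -float(res.fun)}
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FittingError(f"all {n_restarts} restarts failed: {failures}")

    theta = np.clip(best.x, lo, hi)
    ll = -float(best.fun)
    tau = float(theta[0])
    lam = float(theta[1]) if kind == "A3" else None
    k = n_free_params(kind)
    return FitResult(kind, tau, lam, ll, k, n_valid, bic_from(ll, k, n_valid), restarts)


def bic_from(log_likelihood: float, k: int, n_valid: int) -> float:
    """``loglik - (k / 2) ln N`` (log-evidence scale, higher is better)."""
    if n_valid <= 0:
        raise ValueError("N must be positive")
    return log_likelihood - 0.5 * k * math.log(n_valid)


def bic_score(fit: FitResult) -> float:
    """BIC of a completed fit (recomputed from its components)."""
    return bic_from(fit.log_likelihood, fit.k, fit.n_valid)
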
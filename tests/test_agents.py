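"""Belief filtering and agent valence functions."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from revbandit import (
    AgentParams,
    AgentRuntime,
    TransitionModel,
    belief_update,
    decide_argmax,
    expected_bayesian_surprise,
    posterior_predictive,
    valence_A1,
    valence_A2,
    valence_A3,
    valence_C1,
    valence_C2,
)
from revbandit.agents import C2State, transition_only_update

# compatible (action, observation) pairs of the task
COMPATIBLE_PAIRS = [(1, 1), (1, 2), (3, 1), (3, 2), (2, 3), (4, 3)]


def oracle_belief(history, p=0.85, stay=0.9625):
    """Brute-force posterior p(s1_{t+1} = 1 | history) by joint enumeration.

    Enumerates every hidden-state path s1_{1:t+1}, weighting by the uniform
    initial belief, the transition probabilities and the observation
    likelihoods; completely independent of the recursive filter.
    """
    t = len(history)
    switch = 1.0 - stay
    num = den = 0.0
    for path in itertools.product((1, 2), repeat=t + 1):
        w = 0.5
        for k in range(t):
            w *= stay if path[k + 1] == path[k] else switch
        for k, (a, o) in enumerate(history):
            s1 = path[k]
            if a in (2, 4):
                lik = 1.0
            else:
                p_win = (p if s1 == 1 else 1 - p) if a == 1 else (1 - p if s1 == 1 else p)
                lik = p_win if o == 2 else 1.0 - p_win
            w *= lik
        den += w
        if path[-1] == 1:
            num += w
    return num / den


def filtered_belief(history):
    b = 0.5
    for a, o in history:
        b = belief_update(b, a, o)
    return b


class TestBeliefFilter:
    @pytest.mark.parametrize(
        "b,action,obs,expected",
        [
            (0.5, 2, 3, 0.5),  # masked outcome at the symmetric fixed point
            (0.5, 4, 3, 0.5),
            (1.0, 2, 3, 0.9625),  # pure transition row
            (0.5, 1, 2, 0.82375),  # hand-evaluated Bayes + transition step
        ],
    )
    def test_hand_evaluated_updates(self, b, action, obs, expected):
        assert belief_update(b, action, obs) == pytest.approx(expected, abs=1e-12)

    def test_incompatible_action_observation_rejected(self):
        with pytest.raises(ValueError):
            belief_update(0.5, 1, 3)
        with pytest.raises(ValueError):
            belief_update(0.5, 2, 1)

    @pytest.mark.parametrize("length", [1, 2, 3])
    def test_filter_matches_joint_enumeration_short(self, length):
        for history in itertools.product(COMPATIBLE_PAIRS, repeat=length):
            assert filtered_belief(history) == pytest.approx(
                oracle_belief(history), abs=1e-12
            )

    def test_masked_outcomes_contract_geometrically(self):
        b = 0.97
        for _ in range(10):
            b_next = belief_update(b, 4, 3)
            assert (b_next - 0.5) == pytest.approx(0.925 * (b - 0.5), abs=1e-14)
            b = b_next

    def test_reachable_beliefs_stay_interior(self):
        # repeated confirming evidence saturates near, but never at, the bounds
        b = 0.5
        for _ in range(200):
            b = belief_update(b, 1, 2)
        assert b < 0.956
        b = 0.5
        for _ in range(200):
            b = belief_update(b, 1, 1)
        assert b > 0.044

    @given(st.floats(0.0, 1.0), st.sampled_from(COMPATIBLE_PAIRS))
    @settings(max_examples=200, derandomize=True)
    def test_updated_belief_is_a_probability(self, b, pair):
        assert 0.0 <= belief_update(b, *pair) <= 1.0


class TestPosteriorPredictive:
    def test_symmetric_belief_gives_even_odds(self):
        assert posterior_predictive(0.5, 1)[2] == pytest.approx(0.5)

    def test_weighted_mixture(self):
        assert posterior_predictive(0.9, 1)[2] == pytest.approx(0.78)

    def test_masked_action_is_certain(self):
        assert posterior_predictive(0.3, 4) == {3: 1.0}

    @given(st.floats(0.0, 1.0), st.integers(1, 4))
    @settings(max_examples=100, derandomize=True)
    def test_distribution_sums_to_one(self, b, action):
        assert sum(posterior_predictive(b, action).values()) == pytest.approx(1.0)


class TestControlValences:
    def test_random_choice_is_uniform(self):
        assert valence_C1({1, 4}) == {1: 0.5, 4: 0.5}
        assert valence_C1({2, 3}) == {2: 0.5, 3: 0.5}

    def test_first_trial_win_stay_is_flat(self):
        v, _ = valence_C2(C2State(), None, None, {1, 4})
        assert v == {1: 0.5, 4: 0.5}

    def test_win_stay_after_revealed_win(self):
        # chose the square (a=1), saw the moneybag -> stay on square
        v, state = valence_C2(C2State(), 2, 1, {2, 3})
        assert v == {2: 1.0, 3: 0.0}
        assert state.shape_valence == {"square": 1.0, "triangle": 0.0}

    def test_lose_switch_after_revealed_loss(self):
        v, _ = valence_C2(C2State(), 1, 1, {1, 4})
        assert v == {1: 0.0, 4: 1.0}

    def test_masked_outcome_carries_valences_over(self):
        state = C2State({"square": 1.0, "triangle": 0.0})
        v, new_state = valence_C2(state, 3, 2, {1, 4})
        assert v == {1: 1.0, 4: 0.0}
        assert new_state.shape_valence == state.shape_valence

    def test_revealed_outcome_without_action_rejected(self):
        with pytest.raises(ValueError):
            valence_C2(C2State(), 2, None, {1, 4})


class TestBayesianValences:
    def test_expected_reward_at_certainty(self):
        assert valence_A1(1.0, {1, 4})[1] == pytest.approx(0.7)
        assert valence_A1(1.0, {1, 4})[4] == pytest.approx(-0.7)
        assert valence_A1(0.0, {2, 3})[3] == pytest.approx(0.7)

    def test_expected_reward_examples(self):
        assert valence_A1(0.5, {1, 4}) == {1: 0.0, 4: 0.0}
        assert valence_A1(0.25, {1, 4})[1] == pytest.approx(-0.35)

    def test_exploitation_ignores_informativeness(self):
        for b in (0.2, 0.5, 0.8):
            assert valence_A1(b, {1, 4})[1] == pytest.approx(valence_A1(b, {2, 3})[2])

    def test_square_triangle_antisymmetry(self):
        for b in np.linspace(0, 1, 21):
            v = valence_A1(float(b), {1, 4})
            assert v[1] == pytest.approx(-v[4], abs=1e-14)

    def test_surprise_at_flat_belief(self):
        assert expected_bayesian_surprise(0.5, 4) == pytest.approx(0.0, abs=1e-15)
        assert expected_bayesian_surprise(0.5, 1) == pytest.approx(0.2276, abs=5e-4)

    def test_surprise_is_mirror_symmetric_in_belief(self):
        for b in np.linspace(0.01, 0.99, 25):
            for a in (1, 4):
                assert expected_bayesian_surprise(float(b), a) == pytest.approx(
                    expected_bayesian_surprise(float(1 - b), a), abs=1e-12
                )

    def test_informative_surprise_dominates_on_grid(self):
        grid = np.arange(0.01, 0.9901, 0.01)
        v_inf = np.array([expected_bayesian_surprise(float(b), 1) for b in grid])
        v_non = np.array([expected_bayesian_surprise(float(b), 4) for b in grid])
        assert (v_inf >= v_non).all()
        assert (v_inf >= 0).all() and (v_non >= 0).all()

    def test_hybrid_interpolates_between_components(self):
        b = 0.5
        v = valence_A3(b, {1, 4}, 0.5)
        assert v[1] == pytest.approx(0.5 * 0.0 + 0.5 * 0.2276, abs=5e-4)

    def test_hybrid_endpoints_reduce_to_components(self):
        for b in (0.1, 0.5, 0.77):
            assert valence_A3(b, {1, 4}, 1.0) == pytest.approx(valence_A1(b, {1, 4}))
            assert valence_A3(b, {1, 4}, 0.0) == pytest.approx(valence_A2(b, {1, 4}))

    def test_hybrid_rejects_weight_outside_unit_interval(self):
        with pytest.raises(ValueError):
            valence_A3(0.5, {1, 4}, 1.2)

    def test_valences_finite_on_reachable_beliefs(self):
        for b in (0.0441, 0.5, 0.9559):
            for v in (valence_A1(b, {1, 4}), valence_A2(b, {1, 4}), valence_A3(b, {1, 4}, 0.3)):
                assert all(math.isfinite(x) for x in v.values())


class TestDecisionRule:
    def test_strict_maximum_wins(self):
        rng = np.random.default_rng(0)
        assert decide_argmax({1: 0.7, 4: -0.7}, rng) == 1

    def test_exploitation_prefers_lucrative_noninformative(self):
        rng = np.random.default_rng(0)
        v = valence_A1(0.9, {2, 3})
        assert decide_argmax(v, rng) == 2

    def test_exact_ties_split_evenly_over_seeds(self):
        picks = [
            decide_argmax({2: 0.5, 3: 0.5}, np.random.default_rng(s)) for s in range(400)
        ]
        n2 = picks.count(2)
        assert 140 < n2 < 260  # binomial(400, 0.5), ~4 sigma

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            decide_argmax({}, np.random.default_rng(0))


class TestAgentRuntime:
    """The fast scalar runtime must agree with the vocabulary functions."""

    @pytest.mark.parametrize(
        "params",
        [
            AgentParams("A1", tau=0.1),
            AgentParams("A2", tau=0.1),
            AgentParams("A3", tau=0.1, lam=0.3),
        ],
    )
    def test_runtime_valences_match_reference_functions(self, params):
        rng = np.random.default_rng(11)
        runtime = AgentRuntime(params)
        transition = TransitionModel()
        b = 0.5
        for _ in range(100):
            s2 = int(rng.integers(1, 3))
            acts = {1, 4} if s2 == 1 else {2, 3}
            if params.kind == "A1":
                ref = valence_A1(b, acts)
            elif params.kind == "A2":
                ref = valence_A2(b, acts, transition)
            else:
                ref = valence_A3(b, acts, params.lam, transition)
            got = runtime.valences(s2)
            for a in acts:
                assert got[a] == pytest.approx(ref[a], abs=1e-12)
            a = int(rng.choice(sorted(acts)))
            o = 3 if a in (2, 4) else int(rng.integers(1, 3))
            runtime.observe(a, o)
            b = belief_update(b, a, o, transition)
            assert runtime.b == pytest.approx(b, abs=1e-12)

    def test_runtime_c2_matches_reference(self):
        rng = np.random.default_rng(5)
        runtime = AgentRuntime(AgentParams("C2", tau=0.1))
        state = C2State()
        prev_a = prev_o = None
        for _ in range(100):
            s2 = int(rng.integers(1, 3))
            acts = {1, 4} if s2 == 1 else {2, 3}
            ref, state = valence_C2(state, prev_o, prev_a, acts)
            got = runtime.valences(s2)
            assert got == ref
            prev_a = int(rng.choice(sorted(acts)))
            prev_o = 3 if prev_a in (2, 4) else int(rng.integers(1, 3))
            runtime.observe(prev_a, prev_o)

    def test_skip_trial_is_transition_only(self):
        runtime = AgentRuntime(AgentParams("A1", tau=0.1))
        runtime.b = 0.9
        runtime.skip_trial()
        assert runtime.b == pytest.approx(transition_only_update(0.9), abs=1e-15)


class TestAgentParams:
    def test_lambda_only_for_hybrid(self):
        with pytest.raises(ValueError):
            AgentParams("A1", tau=0.1, lam=0.5)
        with pytest.raises(ValueError):
            AgentParams("A3", tau=0.1)  # lam missing

    def test_temperature_must_be_positive(self):
        with pytest.raises(ValueError):
            AgentParams("A1", tau=0.0)
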
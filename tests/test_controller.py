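"""Unit behaviour of the stigmergic learning controller."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from anttow.controller import (
    SLOW_DOWN,
    SPEED_UP,
    ActionOutput,
    AgentState,
    ControllerParams,
    ParameterError,
    PerceptionVector,
    StigmergicAgent,
    instar_update,
    output_neurons,
    perceive,
    reward,
    reward_constants,
    select_action,
    velocity_update,
)


class TestPerceive:
    def test_signs_without_deadband(self):
        p = perceive(0.1, 0.05, 0.01, 0.2, deadband=0.0)
        assert (p.p1, p.p2, p.p3, p.p4) == (1, 1, 1, 1)

    def test_all_zero_inputs(self):
        p = perceive(0.0, 0.0, 0.0, 0.0)
        assert (p.p1, p.p2, p.p3, p.p4) == (0, 0, 0, 0)

    def test_mixed_signs(self):
        p = perceive(-0.2, 0.05, -0.01, 0.0, deadband=0.0)
        assert (p.p1, p.p2, p.p3, p.p4) == (-1, 1, -1, 0)

    def test_deadband_maps_small_magnitudes_to_zero(self):
        p = perceive(0.005, -0.005, 0.5, 0.0, deadband=0.01)
        assert (p.p1, p.p2, p.p3, p.p4) == (0, 0, 1, 0)


class TestOutputNeurons:
    def test_zero_weights_give_zero_outputs(self):
        state = AgentState(v=0.0, v_max=4.0)
        p = PerceptionVector(1, -1, 0, 1)
        assert output_neurons(state, p) == (0.0, 0.0)

    def test_inner_product(self):
        w = np.zeros((4, 2))
        w[:, 0] = [1, 0, 0, 0]
        state = AgentState(v=0.0, v_max=4.0, weights=w)
        p = PerceptionVector(-1, 1, 1, 0)
        a_plus, a_minus = output_neurons(state, p)
        assert a_plus == -1.0 and a_minus == 0.0

    def test_output_bound_from_weight_bound(self):
        params = ControllerParams()  # α/γ = 5
        w = np.full((4, 2), params.w_max)
        state = AgentState(v=0.0, v_max=4.0, weights=w)
        p = PerceptionVector(1, 1, 1, 1)
        a_plus, a_minus = output_neurons(state, p)
        assert abs(a_plus) <= 20.0 and abs(a_minus) <= 20.0


class TestSelectAction:
    def test_tie_favours_speed_up(self, rng):
        params = ControllerParams(epsilon=0.0)
        action = select_action((0.0, 0.0), params, pulling_force=1.0, rng=rng)
        assert action.chosen == SPEED_UP and not action.was_random

    def test_zero_force_forces_speed_up_without_learning(self, rng):
        params = ControllerParams(epsilon=1.0)
        action = select_action((-5.0, 5.0), params, pulling_force=0.0, rng=rng)
        assert action.chosen == SPEED_UP
        assert not action.learning_enabled

    def test_full_exploration_statistics(self, rng):
        params = ControllerParams(epsilon=1.0)
        actions = [
            select_action((1.0, 0.0), params, pulling_force=1.0, rng=rng)
            for _ in range(10_000)
        ]
        assert all(a.was_random for a in actions)
        frac_up = np.mean([a.chosen == SPEED_UP for a in actions])
        assert frac_up == pytest.approx(0.5, abs=0.02)

    def test_epsilon_fraction_within_binomial_bounds(self, rng):
        # 99% binomial bounds for n = 20000, p = 0.2
        params = ControllerParams(epsilon=0.2)
        n = 20_000
        randoms = sum(
            select_action((1.0, 0.0), params, 1.0, rng).was_random
            for _ in range(n)
        )
        se = math.sqrt(n * 0.2 * 0.8)
        assert abs(randoms - 0.2 * n) < 2.576 * se


class TestVelocityUpdate:
    def _action(self, chosen):
        return ActionOutput(0.0, 0.0, chosen, False, True)

    def test_vanishes_at_target_orientation_and_full_speed(self):
        params = ControllerParams()
        state = AgentState(v=4.0, v_max=4.0)
        assert velocity_update(self._action(SPEED_UP), state, 0.0, params) == 0.0

    def test_maximal_command(self):
        params = ControllerParams()  # K_a = 1, K_v = 0.8
        state = AgentState(v=0.0, v_max=4.0)
        cmd = velocity_update(self._action(SPEED_UP), state, math.pi, params)
        assert cmd == pytest.approx(1.8)

    def test_slow_down_sign(self):
        params = ControllerParams()
        state = AgentState(v=4.0, v_max=4.0)
        cmd = velocity_update(self._action(SLOW_DOWN), state, math.pi / 2, params)
        assert cmd == pytest.approx(-0.5)

    def test_faster_agents_are_more_agile(self):
        # at equal v and θ the command magnitude grows with v_max
        params = ControllerParams()
        cmds = [
            abs(velocity_update(self._action(SPEED_UP),
                                AgentState(v=3.0, v_max=vm), 0.3, params))
            for vm in (4.0, 8.0, 12.0)
        ]
        assert cmds[0] < cmds[1] < cmds[2]


class TestReward:
    def test_maximal_reward_at_home_orientation_full_speed(self):
        assert reward(0.0, 0.0, 4.0, 4.0) == pytest.approx(2.0)

    def test_penalty_when_rotating_away(self):
        val = reward(math.pi / 2, 0.1, 4.0, 4.0)
        assert val == pytest.approx(-0.5)

    def test_reward_when_rotating_back(self):
        val = reward(math.pi / 2, -0.1, 0.0, 4.0)
        assert val == pytest.approx(0.5)

    def test_zero_rotation_takes_first_branch(self):
        # the boundary sign(θ·θ̇) = 0 counts as "not rotating"
        assert reward(math.pi / 2, 0.0, 0.0, 4.0) == pytest.approx(0.5)

    def test_signed_penalty_restores_literal_form(self):
        literal = reward(-math.pi / 2, -0.1, 0.0, 4.0, signed_penalty=True)
        assert literal == pytest.approx(0.5)  # −θ/θ_max with θ < 0
        default = reward(-math.pi / 2, -0.1, 0.0, 4.0)
        assert default == pytest.approx(-0.5)


class TestRewardConstants:
    def test_threshold_boundary_is_significant(self):
        assert reward_constants(0.5, (1.0, 0.0), SPEED_UP, tau=0.5) == (1, 0)

    def test_insignificant_change_gives_zero(self):
        assert reward_constants(0.49, (1.0, 0.0), SPEED_UP, tau=0.5) == (0, 0)
        assert reward_constants(-0.49, (1.0, 0.0), SLOW_DOWN, tau=0.5) == (0, 0)

    def test_penalty_goes_to_chosen_neuron_only(self):
        assert reward_constants(-1.0, (0.0, 1.0), SLOW_DOWN, tau=0.5) == (0, -1)
        assert reward_constants(-1.0, (1.0, 0.0), SPEED_UP, tau=0.5) == (-1, 0)


class TestInstarUpdate:
    def test_zero_reinforcement_leaves_weights_unchanged(self):
        params = ControllerParams()
        w = np.arange(8, dtype=float).reshape(4, 2)
        state = AgentState(v=0.0, v_max=4.0, weights=w.copy())
        out = instar_update(state, PerceptionVector(1, 1, 1, 1), (0, 0), params)
        assert np.array_equal(out, w)

    def test_single_step_from_zero(self):
        params = ControllerParams()  # α = 0.1
        state = AgentState(v=0.0, v_max=4.0)
        out = instar_update(state, PerceptionVector(1, 0, 0, 0), (1, 0), params)
        assert out[0, 0] == pytest.approx(0.1)
        assert np.count_nonzero(out) == 1

    def test_persistent_reward_converges_to_alpha_over_gamma(self):
        params = ControllerParams()  # α/γ = 5
        state = AgentState(v=0.0, v_max=4.0)
        p = PerceptionVector(1, 0, 0, 0)
        for _ in range(2000):
            state.weights = instar_update(state, p, (1, 0), params)
        assert state.weights[0, 0] == pytest.approx(5.0, abs=1e-6)

    @given(
        st.lists(
            st.tuples(
                st.sampled_from([-1, 0, 1]), st.sampled_from([-1, 0, 1]),
                st.sampled_from([-1, 0, 1]), st.sampled_from([-1, 0, 1]),
                st.sampled_from([-1, 0, 1]), st.sampled_from([-1, 0, 1]),
            ),
            min_size=1, max_size=60,
        )
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_weights_never_exceed_alpha_over_gamma(self, seq):
        """Eq-4.6 bound under arbitrary reinforcement/perception sequences."""
        params = ControllerParams()
        state = AgentState(v=0.0, v_max=4.0)
        for p1, p2, p3, p4, r1, r2 in seq:
            state.weights = instar_update(
                state, PerceptionVector(p1, p2, p3, p4), (r1, r2), params
            )
            assert np.all(np.abs(state.weights) <= params.w_max + 1e-12)


class TestStigmergicAgent:
    def test_first_epoch_forced_speed_up_without_learning(self):
        agent = StigmergicAgent(v_max=4.0, rng=np.random.default_rng(0))
        agent.decide(theta=0.0, pulling_force=0.0)
        action = agent.history[0]
        assert action.chosen == SPEED_UP and not action.learning_enabled
        assert np.all(agent.weights == 0.0)

    def test_large_penalty_event_updates_weights(self):
        params = ControllerParams(epsilon=0.0)
        agent = StigmergicAgent(v_max=12.0, params=params,
                                rng=np.random.default_rng(1))
        agent.decide(theta=0.0, pulling_force=100.0)       # E = 1 + v/v_max
        agent.decide(theta=-0.4, pulling_force=100.0)      # rotating away: E < 0
        assert np.any(agent.weights != 0.0)

    def test_zero_force_epochs_never_learn(self):
        agent = StigmergicAgent(v_max=4.0, rng=np.random.default_rng(2))
        for theta in (0.0, -0.5, 0.5, -1.0):
            agent.decide(theta=theta, pulling_force=0.0)
        assert np.all(agent.weights == 0.0)
        assert all(a.chosen == SPEED_UP for a in agent.history)

    def test_speed_clamped_to_capability(self):
        agent = StigmergicAgent(v_max=4.0, rng=np.random.default_rng(3))
        for _ in range(100):
            agent.integrate_speed(10.0, dt=0.1)
        assert agent.state.v == 4.0
        for _ in range(100):
            agent.integrate_speed(-10.0, dt=0.1)
        assert agent.state.v == 0.0


def test_invalid_controller_parameters_rejected():
    with pytest.raises(ParameterError):
        ControllerParams(epsilon=1.5)
    with pytest.raises(ParameterError):
        ControllerParams(gamma=-0.1)
    with pytest.raises(ParameterError):
        ControllerParams(tau=-1.0)
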
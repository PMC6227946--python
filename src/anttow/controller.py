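"""Decentralized stigmergic speed controller for one transporter.

Each agent in a towing team runs a two-layer neural network whose inputs are
the *signs* of the load's orientation, angular velocity and angular
acceleration plus the sign of the agent's own recent speed change, and whose
two output neurons vote for a binary action: speed up or slow down.  Action
selection is ε-greedy.  The executed action sets a velocity command

    v̇ = ± [ K_a |θ| / θ_max + K_v (1 − v / v_max) ],

positive for speed-up, negative for slow-down, so that agents with higher
maximum speeds are inherently more agile and the adjustment grows with the
load's angular excursion.  After each decision epoch the agent evaluates a
reward that pays for keeping the load near its initial orientation while
moving fast, penalizes rotation away from it, and converts significant
reward changes (|ΔE| ≥ τ) into ±1 reinforcement of the neuron that produced
the action via the Instar rule

    w_ij ← (1 − γ r_j) w_ij + α r_j p_i ,

with weights saturated at ±α/γ.  An agent that measures zero pulling force
(slack string) speeds up without learning.  Coordination is purely
stigmergic: the only shared signal is the motion of the load itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ControllerParams",
    "PerceptionVector",
    "AgentState",
    "ActionOutput",
    "SPEED_UP",
    "SLOW_DOWN",
    "perceive",
    "output_neurons",
    "select_action",
    "velocity_update",
    "reward",
    "reward_constants",
    "instar_update",
    "StigmergicAgent",
]

SPEED_UP = "speed_up"
SLOW_DOWN = "slow_down"
_ACTION_COLUMN = {SPEED_UP: 0, SLOW_DOWN: 1}


class ParameterError(ValueError):
    """Invalid controller parameters."""


@dataclass(frozen=True)
class ControllerParams:
    """Learning and control gains.

    Defaults are the adaptive-towing experiment settings: ε = 0.2 random
    actions, forgetting rate γ = 0.02, learning rate α = 0.1, reward
    significance threshold τ = 0.5, orientation gain K_a = 1, speed gain
    K_v = 0.8, θ_max = π, decisions at 0.5 Hz.

    ``signed_penalty`` restores the literal signed penalty branch −θ/θ_max of
    the reward (negative only for θ > 0); the default penalizes the
    magnitude, −|θ|/θ_max, so that rotating away from the initial
    orientation is punished on both sides.

    ``deadband`` is the sensing resolution applied to the sign perceptions
    and to the reward's rotation test: a finite-differenced θ̇ below it
    reads as "not rotating" (first reward branch), as it would through a
    real sensor.  Without it, sub-resolution orientation drifts pin the
    reward in the penalty branch at a near-constant value, where no action
    can produce a significant reward change and learning stalls.
    """

    epsilon: float = 0.2
    gamma: float = 0.02
    alpha: float = 0.1
    tau: float = 0.5
    K_a: float = 1.0
    K_v: float = 0.8
    theta_max: float = math.pi
    decision_rate: float = 0.5
    deadband: float = 0.01
    signed_penalty: bool = False
    force_zero_tol: float = 1e-9

    def __post_init__(self) -> None:
        for name in ("epsilon", "gamma", "alpha"):
            val = getattr(self, name)
            if not (0.0 <= val <= 1.0):
                raise ParameterError(f"{name} must be in [0, 1], got {val}")
        if self.tau < 0:
            raise ParameterError(f"tau must be >= 0, got {self.tau}")
        if self.K_a < 0 or self.K_v < 0:
            raise ParameterError("gains K_a, K_v must be >= 0")
        if self.theta_max <= 0:
            raise ParameterError(f"theta_max must be > 0, got {self.theta_max}")
        if self.decision_rate <= 0:
            raise ParameterError("decision_rate must be > 0")

    @property
    def w_max(self) -> float:
        """Maximum attainable weight magnitude α/γ (∞ when γ = 0)."""
        return math.inf if self.gamma == 0 else self.alpha / self.gamma


@dataclass(frozen=True)
class PerceptionVector:
    """Signs (−1/0/+1) of θ, θ̇, θ̈ and the agent's own v̇."""

    p1: int
    p2: int
    p3: int
    p4: int

    def __post_init__(self) -> None:
        for comp in self.as_array():
            if comp not in (-1, 0, 1):
                raise ParameterError(f"perception components must be signs, got {comp}")

    def as_array(self) -> np.ndarray:
        return np.array([self.p1, self.p2, self.p3, self.p4], dtype=float)


@dataclass
class AgentState:
    """One transporter: current speed, capability, and learned weights."""

    v: float
    v_max: float
    weights: np.ndarray = field(default_factory=lambda: np.zeros((4, 2)))
    last_reward: float | None = None
    pulling_force: float = 0.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (4, 2):
            raise ParameterError(f"weights must be 4x2, got {self.weights.shape}")
        if self.v_max <= 0:
            raise ParameterError(f"v_max must be > 0, got {self.v_max}")
        self.v = min(max(self.v, 0.0), self.v_max)


@dataclass(frozen=True)
class ActionOutput:
    """Outcome of one ε-greedy decision."""

    a_plus: float
    a_minus: float
    chosen: str
    was_random: bool
    learning_enabled: bool


def _sign(x: float, deadband: float) -> int:
    if abs(x) <= deadband:
        return 0
    return 1 if x > 0 else -1


def perceive(
    theta: float,
    theta_dot: float,
    theta_ddot: float,
    v_dot: float,
    deadband: float = 0.0,
) -> PerceptionVector:
    """Sign-based perception of the load's rotational state and own v̇.

    Magnitudes at or below ``deadband`` map to 0, modelling the finite
    resolution of the rotation sensing (on hardware the deadband would
    absorb sensor noise; the reward threshold τ provides the significance
    filtering on top).
    """
    return PerceptionVector(
        p1=_sign(theta, deadband),
        p2=_sign(theta_dot, deadband),
        p3=_sign(theta_ddot, deadband),
        p4=_sign(v_dot, deadband),
    )


def output_neurons(state: AgentState, p: PerceptionVector) -> tuple[float, float]:
    """Output activations (a_plus, a_minus) = pᵀ W."""
    a = p.as_array() @ state.weights
    return float(a[0]), float(a[1])


def select_action(
    outputs: tuple[float, float],
    params: ControllerParams,
    pulling_force: float,
    rng: np.random.Generator,
) -> ActionOutput:
    """ε-greedy action selection with the slack-string override.

    Zero measured pulling force forces a speed-up with learning disabled
    for the epoch (a slack agent receives no stigmergic signal from its own
    action).  Otherwise a uniform-random action is taken with probability ε
    (still learned from), else the larger output neuron wins, ties going to
    speed-up.
    """
    a_plus, a_minus = outputs
    if pulling_force <= params.force_zero_tol:
        return ActionOutput(a_plus, a_minus, SPEED_UP, False, False)
    if rng.random() < params.epsilon:
        chosen = SPEED_UP if rng.random() < 0.5 else SLOW_DOWN
        return ActionOutput(a_plus, a_minus, chosen, True, True)
    chosen = SPEED_UP if a_plus >= a_minus else SLOW_DOWN
    return ActionOutput(a_plus, a_minus, chosen, False, True)


def velocity_update(
    action: ActionOutput,
    state: AgentState,
    theta: float,
    params: ControllerParams,
) -> float:
    """Acceleration command v̇ for the chosen action.

    Magnitude K_a|θ|/θ_max + K_v(1 − v/v_max); the caller integrates the
    command and clamps the speed to [0, v_max].
    """
    magnitude = params.K_a * abs(theta) / params.theta_max + params.K_v * (
        1.0 - state.v / state.v_max
    )
    return magnitude if action.chosen == SPEED_UP else -magnitude


def reward(
    theta: float,
    theta_dot: float,
    v: float,
    v_max: float,
    theta_max: float = math.pi,
    signed_penalty: bool = False,
) -> float:
    """Stigmergic reward E for the load state an action produced.

    When the load is rotating back toward its initial orientation, sitting
    at it, or not rotating (sign(θ·θ̇) ≤ 0), the agent is paid for small
    orientation error and for speed:  (θ_max − |θ|)/θ_max + v/v_max.
    Otherwise it is penalized by the orientation error, −|θ|/θ_max
    (or the literal signed −θ/θ_max when ``signed_penalty``).
    """
    if v_max <= 0:
        raise ParameterError("v_max must be > 0")
    if theta * theta_dot <= 0:
        return (theta_max - abs(theta)) / theta_max + v / v_max
    if signed_penalty:
        return -theta / theta_max
    return -abs(theta) / theta_max


def reward_constants(
    delta_E: float,
    outputs: tuple[float, float],
    chosen: str,
    tau: float,
) -> tuple[int, int]:
    """Reinforcement constants (r_plus, r_minus), each in {−1, 0, +1}.

    Only the neuron of the executed action is reinforced: +1 when the reward
    rose by at least τ, −1 when it fell by at least τ, 0 otherwise (τ
    separates meaningful changes from noise).  The boundary |ΔE| = τ counts
    as significant.
    """
    if tau < 0:
        raise ParameterError(f"tau must be >= 0, got {tau}")
    if delta_E >= tau:
        r = 1
    elif delta_E <= -tau:
        r = -1
    else:
        r = 0
    pair = [0, 0]
    pair[_ACTION_COLUMN[chosen]] = r
    return tuple(pair)


def instar_update(
    state: AgentState,
    p: PerceptionVector,
    r: tuple[int, int],
    params: ControllerParams,
) -> np.ndarray:
    """Instar weight update, returning the new 4×2 matrix.

    w_ij ← (1 − γ r_j) w_ij + α r_j p_i for each output neuron j, then
    saturated at ±α/γ.  The saturation is required: for r_j = −1 the map is
    expansive, so the nominal bound α/γ is enforced explicitly.  γ = 0 with
    nonzero reinforcement is permitted but leaves the weights unbounded.
    """
    pv = p.as_array()
    rv = np.asarray(r, dtype=float)
    w = (1.0 - params.gamma * rv[None, :]) * state.weights + (
        params.alpha * rv[None, :] * pv[:, None]
    )
    if params.gamma > 0:
        # saturate only the reinforced columns; r_j = 0 leaves a column
        # untouched even if it already exceeds the nominal bound
        updated = rv != 0
        w[:, updated] = np.clip(w[:, updated], -params.w_max, params.w_max)
    return w


class StigmergicAgent:
    """Full decision loop of one learning transporter (run at decision_rate).

    At each epoch the agent (1) differentiates the sensed load orientation
    with backward differences to obtain θ̇ and θ̈ and its own v̇, (2) scores
    the previous epoch's action with the reward change E(t) − E(t−1) and
    applies the Instar update to that action's neuron with the *current*
    perception (the rotational context persists across epochs, so the
    pattern present when the reward arrives is the one the corrected
    action must respond to), skipping the update whenever the measured
    pulling force is zero, (3) selects a new ε-greedy action (forced
    speed-up when the force reads zero), and (4) emits the velocity
    command to hold until the next epoch.
    """

    def __init__(
        self,
        v_max: float,
        params: ControllerParams | None = None,
        rng: np.random.Generator | None = None,
        v0: float = 0.0,
    ) -> None:
        self.params = params or ControllerParams()
        self.state = AgentState(v=v0, v_max=v_max)
        self.rng = rng if rng is not None else np.random.default_rng()
        self._dt = 1.0 / self.params.decision_rate
        self._theta_prev: float | None = None
        self._theta_dot_prev: float | None = None
        self._v_prev: float = self.state.v
        self._prev_action: ActionOutput | None = None
        self._prev_perception: PerceptionVector | None = None
        self.history: list[ActionOutput] = []

    @property
    def weights(self) -> np.ndarray:
        return self.state.weights

    def decide(self, theta: float, pulling_force: float) -> float:
        """One decision epoch; returns the v̇ command (cm/s²) to hold."""
        params = self.params
        dt = self._dt

        theta_dot = 0.0 if self._theta_prev is None else (theta - self._theta_prev) / dt
        theta_ddot = (
            0.0
            if self._theta_dot_prev is None
            else (theta_dot - self._theta_dot_prev) / dt
        )
        v_dot = (self.state.v - self._v_prev) / dt

        sensed_theta_dot = 0.0 if abs(theta_dot) <= params.deadband else theta_dot
        E_now = reward(
            theta,
            sensed_theta_dot,
            self.state.v,
            self.state.v_max,
            params.theta_max,
            params.signed_penalty,
        )

        p = perceive(theta, theta_dot, theta_ddot, v_dot, params.deadband)

        prev = self._prev_action
        if (
            prev is not None
            and self.state.last_reward is not None
            and pulling_force > params.force_zero_tol
        ):
            delta_E = E_now - self.state.last_reward
            r = reward_constants(
                delta_E, (prev.a_plus, prev.a_minus), prev.chosen, params.tau
            )
            self.state.weights = instar_update(self.state, p, r, params)

        outputs = output_neurons(self.state, p)
        action = select_action(outputs, params, pulling_force, self.rng)
        accel = velocity_update(action, self.state, theta, params)

        self.state.last_reward = E_now
        self.state.pulling_force = pulling_force
        self._prev_action = action
        self._prev_perception = p
        self._theta_prev = theta
        self._theta_dot_prev = theta_dot
        self._v_prev = self.state.v
        self.history.append(action)
        return accel

    def integrate_speed(self, accel: float, dt: float) -> float:
        """Advance the commanded speed by ``accel·dt``, clamped to [0, v_max]."""
        self.state.v = min(max(self.state.v + accel * dt, 0.0), self.state.v_max)
        return self.state.v
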
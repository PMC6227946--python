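"""Planar rigid-load towing environment with string attachments.

A rigid load (modelled as a rod along its leading edge) is towed in the +x
direction by agents connected to anchors on that edge through inextensible,
tension-only strings.  Translation follows Newton's law with kinetic
friction, restricted to the transport direction; rotation is overdamped,
c_θ θ̇ = net torque of string tensions about the centroid.  A taut agent
pulls with the ideal-motor tension F = K (v_agent − w), where w is its
anchor's recession speed along the string — so stiff taut strings couple
speed differences into load rotation kinematically and a slower member's
string anchors its side of the load.  Slack strings transmit nothing; an
agent overtaken by the load is dragged and resists with its body's sliding
friction; agents that would overstretch their string are projected back
onto the taut circle (pacing at the string radius).

Two experiment drivers share this physics:

``run_adaptive_towing``
    Heterogeneous maximum speeds, every agent running the stigmergic
    learning controller at the decision rate, attachment points drawn at
    random each trial.  Reproduces convergence of the load speed to the
    slowest member's maximum.

``run_intermittent_towing``
    Homogeneous commanded speeds with duty-cycled force application (the
    out-of-phase stepping model); no learning.  Reproduces the
    team-size-invariant speed of the binomial-gait model, and, for
    heterogeneous teams, the uncoordinated failure in which the load is
    pulled into the slowest agent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .controller import ControllerParams, StigmergicAgent
from .load_dynamics import GaitSchedule, LoadParams, steady_state_speed

__all__ = [
    "PayloadState",
    "Attachment",
    "TrialResult",
    "SimResult",
    "step_physics",
    "run_adaptive_towing",
    "run_intermittent_towing",
    "default_rotational_resistance",
    "adaptive_load_params",
    "intermittent_load_params",
]

#: Half-span of the anchor mounting region on the leading edge, cm.  Anchors
#: are confined to the central part of the 76.2 cm frame: towing is only
#: coordinable when speed differences rotate the load fast enough to sense,
#: i.e. when anchor separations stay below ~2 × the string length.
EDGE_SPAN = 15.0
#: Minimum separation between sampled anchors, cm (one sensor suite each).
MIN_SEPARATION = 7.0
#: Stepping-experiment geometry: anchors evenly spaced across the full frame
#: with short leads (the wide parallel configuration maximizes the passive
#: string-tilt torque that keeps an unsteered load tracking straight).
STEPPING_EDGE_SPAN = 30.0
STEPPING_STRING_LENGTH = 30.0
#: Towing string length, cm.
STRING_LENGTH = 60.0
#: Torsional drag of the dragged frame: c_θ = TORSIONAL_DRAG_FACTOR ×
#: TWIST_FRICTION_COEFF × m g (dyn·cm per rad/s).  Twisting the frame slides
#: its contact points sideways, so the torsional drag scales with the load's
#: weight through a surface friction coefficient that is independent of the
#: (possibly much lower) rolling resistance to forward motion.  Calibrated so
#: a lone agent pulling at full steady force off-centre turns the 500 g
#: adaptive-experiment load at roughly 0.1 rad/s; see docs/methods.md.
TORSIONAL_DRAG_FACTOR = 200.0
TWIST_FRICTION_COEFF = 0.01
#: Anchor-to-agent distance below which the load has run into the agent.
COLLISION_DISTANCE = 2.0
#: Slack beyond this fraction of the string length marks disengagement.
DISENGAGE_SLACK_FRACTION = 0.5
#: Sustained-condition window for the divergence flag, s.
FLAG_WINDOW = 5.0
#: Uncoordinated transport: some agent's mean commanded speed exceeds the
#: steady-state load speed by more than this ratio (its towing effort is
#: wasted in slip/drag instead of transport).
SPEED_EXCESS_THRESHOLD = 1.5
#: Sliding-friction resistance of a dragged (overtaken, stalled) agent, dyn:
#: μ ≈ 0.3 on a ~300 g robot body.
AGENT_DRAG = 0.3 * 300.0 * 981.0
#: Maximum lateral speed (as a fraction of forward speed) an agent spends
#: steering back to its assigned lane.
LANE_KEEPING_FRACTION = 0.2


class SimulationError(RuntimeError):
    """Non-finite state encountered during integration."""


@dataclass
class PayloadState:
    """Planar pose of the load and its first derivatives.

    ``speed`` is the (non-negative) translation speed along the transport
    direction x̂; ``omega`` is the most recent overdamped rotation rate.
    """

    x: float = 0.0
    y: float = 0.0
    theta: float = 0.0
    speed: float = 0.0
    omega: float = 0.0


@dataclass
class Attachment:
    """One string anchor: signed offset along the leading edge, agent pose."""

    offset: float
    string_length: float
    agent_x: float
    agent_y: float
    taut: bool = True
    slack: float = 0.0
    dragged: bool = False


def default_rotational_resistance(params: LoadParams) -> float:
    """Overdamped torsional drag c_θ of the dragged load, dyn·cm·s/rad."""
    return TORSIONAL_DRAG_FACTOR * TWIST_FRICTION_COEFF * params.m * params.g_accel


def adaptive_load_params(team_vmax) -> LoadParams:
    """Default load for the adaptive experiment: 500 g, stiff motors."""
    return LoadParams(m=500.0, mu_k=0.01, K=20000.0, v_max=max(team_vmax))


def intermittent_load_params(team_vmax, n: int | None = None) -> LoadParams:
    """Default load for the stepping experiment: 500 g per agent, soft coupling.

    The soft gain and low effective friction put the load in the regime
    where it integrates the binomially fluctuating force over many strides
    (relaxation time m/(p_f N K) ≈ 20 s) instead of halting in every
    all-swing gap; see docs/methods.md.
    """
    n = len(team_vmax) if n is None else n
    return LoadParams(m=500.0 * n, mu_k=1e-4, K=50.0, v_max=max(team_vmax))


def _anchor_position(payload: PayloadState, offset: float) -> tuple[float, float]:
    s, c = math.sin(payload.theta), math.cos(payload.theta)
    return payload.x - offset * s, payload.y + offset * c


def step_physics(
    payload: PayloadState,
    attachments: list[Attachment],
    commanded_speeds,
    params: LoadParams,
    rotational_resistance: float,
    dt: float,
    engaged=None,
) -> tuple[PayloadState, list[float]]:
    """Advance the load and agents one time step; returns per-agent forces.

    ``engaged`` masks force application (gait contact windows); bodies
    advance regardless.  Each taut, engaged agent exerts the ideal-motor
    tension F_i = K (v_i − w_i) along its string, where w_i is the anchor's
    recession speed along the string including the rotational contribution
    — so taut strings couple the agents' speed differences into load
    rotation kinematically (a pair of stiff strings at offsets d₁, d₂
    yields θ̇ → (v₂ − v₁)/(d₁ − d₂)).  Translation is a semi-implicit
    Newton update with kinetic friction (clamped at v = 0); rotation is
    overdamped, c_θ θ̇ = net torque, with torsional drag ``rotational_resistance``.
    The coupled (v, θ̇) system is linear for a fixed active set and solved
    exactly, with tension-negative strings dropped iteratively (strings
    cannot push).  Afterwards agents advance at their commanded speeds and
    are projected back onto the taut circle where the string would
    overstretch.
    """
    n = len(attachments)
    if len(commanded_speeds) != n:
        raise ValueError("attachments and commanded_speeds must have equal length")
    if engaged is None:
        engaged = [True] * n

    m, K = params.m, params.K
    f_fric = params.friction_force
    c_theta = rotational_resistance

    # String geometry before the step: direction cosines g_i (transport
    # component) and torque levers L_i = (r_i × û_i)_z.
    s, c = math.sin(payload.theta), math.cos(payload.theta)
    g = [1.0] * n
    lever = [0.0] * n
    puller = [False] * n
    dragged = [False] * n
    for i, att in enumerate(attachments):
        ax, ay = _anchor_position(payload, att.offset)
        dx, dy = att.agent_x - ax, att.agent_y - ay
        dist = math.hypot(dx, dy)
        att.taut = dist >= att.string_length * (1.0 - 1e-9)
        att.slack = max(att.string_length - dist, 0.0)
        if dist > 1e-6:
            g[i], lever[i] = dx / dist, 0.0
            uy = dy / dist
            rx, ry = -att.offset * s, att.offset * c
            lever[i] = rx * uy - ry * g[i]
        # Agents overtaken by the load (string pointing backwards) are
        # dragged along: their stalled bodies resist with sliding friction
        # transmitted through the taut string.
        puller[i] = att.taut and engaged[i] and g[i] > 0.0
        dragged[i] = att.taut and g[i] <= 0.0
        att.dragged = dragged[i]

    drag_x = sum(AGENT_DRAG * g[i] for i in range(n) if dragged[i])
    drag_torque = sum(AGENT_DRAG * lever[i] for i in range(n) if dragged[i])

    v = payload.speed
    active = [i for i in range(n) if puller[i]]
    v_new, omega = v, 0.0
    forces = [0.0] * n
    for _ in range(n + 1):
        s_gg = sum(g[i] * g[i] for i in active)
        s_gl = sum(g[i] * lever[i] for i in active)
        s_ll = sum(lever[i] * lever[i] for i in active)
        s_vg = sum(commanded_speeds[i] * g[i] for i in active)
        s_vl = sum(commanded_speeds[i] * lever[i] for i in active)
        a11 = m / dt + K * s_gg
        a12 = K * s_gl
        a21 = K * s_gl
        a22 = c_theta + K * s_ll
        b1 = m * v / dt + K * s_vg - f_fric + drag_x
        b2 = K * s_vl + drag_torque
        det = a11 * a22 - a12 * a21
        v_new = (b1 * a22 - a12 * b2) / det
        omega = (a11 * b2 - a21 * b1) / det
        if v_new < 0.0 or (v <= 0.0 and K * s_vg + drag_x <= f_fric):
            v_new = 0.0
            omega = b2 / a22
        for i in range(n):
            forces[i] = AGENT_DRAG if dragged[i] else 0.0
        drop = False
        for i in active:
            t_i = K * (commanded_speeds[i] - (v_new * g[i] + omega * lever[i]))
            if t_i < 0.0:
                drop = True
            else:
                forces[i] = t_i
        if not drop:
            break
        active = [
            i
            for i in active
            if K * (commanded_speeds[i] - (v_new * g[i] + omega * lever[i])) >= 0.0
        ]

    payload.speed = v_new
    payload.omega = omega
    payload.theta += omega * dt
    if payload.theta > math.pi:
        payload.theta = math.pi
    elif payload.theta < -math.pi:
        payload.theta = -math.pi

    payload.x += payload.speed * dt

    # Agents walk (holding their assigned lane), then re-normalize against
    # the new anchor positions.  Lane-keeping counters the secular lateral
    # drift that taut-circle projections would otherwise accumulate.
    for i, att in enumerate(attachments):
        att.agent_x += commanded_speeds[i] * dt
        lane_err = att.offset - att.agent_y
        max_step = LANE_KEEPING_FRACTION * max(commanded_speeds[i], 0.5) * dt
        att.agent_y += max(-max_step, min(max_step, lane_err))
        ax, ay = _anchor_position(payload, att.offset)
        dx, dy = att.agent_x - ax, att.agent_y - ay
        dist = math.hypot(dx, dy)
        if dist > att.string_length:
            scale = att.string_length / dist
            att.agent_x = ax + dx * scale
            att.agent_y = ay + dy * scale
            att.taut = True
            att.slack = 0.0
        else:
            att.taut = dist >= att.string_length * (1.0 - 1e-9)
            att.slack = att.string_length - dist

    if not (math.isfinite(payload.speed) and math.isfinite(payload.theta)):
        raise SimulationError("non-finite payload state")
    return payload, forces


@dataclass
class TrialResult:
    """Time series and summary flags for one towing trial."""

    times: np.ndarray
    load_speed: np.ndarray
    theta: np.ndarray
    per_agent_speed: np.ndarray  # (n_agents, n_samples)
    weights: list[np.ndarray]
    offsets: np.ndarray
    steady_state_mean: float
    theta_abs_p95: float
    drag_fraction: float
    speed_excess: float
    diverged: bool
    disengaged: bool
    collision: bool

    @property
    def uncoordinated(self) -> bool:
        """Uncoordinated transport: the load diverged in orientation, or a
        transporter kept commanding a speed far above what the load achieved
        (the dragged-along failure; slack/drag diagnostics are reported
        separately because transient episodes also occur during normal
        adaptation)."""
        return self.diverged or self.speed_excess > SPEED_EXCESS_THRESHOLD


@dataclass
class SimResult:
    """Across-trial summary of a towing experiment."""

    trials: list[TrialResult]
    team_vmax: tuple[float, ...]
    steady_state_mean: float
    steady_state_ci: tuple[float, float]
    trial_means: np.ndarray
    min_vmax: float
    prediction: float | None
    n_uncoordinated: int
    seed: int | None
    mode: str

    @property
    def uncoordinated_fraction(self) -> float:
        return self.n_uncoordinated / len(self.trials)

    @property
    def uncoordinated(self) -> bool:
        """Run-level verdict: a majority of trials flagged."""
        return self.n_uncoordinated > len(self.trials) / 2


def _t_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """t-based confidence interval for the mean of ``values``."""
    values = np.asarray(values, dtype=float)
    n = values.size
    mean = float(values.mean())
    if n < 2:
        return (mean, mean)
    half = float(
        stats.t.ppf(0.5 + level / 2, n - 1) * values.std(ddof=1) / math.sqrt(n)
    )
    return (mean - half, mean + half)


def _sample_offsets(
    n: int, rng: np.random.Generator, span: float, min_sep: float
) -> np.ndarray:
    """Random anchor offsets: one uniform draw per equal segment of the edge.

    Mirrors the parallel mounting configuration in which the transporters
    are distributed across the load's leading edge: the edge is divided
    into n equal segments and each anchor is placed uniformly at random
    within its segment, with a minimum separation enforced.  A single agent
    attaches at the midpoint.
    """
    if n == 1:
        return np.zeros(1)
    edges = np.linspace(-span, span, n + 1)
    for _ in range(10_000):
        cand = np.array([rng.uniform(edges[i], edges[i + 1]) for i in range(n)])
        if np.all(np.diff(cand) >= min_sep):
            return cand
    raise SimulationError("could not place anchors with the requested separation")


def _sustained(mask: np.ndarray, sample_dt: float, window: float) -> bool:
    """True if ``mask`` holds over any contiguous stretch of ``window`` s."""
    need = max(int(round(window / sample_dt)), 1)
    run = 0
    for flag in mask:
        run = run + 1 if flag else 0
        if run >= need:
            return True
    return False


def _flags(
    theta: np.ndarray,
    slack: np.ndarray,
    dist: np.ndarray,
    dragged: np.ndarray,
    sample_dt: float,
    string_length: float,
    start: int,
) -> tuple[bool, bool, bool]:
    """Uncoordinated-transport detectors.

    diverged   — |θ| pinned at π over a sustained window (steady state);
    disengaged — an agent's string slack beyond half its length, or an agent
                 towed backwards by the load (taut string pointing against
                 the transport direction), sustained in steady state;
    collision  — the load ran into an agent at any point in the run (the
                 "load pulled into the slowest robot" event precedes the
                 steady-state window).
    """
    pinned = np.abs(theta[start:]) >= 0.999 * math.pi
    diverged = _sustained(pinned, sample_dt, FLAG_WINDOW)
    loose = slack[:, start:] > DISENGAGE_SLACK_FRACTION * string_length
    disengaged = any(_sustained(row, sample_dt, FLAG_WINDOW) for row in loose) or any(
        _sustained(row, sample_dt, FLAG_WINDOW) for row in dragged[:, start:]
    )
    collision = bool((dist < COLLISION_DISTANCE).any())
    return diverged, disengaged, collision


def _run_trial(
    team_vmax,
    load: LoadParams,
    rotational_resistance: float,
    duration: float,
    dt: float,
    rng_children,
    controller: ControllerParams | None,
    gait: GaitSchedule | None,
    string_length: float,
    span: float,
    min_sep: float,
    transient_fraction: float,
    record_every: int,
    even_offsets: bool,
) -> TrialResult:
    n_agents = len(team_vmax)
    trial_rng = np.random.default_rng(rng_children[0])

    if even_offsets:
        offsets = (
            np.zeros(1) if n_agents == 1 else np.linspace(-span, span, n_agents)
        )
    else:
        offsets = _sample_offsets(n_agents, trial_rng, span, min_sep)

    payload = PayloadState()
    attachments = [
        Attachment(
            offset=float(d),
            string_length=string_length,
            agent_x=string_length,  # start taut, straight ahead of the anchor
            agent_y=float(d),
        )
        for d in offsets
    ]

    adaptive = controller is not None
    if adaptive:
        agents = [
            StigmergicAgent(
                v_max=vm, params=controller, rng=np.random.default_rng(child)
            )
            for vm, child in zip(team_vmax, rng_children[1:])
        ]
        decision_steps = max(int(round(1.0 / (controller.decision_rate * dt))), 1)
        # Decisions are taken at unit time increments, so the commanded v̇ is
        # a per-decision speed increment: spread it over the epoch.
        accel_scale = controller.decision_rate
        speeds = [0.0] * n_agents
        accels = [0.0] * n_agents
    else:
        active_windows = gait.offsets_for(n_agents, trial_rng)
        speeds = [float(v) for v in team_vmax]

    n_steps = int(round(duration / dt))
    n_rec = n_steps // record_every
    rec_t = np.empty(n_rec)
    rec_v = np.empty(n_rec)
    rec_th = np.empty(n_rec)
    rec_agent_v = np.empty((n_agents, n_rec))
    rec_slack = np.empty((n_agents, n_rec))
    rec_dist = np.empty((n_agents, n_rec))
    rec_dragged = np.zeros((n_agents, n_rec), dtype=bool)

    forces = [0.0] * n_agents
    transient_step = int(transient_fraction * n_steps)
    drag_steps = [0] * n_agents
    # Agents sense the force averaged over the decision epoch ("measures
    # F_k = 0 during some time period"), not an instantaneous sample that
    # can read zero during taut/slack chatter.
    force_accum = [0.0] * n_agents
    rec = 0
    for step in range(n_steps):
        t = step * dt
        if adaptive:
            if step % decision_steps == 0:
                scale = 1.0 / decision_steps
                for k, agent in enumerate(agents):
                    accels[k] = accel_scale * agent.decide(
                        payload.theta, force_accum[k] * scale
                    )
                    force_accum[k] = 0.0
            for k, agent in enumerate(agents):
                speeds[k] = agent.integrate_speed(accels[k], dt)
            engaged = None
        else:
            phase = (t - active_windows) % gait.t_s
            engaged = list(phase < gait.t_c)

        payload, forces = step_physics(
            payload, attachments, speeds, load, rotational_resistance, dt, engaged
        )
        if adaptive:
            for k in range(n_agents):
                force_accum[k] += forces[k]
        if step >= transient_step:
            for k, att in enumerate(attachments):
                if att.dragged:
                    drag_steps[k] += 1

        if (step + 1) % record_every == 0:
            rec_t[rec] = t + dt
            rec_v[rec] = payload.speed
            rec_th[rec] = payload.theta
            for k, att in enumerate(attachments):
                rec_agent_v[k, rec] = speeds[k]
                rec_slack[k, rec] = att.slack
                ax, ay = _anchor_position(payload, att.offset)
                rec_dist[k, rec] = math.hypot(att.agent_x - ax, att.agent_y - ay)
                rec_dragged[k, rec] = att.taut and att.agent_x < ax
            rec += 1

    sample_dt = record_every * dt
    start = int(transient_fraction * n_rec)
    window_steps = n_steps - transient_step
    drag_fraction = max(drag_steps) / window_steps if window_steps else 0.0
    ss_load = float(rec_v[start:].mean())
    vbar_max = max(
        float(rec_agent_v[k, start:].mean()) for k in range(n_agents)
    )
    speed_excess = (vbar_max - ss_load) / max(ss_load, 0.1)
    diverged, disengaged, collision = _flags(
        rec_th, rec_slack, rec_dist, rec_dragged, sample_dt, string_length, start
    )
    return TrialResult(
        times=rec_t,
        load_speed=rec_v,
        theta=rec_th,
        per_agent_speed=rec_agent_v,
        weights=[a.weights.copy() for a in agents] if adaptive else [],
        offsets=offsets,
        steady_state_mean=ss_load,
        theta_abs_p95=float(np.percentile(np.abs(rec_th[start:]), 95)),
        drag_fraction=drag_fraction,
        speed_excess=speed_excess,
        diverged=diverged,
        disengaged=disengaged,
        collision=collision,
    )


def run_adaptive_towing(
    team_vmax,
    controller: ControllerParams | None = None,
    load: LoadParams | None = None,
    trials: int = 10,
    duration: float = 600.0,
    seed: int | None = None,
    dt: float = 0.01,
    rotational_resistance: float | None = None,
    string_length: float = STRING_LENGTH,
    edge_span: float = EDGE_SPAN,
    min_separation: float = MIN_SEPARATION,
    transient_fraction: float = 0.5,
    record_every: int = 10,
) -> SimResult:
    """Adaptive-team experiment: every agent learns via stigmergic feedback.

    Anchor offsets are drawn uniformly (minimum separation enforced) for
    each trial; a single agent attaches at the midpoint.  Returns per-trial
    steady-state means and their across-trial mean with a t-based 95%
    confidence interval.
    """
    team_vmax = tuple(float(v) for v in team_vmax)
    if trials < 1:
        raise ValueError("trials must be >= 1")
    controller = controller or ControllerParams()
    load = load or adaptive_load_params(team_vmax)
    c_r = (
        default_rotational_resistance(load)
        if rotational_resistance is None
        else rotational_resistance
    )

    n_agents = len(team_vmax)
    children = np.random.SeedSequence(seed).spawn(trials)
    results = []
    for child in children:
        sub = child.spawn(n_agents + 1)
        results.append(
            _run_trial(
                team_vmax, load, c_r, duration, dt, sub, controller, None,
                string_length, edge_span, min_separation, transient_fraction,
                record_every, even_offsets=False,
            )
        )
    means = np.array([r.steady_state_mean for r in results])
    return SimResult(
        trials=results,
        team_vmax=team_vmax,
        steady_state_mean=float(means.mean()),
        steady_state_ci=_t_ci(means),
        trial_means=means,
        min_vmax=min(team_vmax),
        prediction=None,
        n_uncoordinated=sum(r.uncoordinated for r in results),
        seed=seed,
        mode="adaptive",
    )


def run_intermittent_towing(
    team_vmax,
    gait: GaitSchedule,
    load: LoadParams | None = None,
    trials: int = 10,
    duration: float = 400.0,
    seed: int | None = None,
    dt: float = 0.01,
    rotational_resistance: float | None = None,
    string_length: float = STEPPING_STRING_LENGTH,
    edge_span: float = STEPPING_EDGE_SPAN,
    transient_fraction: float = 0.5,
    record_every: int = 10,
) -> SimResult:
    """Out-of-phase stepping experiment: constant commanded speeds, gated force.

    Agents walk continuously at their maximum speed and apply the motor
    force only during gait contact windows (stride phases drawn uniformly
    per trial).  Anchors are evenly spaced, mirroring the parallel test
    configuration.  For a homogeneous team the analytic steady state of the
    binomial-gait model is attached as ``prediction``.
    """
    team_vmax = tuple(float(v) for v in team_vmax)
    if trials < 1:
        raise ValueError("trials must be >= 1")
    load = load or intermittent_load_params(team_vmax)
    c_r = (
        default_rotational_resistance(load)
        if rotational_resistance is None
        else rotational_resistance
    )

    homogeneous = len(set(team_vmax)) == 1
    prediction = (
        steady_state_speed(load, len(team_vmax), gait.p_f) if homogeneous else None
    )
    children = np.random.SeedSequence(seed).spawn(trials)
    results = []
    for child in children:
        results.append(
            _run_trial(
                team_vmax, load, c_r, duration, dt, child.spawn(1), None, gait,
                string_length, edge_span, MIN_SEPARATION, transient_fraction,
                record_every, even_offsets=True,
            )
        )
    means = np.array([r.steady_state_mean for r in results])
    return SimResult(
        trials=results,
        team_vmax=team_vmax,
        steady_state_mean=float(means.mean()),
        steady_state_ci=_t_ci(means),
        trial_means=means,
        min_vmax=min(team_vmax),
        prediction=prediction,
        n_uncoordinated=sum(r.uncoordinated for r in results),
        seed=seed,
        mode="intermittent",
    )
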
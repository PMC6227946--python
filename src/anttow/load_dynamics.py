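"""Intermittent, constant-force towing of a dragged load.

A homogeneous team of N walkers tows a load along a line.  Each walker pulls
with an ideal-motor force F = K(v_max − v_L) during the ground-contact phase
of its gait and exerts no force during the swing phase, so at any instant the
number of pullers is n ~ Binomial(N, p_f) with duty cycle p_f = t_c / t_s
(contact time over stride period, phases independently and uniformly offset).
The load obeys Newton's law with kinetic friction,

    m dv_L/dt = n(t) K (v_max − v_L) − μ_k m g        (v_L kept ≥ 0),

whose time-averaged steady state is the closed form

    ‖v_L‖_ss = v_max − μ_k m g / (p_f N K),

reducing to the continuous-pulling result at p_f = 1.  Because the slowing
term scales as m/N, constant mass per walker implies a team-size-invariant
speed — the signature of this model.

Two stepping modes are provided.  ``dynamics="newton"`` (default) integrates
the equation above; the load coasts through brief all-swing gaps and the
long-run mean converges to the closed form.  ``dynamics="quasistatic"`` drops
inertia entirely: speed is the instantaneous force balance and is exactly 0
whenever no walker pulls.  The quasi-static mode honours the
stops-immediately contract but its time average is biased away from the
closed form by the n = 0 fraction and the nonlinearity in n, so the Newtonian
mode is the one validated against the prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "LoadParams",
    "GaitSchedule",
    "LoadTrajectory",
    "ActiveCountFit",
    "pulling_fraction",
    "steady_state_speed",
    "simulate_intermittent",
    "active_count_distribution",
]

#: Standard gravity in CGS units (cm/s^2).
G_CGS = 981.0


class ParameterError(ValueError):
    """Invalid physical or gait parameters."""


@dataclass(frozen=True)
class LoadParams:
    """Physical parameters of the towed load, CGS units (cm, g, s).

    m        : load mass, g
    mu_k     : kinetic friction coefficient of load on ground
    K        : motor gain, force per unit speed deficit (dyn·s/cm)
    v_max    : no-load maximum walker speed, cm/s
    g_accel  : gravitational acceleration, cm/s^2
    direction: unit transport direction (the model is one-dimensional; the
               direction is carried for the planar simulator)
    """

    m: float
    mu_k: float
    K: float
    v_max: float
    g_accel: float = G_CGS
    direction: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ParameterError(f"mass must be > 0, got {self.m}")
        if self.mu_k < 0:
            raise ParameterError(f"mu_k must be >= 0, got {self.mu_k}")
        if self.K <= 0:
            raise ParameterError(f"motor gain K must be > 0, got {self.K}")
        if self.v_max <= 0:
            raise ParameterError(f"v_max must be > 0, got {self.v_max}")
        norm = math.hypot(*self.direction)
        if not math.isclose(norm, 1.0, rel_tol=1e-9):
            raise ParameterError(f"direction must be a unit vector, |d|={norm}")

    @property
    def friction_force(self) -> float:
        """Kinetic friction magnitude μ_k m g, dyn."""
        return self.mu_k * self.m * self.g_accel


@dataclass(frozen=True)
class GaitSchedule:
    """Duty-cycled gait: pulling during [offset, offset + t_c) mod t_s.

    t_c : ground-contact (pulling) time per stride, s
    t_s : stride period, s  (0 < t_c < t_s; impulsive gaits out of scope)
    phase_offsets : per-agent stride start times in [0, t_s); if None the
        simulator draws them independently and uniformly at random.
    """

    t_c: float
    t_s: float
    phase_offsets: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not (0 < self.t_c < self.t_s):
            raise ParameterError(
                f"gait requires 0 < t_c < t_s, got t_c={self.t_c}, t_s={self.t_s}"
            )
        if self.phase_offsets is not None:
            object.__setattr__(self, "phase_offsets", tuple(self.phase_offsets))
            if any(not (0 <= o < self.t_s) for o in self.phase_offsets):
                raise ParameterError("phase offsets must lie in [0, t_s)")

    @property
    def p_f(self) -> float:
        return self.t_c / self.t_s

    def offsets_for(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.phase_offsets is not None:
            if len(self.phase_offsets) != n:
                raise ParameterError(
                    f"{len(self.phase_offsets)} phase offsets given for {n} agents"
                )
            return np.asarray(self.phase_offsets, dtype=float)
        return rng.uniform(0.0, self.t_s, size=n)

    def active_matrix(self, times: np.ndarray, offsets: np.ndarray) -> np.ndarray:
        """Boolean (n_agents, n_times): is each agent in its contact phase."""
        phase = (times[None, :] - offsets[:, None]) % self.t_s
        return phase < self.t_c


def pulling_fraction(gait: GaitSchedule) -> float:
    """Probability p_f = t_c / t_s that a walker is pulling at a given instant."""
    return gait.p_f


def steady_state_speed(params: LoadParams, N: int, p_f: float) -> float:
    """Closed-form steady-state load speed, clamped at zero.

    max(0, v_max − μ_k m g / (p_f N K)); p_f = 1 is continuous pulling.
    """
    if N < 1:
        raise ParameterError(f"N must be >= 1, got {N}")
    if not (0 < p_f <= 1):
        raise ParameterError(f"p_f must be in (0, 1], got {p_f}")
    return max(0.0, params.v_max - params.friction_force / (p_f * N * params.K))


@dataclass
class LoadTrajectory:
    """Time-stepped record of a duty-cycled towing run."""

    times: np.ndarray
    load_speed: np.ndarray
    active_count: np.ndarray
    steady_state_mean: float
    prediction: float
    feasible: bool
    N: int
    p_f: float
    dt: float
    seed: int | None
    offsets: np.ndarray = field(repr=False)
    dynamics: str = "newton"


def _integrate_newton(
    params: LoadParams, n_active: np.ndarray, dt: float
) -> np.ndarray:
    """Semi-implicit Euler for m v̇ = nK(v_max − v) − μmg, with v clamped ≥ 0.

    At v = 0 the load starts moving only once the available motor force
    n K v_max exceeds the friction threshold.
    """
    m, K, vmax = params.m, params.K, params.v_max
    f_fric = params.friction_force
    v = 0.0
    out = np.empty(n_active.size)
    for i, n in enumerate(n_active):
        if v <= 0.0 and n * K * vmax <= f_fric:
            v = 0.0
        else:
            drive = n * K * vmax - f_fric
            v = (v + dt * drive / m) / (1.0 + dt * n * K / m)
            if v < 0.0:
                v = 0.0
        out[i] = v
    return out


def simulate_intermittent(
    params: LoadParams,
    gait: GaitSchedule,
    N: int,
    duration: float,
    dt: float = 0.01,
    seed: int | None = None,
    dynamics: str = "newton",
    transient_fraction: float = 0.5,
) -> LoadTrajectory:
    """Simulate N duty-cycled walkers towing the load for ``duration`` seconds.

    Phase offsets are drawn uniformly in [0, t_s) (or taken from the gait),
    each walker pulls with the ideal-motor force during its contact windows,
    and the steady-state mean is taken over the final
    ``1 − transient_fraction`` of the run.  Infeasible parameter sets (the
    closed form predicts zero speed) are flagged, not raised.
    """
    if N < 1:
        raise ParameterError(f"N must be >= 1, got {N}")
    if dt <= 0 or dt > gait.t_c / 5:
        raise ParameterError(f"dt must satisfy 0 < dt << t_c, got dt={dt}")
    if duration < 20 * gait.t_s:
        raise ParameterError(
            f"duration must cover at least 20 stride periods ({20 * gait.t_s} s)"
        )
    if dynamics not in ("newton", "quasistatic"):
        raise ParameterError(f"unknown dynamics mode {dynamics!r}")

    rng = np.random.default_rng(seed)
    offsets = gait.offsets_for(N, rng)
    n_steps = int(round(duration / dt))
    times = (np.arange(n_steps) + 1) * dt
    active = gait.active_matrix(times, offsets)
    n_active = active.sum(axis=0)

    if dynamics == "quasistatic":
        with np.errstate(divide="ignore"):
            deficit = np.where(
                n_active > 0, params.friction_force / (n_active * params.K), np.inf
            )
        speed = np.maximum(0.0, params.v_max - deficit)
        speed[n_active == 0] = 0.0
    else:
        speed = _integrate_newton(params, n_active, dt)

    start = int(transient_fraction * n_steps)
    ss_mean = float(speed[start:].mean())
    prediction = steady_state_speed(params, N, gait.p_f)
    return LoadTrajectory(
        times=times,
        load_speed=speed,
        active_count=n_active.astype(int),
        steady_state_mean=ss_mean,
        prediction=prediction,
        feasible=prediction > 0.0,
        N=N,
        p_f=gait.p_f,
        dt=dt,
        seed=seed,
        offsets=offsets,
        dynamics=dynamics,
    )


@dataclass(frozen=True)
class ActiveCountFit:
    """Empirical active-puller distribution against Binomial(N, p_f)."""

    N: int
    p_f: float
    observed: np.ndarray
    expected: np.ndarray
    mean_active: float
    tv_distance: float
    chisq: float
    ok: bool


def active_count_distribution(
    trajectories: "LoadTrajectory | Sequence[LoadTrajectory]",
    N: int,
    p_f: float,
    tol: float = 0.05,
) -> ActiveCountFit:
    """Compare pooled active-count time fractions with Binomial(N, p_f).

    Within a single trial the time fractions are set by the fixed phase
    offsets; the binomial law describes the ensemble over random offsets, so
    pooling several independently seeded trajectories is the meaningful
    check.  ``ok`` is a total-variation tolerance (the chi-square statistic
    is reported for reference; time samples are autocorrelated so it is not
    a calibrated test).
    """
    if isinstance(trajectories, LoadTrajectory):
        trajectories = [trajectories]
    counts = np.concatenate([t.active_count for t in trajectories])
    observed = np.bincount(counts, minlength=N + 1).astype(float)
    observed /= observed.sum()
    expected = stats.binom.pmf(np.arange(N + 1), N, p_f)
    tv = 0.5 * float(np.abs(observed - expected).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = (observed - expected) ** 2 / expected
    chisq = float(np.nansum(contrib))
    return ActiveCountFit(
        N=N,
        p_f=p_f,
        observed=observed,
        expected=expected,
        mean_active=float(counts.mean()),
        tv_distance=tv,
        chisq=chisq,
        ok=tv <= tol,
    )
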
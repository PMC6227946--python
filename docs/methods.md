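# Methods

`anttow` implements and tests two competing mechanistic explanations for a
robust observation about cooperative towing in ant teams: the steady-state
transport speed *decreases* with team size even when the load mass per
transporter is held constant.

## 1. Order statistics of a truncated speed distribution

Individual maximum towing speed is modelled as Gaussian with the fitted
parameters μ = 0.7 cm s⁻¹ and σ = 0.36 cm s⁻¹, truncated to [0, 1.2] cm s⁻¹
(slightly above the fastest observed individual) and renormalized to total
probability 1. If a team of n transporters must travel at the pace of its
slowest member, the team speed is the first-order statistic of n draws.
With ϕ, Φ the truncated pdf/cdf, the r-th order statistic has

    E(r, n)   = C(r,n) ∫ v Φ(v)^(r−1) [1 − Φ(v)]^(n−r) ϕ(v) dv,
    Var(r, n) = C(r,n) ∫ (v − E)² Φ^(r−1) (1 − Φ)^(n−r) ϕ dv,

with the combinatorial constant C(r, n) = n!/((r−1)!(n−r)!).

**Numerics.** The integrals are evaluated after the substitution u = Φ(v),
giving ∫₀¹ f(Q(u)) · Beta(r, n−r+1)(u) du with Q the truncated quantile
function, by adaptive quadrature (absolute tolerance 1e-10). This form is
well conditioned uniformly in σ: in the σ → 0 limit the integrand tends to
the constant μ, whereas a v-space quadrature cannot locate a near-degenerate
spike on a finite interval. The sampling cross-check draws by inverse cdf
(exact, reproducible under a seed), takes team minima, and compares means
and variances at three standard errors; the variance SE is moment-based,
sqrt((m₄ − s⁴)/reps).

For the fitted distribution, E(1, 1) = 0.6629 cm s⁻¹ (closed form and
quadrature agree to < 1e-8) and E(1, n) declines strictly with n —
the predicted signature of slowest-member adaptation.

## 2. Intermittent, constant-force towing

The alternative explanation is out-of-phase stepping: each of N identical
walkers pulls only during the ground-contact fraction p_f = t_c/t_s of its
stride (contact time 1.5 s in a 3 s stride ⇒ p_f = 0.5), with stride phases
independent and uniform. At any instant the number of pullers is
Binomial(N, p_f). Each puller exerts the ideal-motor force K(v_max − v_L);
the load slides against kinetic friction μ_k m g. Time-averaging the force
balance gives the closed form

    ‖v_L‖_ss = v_max − μ_k m g / (p_f N K),

which is invariant under constant mass per walker (m ∝ N) — the signature
that distinguishes this model from the order-statistics one.

**Simulation mode.** The default integrator is Newtonian (semi-implicit
Euler, dt = 0.01 s): the load carries inertia and coasts through brief
all-swing gaps. This is not incidental. A strictly quasi-static (zero
inertia) stepping rule makes the instantaneous speed max(0, v_max −
μ_k m g/(n(t)K)), whose time average is a binomial mixture that differs
from the closed form by a Jensen gap plus the n = 0 stop fraction — for
N = 2, p_f = 0.5, the load would be stopped 25% of the time and the mean
would undershoot the prediction by far more than any reasonable tolerance.
The closed form is a *time-averaged force balance*, and recovering it
requires the load to integrate the fluctuating force over the stride. The
default parameters (m = 500 g per walker, K = 50 dyn·s/cm, μ_k = 1e-4,
i.e. a low-resistance, caster-like payload) put the relaxation time
m/(p_f N K) ≈ 20 s well above the stride period; runs last 400 s and
average the second half. Simulated means then match the closed form to
about 0.1% and are team-size invariant. A `dynamics="quasistatic"` mode is
retained; it honours the stops-immediately contract exactly and is the
right mode for studying the stop-and-go limit, but its long-run mean is
biased below the closed form for the reason above.

## 3. Stigmergic learning controller

Each transporter runs a two-layer network at 0.5 Hz. Inputs are the signs
of the load's orientation θ, its finite-differenced derivatives θ̇, θ̈, and
the agent's own speed change; the two outputs vote for speed-up vs
slow-down (ε-greedy, ε = 0.2; ties favour speed-up). The executed action
commands a speed change of magnitude K_a|θ|/θ_max + K_v(1 − v/v_max)
(K_a = 1, K_v = 0.8, θ_max = π) — faster agents are inherently more agile.
The reward pays (θ_max − |θ|)/θ_max + v/v_max while the load is not
rotating away from its initial orientation and penalizes |θ|/θ_max
otherwise; reward changes of at least τ = 0.5 reinforce (±1) the neuron of
the executed action through the Instar rule
w ← (1 − γr)w + αr·p (α = 0.1, γ = 0.02), saturated at ±α/γ = 5.
An agent measuring zero pulling force speeds up without learning.

Decisions the implementation had to make, and why:

- **Saturation.** For r = −1 the Instar map is expansive (w ← (1+γ)w − αp
  diverges away from the α/γ fixed point), so the nominal bound α/γ is
  enforced as an explicit clip; without it adversarial reinforcement
  sequences grow weights without bound.
- **Credit timing.** The update at epoch t credits the action executed
  over (t−1, t] — the one whose outcome the reward change measures — using
  the *current* perception p(t). Because the rotational context persists
  across epochs, p(t) is the pattern under which the corrected action
  preference must apply. Binding the *previous* perception instead leaves
  the very first branch-flip penalty (the largest single learning event
  from a standing start) unlearnable, and the team never converges.
- **Force measurement.** The pulling force is averaged over the decision
  epoch. Instantaneous sampling reads spurious zeros during taut/slack
  chatter, which disables learning at exactly the epochs that matter.
- **Velocity semantics.** Decisions are taken at unit time increments, so
  the commanded v̇ is applied as a per-decision speed increment (Δv per
  epoch equals the commanded magnitude).
- **Sensing deadband (0.01 rad, rad/s).** The reward's branch test uses
  the finite-differenced θ̇; without a resolution floor it responds to
  sub-milliradian-per-second numerical drifts, pinning the reward at a
  constant value where no action can produce |ΔE| ≥ τ and learning
  freezes. The deadband reads "below resolution" as "not rotating", as a
  physical sensor would.
- **Penalty sign.** The penalty branch uses −|θ|/θ_max so that rotating
  away is punished for either sign of θ; `signed_penalty=True` restores
  the literal signed form, which only penalizes positive θ.
- **Initial weights** are zero (unbiased; with the tie rule the first
  greedy action is speed-up, matching the transport incentive).

## 4. Planar towing simulator

A rigid load (modelled as its 76 cm leading edge) is towed in +x by agents
attached through inextensible, tension-only strings to anchors at signed
offsets along the edge. Translation is Newtonian with kinetic friction,
restricted to the transport direction. Rotation is overdamped,
c_θ θ̇ = net torque of string tensions, with torsional drag
c_θ = 200 × 0.01 × m g. The twist coefficient (0.01) is deliberately
independent of the translational rolling resistance: twisting the frame
slides its contact points sideways against ordinary surface friction even
when it rolls forward easily, and tying c_θ to a low translational μ_k
makes the orientation of the stepping-experiment load a near-free
coordinate that random active-set asymmetries walk away from. The
combined factor is calibrated so a lone agent pulling at full steady
force off-centre turns the 500 g load at roughly 0.1 rad s⁻¹.
Crucially, each taut
agent's motor tension is K(v_agent − w) with w the *anchor's* recession
speed along the string, including the rotational term: stiff taut strings
therefore couple speed differences kinematically — a pair of strings at
offsets d₁, d₂ rotates the load at (v₁ − v₂)/(d₂ − d₁), and a slower
member's string anchors its side. The coupled (v, θ̇) system is linear for
a fixed set of tension-positive strings and is solved exactly each step,
dropping strings that would push.

Additional physical elements, each load-bearing for the observed
behaviour:

- **Dragged-agent resistance.** An agent overtaken by the load (string
  taut backwards) is dragged and resists with the sliding friction of its
  stalled body (0.3 × 300 g × g ≈ 0.9 N). Dragging a teammate is therefore
  expensive: the load cannot outrun its slowest member for long. This
  mirrors the wheel-slip stalling seen when heterogeneous teams pull
  intermittently without adaptation.
- **Lane-keeping.** Agents steer back to their assigned lateral lane at up
  to 20% of forward speed. Without it, taut-circle projections accumulate
  a secular lateral drift that collapses the team onto the centreline and
  sends long runs into a degenerate single-file geometry.
- **Anchor geometry.** For the adaptive experiment, anchors are confined
  to the central ±15 cm of the edge with ≥ 7 cm separation (one per equal
  segment, uniform within it, mirroring the parallel mounting
  configuration), and strings are 60 cm. Coordination requires both: wide
  anchor separations make the kinematic rotation per unit speed
  difference too slow to sense above the deadband, and short strings
  leave too little slack budget for the team to survive the pre-learning
  transient without an overtake. The stepping experiment, which has no
  steering, instead uses the full-frame configuration (even spacing
  across ±30 cm, 30 cm leads), which maximizes the passive string-tilt
  torque that keeps the load tracking straight.

**Adaptive experiment.** Teams of [4, 12], [4, 8, 12] and [4, 6, 9, 12]
cm s⁻¹ on a 500 g load (K = 2×10⁴ dyn·s/cm, μ_k = 0.01), ten trials of
600 s, anchors re-drawn each trial, steady state = the second half. The
across-trial 95% t-interval of the steady-state mean load speed contains
4 cm s⁻¹ — the slowest member's maximum — for all three team sizes. The
mechanism is mixed: the two-agent team shows clean learned parity (the
fast member's commanded speed settles at ≈ 4.1–4.4 cm s⁻¹), while in
larger teams learned slowing combines with physical chaining through the
slowest member's string; commanded speeds come down substantially but not
all the way to 4.

**Stepping experiment.** Homogeneous teams (8 cm s⁻¹, 500 g per agent)
with gait-gated forces reproduce the intermittent model closed form within 2% and are
team-size invariant. Agent bodies advance continuously while force is
gated by the contact windows — the intermittency of this model is in force
application, not body motion; a halting body would leave metres of slack
every stride and decouple the model from its own closed form.

**Uncoordinated-transport flag.** A run is flagged when the orientation
pins at ±π for a sustained window, or when some agent's window-mean
commanded speed exceeds the steady-state load speed by more than 1.5× —
persistent wasted towing effort, the dragged-along failure. Heterogeneous
teams under intermittent constant pulling sit at
(v_fastest − v_slowest)/v_slowest = 2.0 structurally (no adaptation ever
happens and the load is chained at the slowest speed), while adaptive
teams stay at ≤ ~1.2; the separation is complete across seeds. Slack- and
collision-based statistics are reported as diagnostics but are not part of
the verdict: transient slack and drag episodes are part of normal
adaptation, and the non-adaptive failure settles into a chained state
whose slack statistics look quiescent. The run-level verdict is a majority
of trials.

## 5. What the synthetic conditions do and do not show

The speed-distribution fixture emulates only the distributional *shape* of
individual towing speeds (truncated Gaussian with the fitted moments); it
contains no trial-to-trial correlations, fatigue, or measurement error.
The towing simulator is noiseless — sensing error enters only through the
deadband — and its unreported physical constants (motor gain, friction,
torsional drag, string length, anchor span, drag of a stalled body) are
package defaults chosen by the analyses above, not measured values. Tests
passing under these conditions show that the models and the controller
behave as theorized in a self-consistent physical world of the right
scale; they do not validate the specific constants against hardware.

Known limitations: orientation regulation in the adaptive experiment is
weaker than speed regulation (|θ| can dwell around 1–1.5 rad in long runs;
the reward is insensitive to slow sub-threshold drifts by construction);
translation is constrained to the transport direction; rotation is
overdamped with a scalar drag; and the learning dynamics, while convergent
in distribution across seeds, retain occasional slow-converging trials
that widen the across-trial confidence intervals.

## 6. Problem sizes

Default run lengths — 600 s adaptive (10 trials/team), 400 s stepping
(10 trials/size), 10⁶-replicate Monte-Carlo oracles — were chosen so each
experiment comfortably exceeds its own relaxation scales (learning
convergence ≈ 100–200 s; load relaxation ≈ 20 s; oracle SE ≈ 3×10⁻⁴ cm/s).
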
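# Methods

## The plant: muscle-tendon unit and mass-spring-friction load

The mechanical load is a 0.900 g mass on a rail, pulled by the muscle
against an extension spring (ks = 35.025 N/m), a viscous damper
(c = 3.500 N·s/m) and Coulomb friction with static/kinetic coefficients
0.120/0.080.  Positive x is the direction of muscle shortening.  The
friction is implemented as standard stick-slip: at rest the static
force cancels the net applied force exactly until it reaches the
breakaway threshold μs·m·g ≈ 1.059 mN; while sliding, the kinetic
magnitude μk·m·g ≈ 0.706 mN opposes the velocity.  A literal
transcription of the published sub-threshold branch
(μs·m·g·sign(ẋ)) is available as `friction_mode="literal"` for
comparison; it applies no force at rest (sign(0) = 0), so a body under
any sub-threshold force would creep — the stick-slip resolution is the
physical default.  Velocity zero-crossings are detected after each
fixed integration step with a 1 µm/s velocity tolerance, and sticking
is re-entered only when the net force is below threshold; this
suppresses sign chatter without event-location machinery.

The spring rest offset x* defaults to 0, making x = 0 with a slack
tendon and relaxed spring an exact equilibrium that satisfies the rest
initial conditions.  The alternative of pre-tensioning the spring by
the 1 g resting tension of the bench preparation is *not* the default
because, combined with a tendon initialized at slack length, it is not
an equilibrium: the pre-tension would have to be carried by a
pre-strained tendon and a passively stretched fiber, contradicting the
fiber-at-optimal-length initial condition.  In this model family the
passive fiber force at optimal length is zero by construction, so the
bench's "1 g at l0M" is read as the length convention used to define
l0M operationally, not as a reproducible static load.

The muscle-tendon unit is a zero-pennation Hill-type model of the
Thelen family: the published constitutive curves and constants of that
model are used directly —

| parameter | value | meaning |
|---|---|---|
| γ | 0.45 | active force-length width (Gaussian in l̃ = lM/l0M) |
| kPE, ε0M | 4, 0.6 | passive exponential shape/strain scale |
| Af | 0.25 | force-velocity curvature |
| F̃len | 1.4 | lengthening force plateau |
| τ_act, τ_deact | 10 ms, 40 ms | activation/deactivation time constants |
| F̃toe, k_toe | 0.33, 3 | tendon toe-region shape |
| k_lin, ε_toe | 42.8, 0.0244 | tendon linear stiffness and transition strain |

Geometry and scale describe a mouse EDL: mean whole-muscle length
10.44 mm and the fiber-to-muscle ratio 0.44 give l0M = 4.59 mm and a
tendon slack length of 5.85 mm; F0M = 0.40 N is a typical tetanic
force for this muscle.  The maximum shortening velocity is set to
vmax = 12 l0M/s — the EDL is among the fastest mammalian muscles, and
values of 10–14 l0M/s are reported for it, versus the generic 10 l0M/s
of the model family.  A 1 mm contraction is ≈ 22 % of l0M, inside the
20–40 % working range of the bench preparation.

The contraction dynamics inverts the force balance
a·f_L·f_V(ṽ) + f_PE = f_T for the fiber velocity.  The inversion is
closed-form on both the shortening and lengthening branches; near the
lengthening plateau (beyond 95 % of F̃len) the hyperbola is continued
linearly so the inverse exists for any demanded force, and the result
is clamped to ±vmax.  A safeguarded bracketing solver
(`method="brentq"`) solves the same balance independently and is used
as the round-trip oracle in the tests (agreement to 1e-9 relative).
At zero active capacity (a·f_L ≈ 0) the fiber parks when the demand is
slack and recoils at the velocity bound when the passive force exceeds
the tendon force; an optional activation floor (`a_min`) is available
but off by default.

## The stimulation channel

The controller effort u carries units of seconds (gains are s/m,
errors are meters).  It is converted to a pulse width saturated in
[0, 200] µs, held over each 10 ms PWM frame, and the duty fraction
pw/200 µs drives the activation dynamics as the excitation.  The
linear duty-fraction recruitment proxy is the single largest modelling
assumption and is isolated in one function so a sigmoidal recruitment
curve can be substituted.

The effort→pulse-width gain is the one free scale of the channel.  It
is frozen at 4.92e4 µs per effort-unit, calibrated once so that the
channel's steady-state gain at the 1 mm operating point equals
b/|a| = 2.43 m of the first-order muscle model (a = −3.5 1/s,
b = 8.5 m/s²) that the adaptive controllers are designed against.
With this single scalar fixed, a least-squares first-order fit of the
simulated open-loop step response returns (a, b) = (−3.56, 8.65),
within 2 % of the design constants — i.e. the composite
muscle-plus-load path seen by the controllers reproduces the effective
linear plant their printed gain tables assume, which is the property
that makes those gain tables meaningful on this testbed.

## Controllers

All control laws update at 250 Hz with explicit-Euler adaptation,
mirroring a real-time implementation; the plant integrates underneath
with fixed-step RK4 at 0.1 ms.  The reference models (first-order for
MRAC, the PI-stabilized 2×2 system for ADP-PI) are advanced by the
exact discretization of their linear ODEs per tick, removing
integration drift from the comparison trajectories.  The Lyapunov
matrix P solves A_rᵀP + P A_r + Q = 0 with Q = I (only positive
definiteness is required; identity is the neutral choice).

Sign conventions: the tracking error is e = x − x_d, and the PI effort
is negated once (`output_sign = −1`) so that a positive step command
produces positive pulse widths; the MRAC and ADP-PI laws carry their
own signs (sign(b) = sign(λ*) = +1: stimulation shortens the muscle).
The PI integral and the ADP-PI integral state both accumulate the
current tick's error before the effort is computed; with zero
adaptation gains and zero initial estimates the ADP-PI law is then
bit-identical to the PI law, a property the tests assert on full
closed-loop runs.  PI anti-windup (conditional integration during
saturation) exists but is off by default, matching the plain textbook
law.

The open-loop "controller" is a fixed effort schedule.  For the step
study the constant is found by bisection on the end-of-run position
(`tune_openloop_effort`), the simulation analogue of tuning by
inspection; the steady-state map from effort to position is monotone,
so bisection is exact up to the stiction dead band.

## Metrics

STE is the mean squared pointwise deviation of the achieved trajectory
from its target — the desired trajectory for PI/open-loop, the
reference trajectory for the adaptive controllers — reported in mm².
The settling time of a step response is the earliest time after which
the trace stays within ±2 % of the 1 mm final value of its target for
the remainder of the record ("reach and maintain": the last band entry
counts, not the first).  For the adaptive controllers the target is
their reference trajectory, the same convention as the STE; for
PI/open-loop on a step the two conventions coincide.  Settling is
reported for steps only; wider bands can only settle earlier (a
property test).

## Verification fixtures

The stability guarantees of the adaptive laws hold for first-order
linear plants with matched uncertainty, not for the full muscle, so
they are verified on exactly those plants:

* MRAC: ẋ = a x + b u with hidden (a, b) = (−1, 1), reference pole −2,
  unit step, γ = 50.  The Lyapunov function built from the hidden
  ideal gains θ*_x = (a_r − a)/b, θ*_r = b_r/b is nonincreasing to
  machine precision and V̇ tracks a_r·e² to within 5 % of its scale.
* ADP-PI: ẋ = a x + b(λ* u + W*ᵀφ(x)) with (a, b) equal to the
  controller's assumed constants, λ* = 1.3,
  W* = [0.01, 0, 0, 0.02] — note the matched uncertainty enters
  through the input channel, multiplied by b.  The ideal weights are
  W*/λ* and (1 − λ*)/λ*·K*; with them, V is nonincreasing and its
  total drop equals ∫e_aᵀQe_a dt to 0.5 %.

Both fixtures drive the tracking error below 1 % of the unit step
within a 10 s run.  These checks certify the implementation of the
adaptation laws; they say nothing about convergence speed on the
nonlinear muscle, where the matched-uncertainty assumption is only
approximate.

## Numerical choices and problem sizes

Plant/muscle integration: fixed-step RK4, dt = 0.1 ms, with the
friction regime frozen within a step and stick/slip transitions
resolved at step boundaries.  Halving dt changes the final position of
every headline run by well under 0.1 %.  The step-response study uses
8 s runs (2001 recorded samples at 250 Hz); the verification fixtures
use 10 s at dt = 1 ms.  All runs are deterministic; a seed exists only
for the optional measurement-noise path, and the optional 5 µm encoder
quantization is off by default so the recorded trajectories are the
true ones.  Divergence (|x| > 0.1 m or non-finite state) aborts a run
with the last stable time in the diagnostic; batch runs collect
per-run failures instead of aborting.

## Known limitations

* The pulse-width→recruitment map is linear by assumption; real
  recruitment curves are sigmoidal and history-dependent.
* No fatigue, calcium dynamics, recruitment order or temperature
  dependence; the muscle parameters are a fixed transcription, not a
  fit to any particular animal.
* The stick-slip model uses a single static threshold; real rail
  friction shows presliding creep and load dependence.
* Adaptive-gain convergence is not claimed anywhere — only tracking
  error convergence, which is all the underlying theory provides.
* MRAC on the full muscle settles into the 2 % band noticeably later
  (~4.9 s) than on its ideal linear plant (~4.4 s): the printed
  adaptation rates are slow relative to the 8 s horizon, so its
  settling time is dominated by the adaptation transient.
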
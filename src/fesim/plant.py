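"""Mass-spring-damper load with stick-slip Coulomb friction.

The muscle pulls a mass block along a rail against an extension spring,
a viscous damper and Coulomb friction:

    m x'' + c x' + ks (x - x*) = F_MT - Ff

Positive ``x`` is the direction of muscle shortening, so a contraction
moves the mass toward positive displacement.  Friction switches between
a static regime (the block stays at rest while the net applied force is
below the breakaway threshold ``mu_s * m * g``) and a kinetic regime
(constant magnitude ``mu_k * m * g`` opposing motion).  A literal
transcription of the published friction branch, which applies
``mu_s * m * g * sign(x')`` below threshold, is available as
``friction_mode="literal"`` for comparison; it is not physical at
rest (sign(0) = 0 injects no force) and is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .muscle import MuscleState

__all__ = [
    "PlantParams",
    "PlantState",
    "static_threshold",
    "kinetic_friction",
    "friction_force",
    "derivatives_core",
    "plant_derivatives",
    "coupling_update",
]


@dataclass
class PlantParams:
    """Load constants: mass in kg, damping in N s/m, stiffness in N/m."""

    m: float = 9.0e-4        # 0.900 g mass block on the rail
    c: float = 3.500         # damping of the rail/spring assembly
    ks: float = 35.025       # extension spring constant
    mu_s: float = 0.120      # static friction coefficient
    mu_k: float = 0.080      # kinetic friction coefficient
    x_star: float = 0.0      # spring rest offset (m)
    g: float = 9.81          # gravity (m/s^2)
    friction_mode: str = "stick_slip"   # or "literal"
    v_tol: float = 1e-6      # |x'| below which the block counts as at rest

    def __post_init__(self) -> None:
        for name in ("m", "c", "ks", "g"):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"PlantParams.{name} must be > 0")
        if not 0.0 <= self.mu_k <= self.mu_s:
            raise ValueError("need 0 <= mu_k <= mu_s")
        if self.friction_mode not in ("stick_slip", "literal"):
            raise ValueError(f"unknown friction_mode {self.friction_mode!r}")


@dataclass
class PlantState:
    x: float = 0.0
    xdot: float = 0.0
    sticking: bool = True

    def __post_init__(self) -> None:
        if self.sticking and self.xdot != 0.0:
            raise ValueError("sticking state requires zero velocity")


def static_threshold(params: PlantParams) -> float:
    """Breakaway force mu_s * m * g (N)."""
    return params.mu_s * params.m * params.g


def kinetic_friction(params: PlantParams) -> float:
    """Sliding friction magnitude mu_k * m * g (N)."""
    return params.mu_k * params.m * params.g


def _net_applied(state: PlantState, F_MT: float, params: PlantParams) -> float:
    return F_MT - params.c * state.xdot - params.ks * (state.x - params.x_star)


def _sign(v: float) -> float:
    if v > 0.0:
        return 1.0
    if v < 0.0:
        return -1.0
    return 0.0


def friction_force(state: PlantState, F_MT: float, params: PlantParams) -> float:
    """Signed friction force (N) opposing motion / impending motion.

    With the block moving, friction is kinetic: ``mu_k m g`` against the
    velocity.  With the block at rest, static friction cancels the net
    applied force exactly while it stays below the breakaway threshold,
    and switches to the kinetic magnitude (against the impending motion)
    once the threshold is reached.  The magnitude never exceeds
    ``mu_s m g``.
    """
    F_net = _net_applied(state, F_MT, params)
    thresh = static_threshold(params)
    if params.friction_mode == "literal":
        if abs(F_net) >= thresh:
            return kinetic_friction(params) * _sign(state.xdot)
        return thresh * _sign(state.xdot)
    if abs(state.xdot) > params.v_tol:
        return kinetic_friction(params) * _sign(state.xdot)
    if abs(F_net) < thresh:
        return F_net  # static friction cancels the applied force
    return kinetic_friction(params) * _sign(F_net)


def derivatives_core(
    x: float, xdot: float, sticking: bool, F_MT: float, params: PlantParams
) -> tuple[float, float]:
    """Float-only core of :func:`plant_derivatives` (integration hot path)."""
    F_net = F_MT - params.c * xdot - params.ks * (x - params.x_star)
    thresh = params.mu_s * params.m * params.g
    if params.friction_mode == "literal":
        # literal transcription: friction enters as Ff * sign(x')
        s = _sign(xdot)
        Ff = (params.mu_k if abs(F_net) >= thresh else params.mu_s) \
            * params.m * params.g * s
        return xdot, (F_net - Ff * s) / params.m
    if sticking and abs(F_net) < thresh:
        return 0.0, 0.0
    if abs(xdot) > params.v_tol:
        Ff = params.mu_k * params.m * params.g * _sign(xdot)
    elif abs(F_net) < thresh:
        Ff = F_net
    else:
        Ff = params.mu_k * params.m * params.g * _sign(F_net)
    return xdot, (F_net - Ff) / params.m


def plant_derivatives(
    state: PlantState, F_MT: float, params: PlantParams
) -> tuple[float, float]:
    """(dx/dt, d2x/dt2) of the load under muscle force ``F_MT``."""
    return derivatives_core(state.x, state.xdot, state.sticking, F_MT, params)


def coupling_update(plant: PlantState, muscle: MuscleState) -> MuscleState:
    """Shorten the muscle-tendon path by the mass displacement.

    The mass moves in the direction of contraction, so
    ``lMT = lMT_rest - x``.
    """
    return replace(muscle, lMT=muscle.lMT_rest - plant.x)
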
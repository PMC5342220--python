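"""Hill-type muscle-tendon actuator with Thelen-style constitutive curves.

The actuator is the force source of the testbed: a contractile fiber in
series with an elastic tendon, driven by a normalized neural excitation
``u_exc`` in [0, 1].  Four phenomenological relations define it:

* first-order activation dynamics with activation/deactivation time
  constants that themselves depend on the activation level,
* an active force-length curve (Gaussian in normalized fiber length),
* a passive exponential force-length curve,
* a hyperbolic force-velocity curve with a distinct lengthening branch,
* an exponential-toe / linear tendon stress-strain curve.

All forces inside this module are normalized by the maximum isometric
force ``F0M``; :func:`muscle_tendon_force` converts back to newtons.
Pennation is fixed at zero, so the muscle-tendon length splits as
``lMT = lM + lT``.

Default constitutive constants are the standard published values for
this model family; the geometry (optimal fiber length, tendon slack
length) and force scale describe a mouse extensor digitorum longus
(EDL), a fast-twitch muscle, whence the maximum shortening velocity of
12 optimal lengths per second.  See docs/methods.md for the parameter
rationale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "MuscleParams",
    "MuscleState",
    "init_muscle_state",
    "activation_rate",
    "tendon_force",
    "active_force_length",
    "passive_force_length",
    "force_velocity",
    "fiber_force",
    "fiber_velocity",
    "muscle_tendon_force",
]


@dataclass
class MuscleParams:
    """Constants of the muscle-tendon unit.

    Lengths in meters, forces in newtons, time constants in seconds.
    ``vmax`` is expressed in optimal fiber lengths per second.
    """

    F0M: float = 0.40           # max isometric force (N), mouse EDL scale
    l0M: float = 4.59e-3        # optimal fiber length (m) = 0.44 * 10.44 mm
    lsT: float = 5.85e-3        # tendon slack length (m)
    fiber_ratio: float = 0.44   # optimal-fiber / whole-muscle length
    tau_act: float = 0.010      # activation time constant (s)
    tau_deact: float = 0.040    # deactivation time constant (s)
    gamma_fl: float = 0.45      # active force-length shape factor
    kPE: float = 4.0            # passive exponential shape factor
    eps0M: float = 0.6          # passive strain at one normalized force
    vmax: float = 12.0          # max shortening velocity (l0M/s), fast twitch
    Af: float = 0.25            # force-velocity curvature
    FlenM: float = 1.4          # max normalized lengthening force
    eps_toe: float = 0.02436    # tendon strain at the toe/linear transition
    k_toe: float = 3.0          # tendon toe-region exponential shape
    k_lin: float = 42.8         # tendon linear-region stiffness (1/strain)
    f_toe: float = 0.33         # normalized tendon force at eps_toe
    a_min: float = 0.0          # optional activation floor (0 disables)

    def __post_init__(self) -> None:
        positive = {
            "F0M": self.F0M, "l0M": self.l0M, "lsT": self.lsT,
            "tau_act": self.tau_act, "tau_deact": self.tau_deact,
            "gamma_fl": self.gamma_fl, "kPE": self.kPE, "eps0M": self.eps0M,
            "vmax": self.vmax, "Af": self.Af, "FlenM": self.FlenM,
            "eps_toe": self.eps_toe, "k_toe": self.k_toe, "k_lin": self.k_lin,
            "f_toe": self.f_toe,
        }
        for name, value in positive.items():
            if not value > 0.0:
                raise ValueError(f"MuscleParams.{name} must be > 0, got {value!r}")
        if not 0.0 < self.fiber_ratio < 1.0:
            raise ValueError("fiber_ratio must lie in (0, 1)")
        if not 0.0 <= self.a_min < 1.0:
            raise ValueError("a_min must lie in [0, 1)")
        if self.FlenM <= 1.0:
            raise ValueError("FlenM must exceed 1 (lengthening force plateau)")


@dataclass
class MuscleState:
    """Dynamic state: activation ``a``, fiber length ``lM``, path length ``lMT``.

    ``lMT_rest`` remembers the rest path length so the load coupling can
    shorten the path by the mass displacement.
    """

    a: float
    lM: float
    lMT: float
    lMT_rest: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.a <= 1.0:
            raise ValueError(f"activation must lie in [0, 1], got {self.a!r}")
        if not self.lM > 0.0:
            raise ValueError("fiber length must be positive")
        if self.lMT - self.lM < -1e-12:
            raise ValueError("tendon length lMT - lM must be nonnegative")

    @property
    def lT(self) -> float:
        """Tendon length under the zero-pennation split."""
        return self.lMT - self.lM


def init_muscle_state(params: MuscleParams) -> MuscleState:
    """Rest state: fiber at optimal length, tendon at slack length, inactive."""
    lMT0 = params.l0M + params.lsT
    return MuscleState(a=0.0, lM=params.l0M, lMT=lMT0, lMT_rest=lMT0)


def activation_rate(a: float, u_exc: float, params: MuscleParams) -> float:
    """First-order activation dynamics, da/dt in 1/s.

    The effective time constant shrinks with activation during excitation
    and grows during relaxation:

        tau = tau_act * (0.5 + 1.5 a)   if u_exc > a
        tau = tau_deact / (0.5 + 1.5 a) otherwise

    which keeps ``a`` inside [0, 1] for any excitation in [0, 1].
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"activation must lie in [0, 1], got {a!r}")
    if not 0.0 <= u_exc <= 1.0:
        raise ValueError(f"excitation must lie in [0, 1], got {u_exc!r}")
    scale = 0.5 + 1.5 * a
    if u_exc > a:
        tau = params.tau_act * scale
    else:
        tau = params.tau_deact / scale
    return (u_exc - a) / tau


def tendon_force(lT: float, params: MuscleParams) -> float:
    """Normalized tendon force (units of F0M) as a function of tendon length.

    Zero at or below slack; exponential toe region up to strain
    ``eps_toe``; linear with stiffness ``k_lin`` beyond.  Continuous and
    nondecreasing in strain.
    """
    if lT < 0.0:
        raise ValueError("tendon length must be nonnegative")
    eps = (lT - params.lsT) / params.lsT
    if eps <= 1e-12:  # slack, or strain below float resolution of the lengths
        return 0.0
    if eps < params.eps_toe:
        return (params.f_toe
                * math.expm1(params.k_toe * eps / params.eps_toe)
                / math.expm1(params.k_toe))
    return params.k_lin * (eps - params.eps_toe) + params.f_toe


def active_force_length(lM_norm: float, params: MuscleParams) -> float:
    """Gaussian active force-length curve, maximal (1) at optimal length."""
    d = lM_norm - 1.0
    return math.exp(-d * d / params.gamma_fl)


def passive_force_length(lM_norm: float, params: MuscleParams) -> float:
    """Exponential passive force-length curve, zero at and below optimum."""
    if lM_norm <= 1.0:
        return 0.0
    num = math.expm1(params.kPE * (lM_norm - 1.0) / params.eps0M)
    return num / math.expm1(params.kPE)


def _fv_scale(a: float) -> float:
    # activation-dependent scaling of the maximum contraction velocity
    return 0.25 + 0.75 * a


# Beyond this fraction of the lengthening plateau the hyperbolic branch is
# continued linearly, keeping force-velocity invertible for any demand.
_FV_LIN_FRACTION = 0.95


def force_velocity(a: float, v_norm: float, params: MuscleParams) -> float:
    """Normalized force-velocity multiplier ``fV`` (1 at zero velocity).

    ``v_norm`` is the fiber velocity in l0M/s, negative for shortening.
    Shortening follows the classic hyperbola reaching zero force at the
    (activation-scaled) maximum shortening velocity; lengthening rises
    toward the ``FlenM`` plateau and is extended linearly near the
    plateau so the curve stays strictly increasing.
    """
    Af, Flen = params.Af, params.FlenM
    V = v_norm / (_fv_scale(a) * params.vmax)
    if V <= 0.0:
        if V <= -1.0:
            return 0.0
        return (1.0 + V) / (1.0 - V / Af)
    rho_c = 1.0 + _FV_LIN_FRACTION * (Flen - 1.0)
    beta_c = (rho_c - 1.0) / (Flen - rho_c)
    V_c = beta_c * (Flen - 1.0) / (2.0 + 2.0 / Af)
    if V < V_c:
        beta = V * (2.0 + 2.0 / Af) / (Flen - 1.0)
        return (1.0 + beta * Flen) / (1.0 + beta)
    # linear continuation with the slope of the hyperbola at the junction
    drho_dV = (2.0 + 2.0 / Af) * (Flen - rho_c) ** 2 / (Flen - 1.0) ** 2
    return rho_c + (V - V_c) * drho_dV


def fiber_force(a: float, lM: float, vM: float, params: MuscleParams) -> float:
    """Normalized fiber force ``a*fL*fV + fPE`` at fiber velocity ``vM`` (m/s)."""
    if not lM > 0.0:
        raise ValueError("fiber length must be positive")
    lM_norm = lM / params.l0M
    v_norm = vM / params.l0M
    fl = active_force_length(lM_norm, params)
    fv = force_velocity(a, v_norm, params)
    fpe = passive_force_length(lM_norm, params)
    return a * fl * fv + fpe


def _invert_force_velocity(a: float, rho: float, params: MuscleParams) -> float:
    """Velocity (l0M/s) at which the contractile element supplies ``rho``
    times its isometric capacity ``a*fL``.  Inverse of the branch logic in
    :func:`force_velocity`."""
    Af, Flen = params.Af, params.FlenM
    scale = _fv_scale(a) * params.vmax
    if rho <= 0.0:
        return -scale  # at or past maximum shortening velocity
    if rho < 1.0:
        V = (rho - 1.0) / (1.0 + rho / Af)
    else:
        rho_c = 1.0 + _FV_LIN_FRACTION * (Flen - 1.0)
        beta_c = (rho_c - 1.0) / (Flen - rho_c)
        V_c = beta_c * (Flen - 1.0) / (2.0 + 2.0 / Af)
        if rho < rho_c:
            beta = (rho - 1.0) / (Flen - rho)
            V = beta * (Flen - 1.0) / (2.0 + 2.0 / Af)
        else:
            drho_dV = (2.0 + 2.0 / Af) * (Flen - rho_c) ** 2 / (Flen - 1.0) ** 2
            V = V_c + (rho - rho_c) / drho_dV
    return V * scale


def fiber_velocity(
    a: float,
    lM: float,
    lMT: float,
    params: MuscleParams,
    method: str = "analytic",
) -> float:
    """Fiber velocity (m/s) balancing tendon force against fiber force.

    This is the contraction dynamics: the series tendon transmits
    ``tendon_force(lMT - lM)``, and the fiber must produce the same force,
    which fixes its velocity through the force-velocity curve.  The
    result is clamped to ``[-vmax, +vmax]`` (in l0M/s).

    ``method='analytic'`` inverts the force-velocity branches in closed
    form (with the linear lengthening continuation this inverse exists
    for every demanded force); ``method='brentq'`` solves the same
    balance by safeguarded bracketing and is kept as a cross-check.
    """
    if not lM > 0.0:
        raise ValueError("fiber length must be positive")
    lT = lMT - lM
    if lT < 0.0:
        raise ValueError("tendon length must be nonnegative")
    a = max(a, params.a_min)
    ft = tendon_force(lT, params)
    lM_norm = lM / params.l0M
    fl = active_force_length(lM_norm, params)
    fpe = passive_force_length(lM_norm, params)
    f_ce = ft - fpe  # force the contractile element must supply
    afl = a * fl

    vmax_mps = params.vmax * params.l0M
    if afl < 1e-9:
        # no active capacity: a slack demand parks the fiber, a pulling
        # tendon back-drives it at the velocity bound
        if f_ce < -1e-12:
            return -_fv_scale(a) * vmax_mps  # passive recoil, max shortening
        if f_ce <= 1e-12:
            return 0.0
        return vmax_mps

    if method == "analytic":
        v_norm = _invert_force_velocity(a, f_ce / afl, params)
        return max(-vmax_mps, min(vmax_mps, v_norm * params.l0M))
    if method != "brentq":
        raise ValueError(f"unknown method {method!r}")

    from scipy.optimize import brentq

    def residual(vM: float) -> float:
        return fiber_force(a, lM, vM, params) - ft

    lo, hi = -vmax_mps, vmax_mps
    f_lo, f_hi = residual(lo), residual(hi)
    if f_lo >= 0.0:
        return lo
    if f_hi <= 0.0:
        return hi
    v = brentq(residual, lo, hi, xtol=1e-14, rtol=1e-15, maxiter=200)
    return float(v)


def muscle_tendon_force(state: MuscleState, params: MuscleParams) -> float:
    """Force transmitted to the load, in newtons (the tendon force)."""
    return params.F0M * tendon_force(state.lMT - state.lM, params)


def mtu_rates(
    a: float, lM: float, lMT: float, u_exc: float, params: MuscleParams
) -> tuple[float, float, float]:
    """Fused rates for the integration hot path: (da/dt, dlM/dt, F_MT).

    Equivalent to :func:`activation_rate`, :func:`fiber_velocity`
    (analytic) and :func:`muscle_tendon_force`, sharing the tendon-force
    evaluation between the force output and the contraction dynamics.
    """
    # activation dynamics
    scale = 0.5 + 1.5 * a
    if u_exc > a:
        da = (u_exc - a) / (params.tau_act * scale)
    else:
        da = (u_exc - a) * scale / params.tau_deact

    lT = lMT - lM
    # transient RK4 substates may overshoot the path length; slack either way
    ft = tendon_force(lT, params) if lT > 0.0 else 0.0
    lM_norm = lM / params.l0M
    fl = active_force_length(lM_norm, params)
    fpe = passive_force_length(lM_norm, params)
    f_ce = ft - fpe
    a_eff = a if a > params.a_min else params.a_min
    afl = a_eff * fl
    vmax_mps = params.vmax * params.l0M
    if afl < 1e-9:
        if f_ce < -1e-12:
            vM = -_fv_scale(a_eff) * vmax_mps
        elif f_ce <= 1e-12:
            vM = 0.0
        else:
            vM = vmax_mps
    else:
        v_norm = _invert_force_velocity(a_eff, f_ce / afl, params) * params.l0M
        vM = max(-vmax_mps, min(vmax_mps, v_norm))
    return da, vM, params.F0M * ft


def with_path_length(state: MuscleState, lMT: float) -> MuscleState:
    """Copy of ``state`` with an updated muscle-tendon path length."""
    return replace(state, lMT=lMT)
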
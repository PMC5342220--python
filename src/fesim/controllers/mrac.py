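"""Model reference adaptive controller (direct MRAC, scalar plant).

The muscle is abstracted as an uncertain first-order system
``x' = a x + b u`` with ``a`` unknown and ``b`` of known sign.  The
controller drives it toward the stable reference model
``xr' = a_r xr + b_r r`` through the gradient adaptation laws

    theta_x' = -gamma_x e_ad x sign(b)
    theta_r' = -gamma_r e_ad r sign(b),      e_ad = x - xr,

and the control law ``u = theta_x x + theta_r r``.  The Lyapunov
function ``e_ad^2/2 + b theta~_x^2/(2 gamma_x) + b theta~_r^2/(2
gamma_r)`` then has derivative ``a_r e_ad^2 <= 0``, so the tracking
error converges to zero (error convergence only; the gains themselves
need not converge to their ideal values).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ..trajectories import ReferenceParams

__all__ = ["MRACParams", "MRACState", "mrac_update"]


@dataclass
class MRACParams:
    gamma_x: float = 1.45e5      # adaptation rate on the state gain (1/m^3)
    gamma_r: float = 1.45e5      # adaptation rate on the input gain (1/m^3)
    sign_b: float = 1.0          # known sign of the plant input gain
    reference: ReferenceParams = field(default_factory=ReferenceParams)

    def __post_init__(self) -> None:
        if not (self.gamma_x > 0.0 and self.gamma_r > 0.0):
            raise ValueError("adaptation rates must be positive")
        if self.sign_b not in (-1.0, 1.0):
            raise ValueError("sign_b must be +1 or -1")


@dataclass
class MRACState:
    theta_x: float = 0.035       # adaptive state-feedback gain (s/m)
    theta_r: float = 0.140       # adaptive feedforward gain (s/m)


def mrac_update(
    state: MRACState,
    x: float,
    xr: float,
    r: float,
    dt: float,
    params: MRACParams,
) -> tuple[float, MRACState]:
    """One controller tick; returns (effort, new state).

    The adaptation laws are integrated with explicit Euler over ``dt``
    and the effort is evaluated with the updated gains.
    """
    if not dt > 0.0:
        raise ValueError("dt must be positive")
    e_ad = x - xr
    theta_x = state.theta_x - params.gamma_x * e_ad * x * params.sign_b * dt
    theta_r = state.theta_r - params.gamma_r * e_ad * r * params.sign_b * dt
    effort = theta_x * x + theta_r * r
    return effort, MRACState(theta_x=theta_x, theta_r=theta_r)
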
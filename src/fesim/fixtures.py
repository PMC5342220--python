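"""Synthetic linear plants for controller verification.

The stability proofs of the adaptive controllers hold for first-order
linear plants with matched uncertainty, not for the full muscle.  These
fixtures instantiate exactly those plants so the Lyapunov decrease and
error-convergence guarantees can be checked numerically:

* MRAC:   x' = a x + b u                     (a, b unknown to the controller)
* ADP-PI: x' = a x + b (lambda* u + W*^T phi(x))   (lambda*, W* unknown;
  the uncertainty is matched, i.e. enters through the input channel)

Both simulators integrate the plant with RK4 on the controller grid
(the adaptation laws themselves are Euler, as in the real loop) and
return the Lyapunov function evaluated with the hidden true parameters,
so a test can assert it is nonincreasing up to integration error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .controllers import (
    ADPPIParams,
    ADPPIState,
    MRACParams,
    MRACState,
    adppi_basis,
    adppi_update,
    mrac_update,
)
from .controllers.adppi import advance_xlin
from .trajectories import ReferenceState, reference_step

__all__ = [
    "LinearPlantFixture",
    "simulate_mrac_linear",
    "simulate_adppi_linear",
]


@dataclass
class LinearPlantFixture:
    """Hidden true parameters of the verification plant."""

    a_true: float = -1.0
    b_true: float = 1.0
    lambda_true: float = 1.3
    W_true: np.ndarray = field(
        default_factory=lambda: np.array([0.01, 0.0, 0.0, 0.02])
    )

    def __post_init__(self) -> None:
        self.W_true = np.asarray(self.W_true, dtype=float)
        if self.b_true == 0.0:
            raise ValueError("b_true must be nonzero")
        if self.W_true.shape != (4,):
            raise ValueError("W_true must have 4 components")


def _rk4_scalar(f, x: float, dt: float) -> float:
    k1 = f(x)
    k2 = f(x + 0.5 * dt * k1)
    k3 = f(x + 0.5 * dt * k2)
    k4 = f(x + dt * k3)
    return x + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def simulate_mrac_linear(
    fixture: LinearPlantFixture,
    params: MRACParams,
    state0: MRACState,
    r_of_t,
    duration: float,
    dt: float = 1e-3,
) -> dict[str, np.ndarray]:
    """Closed MRAC loop on the linear plant x' = a x + b u.

    Returns time series including the tracking error ``e_ad = x - xr``
    and the Lyapunov function built from the hidden ideal gains
    ``theta_x* = (a_r - a)/b``, ``theta_r* = b_r/b``.
    """
    a, b = fixture.a_true, fixture.b_true
    ref = params.reference
    theta_x_star = (ref.a_r - a) / b
    theta_r_star = ref.b_r / b

    n = round(duration / dt)
    t = np.arange(n + 1) * dt
    x = 0.0
    ref_state = ReferenceState()
    ctrl = MRACState(theta_x=state0.theta_x, theta_r=state0.theta_r)
    xs, xrs, es, Vs = [], [], [], []
    ths = []
    for i in range(n + 1):
        r = float(r_of_t(t[i]))
        if i > 0:
            ref_state = reference_step(ref_state, r, dt, ref)
        u, ctrl = mrac_update(ctrl, x, ref_state.xr, r, dt, params)
        e = x - ref_state.xr
        tx = ctrl.theta_x - theta_x_star
        tr = ctrl.theta_r - theta_r_star
        V = 0.5 * e * e \
            + 0.5 * abs(b) / params.gamma_x * tx * tx \
            + 0.5 * abs(b) / params.gamma_r * tr * tr
        xs.append(x); xrs.append(ref_state.xr); es.append(e); Vs.append(V)
        ths.append((ctrl.theta_x, ctrl.theta_r))
        if i < n:
            x = _rk4_scalar(lambda s: a * s + b * u, x, dt)
    ths = np.array(ths)
    return {
        "t": t, "x": np.array(xs), "xr": np.array(xrs),
        "e_ad": np.array(es), "V": np.array(Vs),
        "theta_x": ths[:, 0], "theta_r": ths[:, 1],
    }


def simulate_adppi_linear(
    fixture: LinearPlantFixture,
    params: ADPPIParams,
    xd_of_t,
    duration: float,
    dt: float = 1e-3,
) -> dict[str, np.ndarray]:
    """Closed adaptive-augmented-PI loop on the matched-uncertainty plant
    x' = a x + b (lambda* u + W*^T phi(x)), with (a, b) equal to the
    controller's assumed constants.

    Returns the augmented tracking error ``e_a = xa - xlin`` and the
    Lyapunov function built from the hidden ideal gains
    ``K~ = K^ - (1 - lambda*)/lambda* K*`` and ``W~ = W^ - W*/lambda*``
    (the adaptation estimates the scaled vector ``W*/lambda*``).
    """
    a, b = params.a_lin, params.b_lin
    lam, W_star = fixture.lambda_true, fixture.W_true
    K_star = np.array([params.kp, params.ki])
    K_ideal = (1.0 - lam) / lam * K_star
    W_ideal = W_star / lam
    P = params.P

    n = round(duration / dt)
    t = np.arange(n + 1) * dt
    x = 0.0
    xI = 0.0
    xlin = np.zeros(2)
    ctrl = ADPPIState()
    xs, ea0s, ea1s, Vs, us = [], [], [], [], []
    for i in range(n + 1):
        xd = float(xd_of_t(t[i]))
        if i > 0:
            xlin = advance_xlin(xlin, xd, dt, params)
        u, ctrl = adppi_update(ctrl, x, xd, xlin, dt, params)
        xI = ctrl.xI
        ea = np.array([x - xlin[0], xI - xlin[1]])
        Kt = ctrl.K_hat - K_ideal
        Wt = ctrl.W_hat - W_ideal
        V = float(ea @ P @ ea) \
            + abs(lam) * float(Kt / params.Gamma_K @ Kt) \
            + abs(lam) * float(Wt / params.Gamma_W @ Wt)
        xs.append(x); ea0s.append(ea[0]); ea1s.append(ea[1])
        Vs.append(V); us.append(u)
        if i < n:
            f = lambda s: a * s + b * (lam * u + float(W_star @ adppi_basis(s)))
            x = _rk4_scalar(f, x, dt)
    return {
        "t": t, "x": np.array(xs),
        "ea": np.stack([np.array(ea0s), np.array(ea1s)], axis=1),
        "V": np.array(Vs), "u": np.array(us),
    }
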
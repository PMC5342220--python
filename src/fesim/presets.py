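"""Named controller parameter presets.

The adaptive controllers were tuned per trajectory, separately for the
bench experiments and for the simulation study; the resulting parameter
sets are shipped here as named presets (``step_sim``, ``step_exp``,
``sine_sim``, ...).  The PI presets reuse the linear gains of the
corresponding adaptive-augmented-PI rows, which are the tuned PI gains
that controller builds on.

Units: adaptation rates gamma in 1/m^3; theta gains in s/m; kP in s/m;
kI in 1/m; a in 1/s; b in m/s^2; Gamma_K in s^2/m^3; Gamma_W in s^2/m^2.
"""

from __future__ import annotations

import numpy as np

from .controllers import ADPPIParams, MRACParams, MRACState, PIGains
from .trajectories import ReferenceParams

__all__ = [
    "MRAC_PRESETS",
    "ADPPI_PRESETS",
    "mrac_preset",
    "adppi_preset",
    "pi_preset",
]

_REF = {"a_r": -2.0, "b_r": 2.0}

# rows: gamma_x, gamma_r, theta_x(0), theta_r(0)  (a_r = -2, b_r = 2 for all)
MRAC_PRESETS: dict[str, dict[str, float]] = {
    "step_exp":   {"gamma_x": 1.00e5, "gamma_r": 1.00e5, "theta_x0": 0.025, "theta_r0": 0.040},
    "step_sim":   {"gamma_x": 1.45e5, "gamma_r": 1.45e5, "theta_x0": 0.035, "theta_r0": 0.140},
    "sine_exp":   {"gamma_x": 8.00e5, "gamma_r": 5.00e5, "theta_x0": 0.020, "theta_r0": 0.060},
    "sine_sim":   {"gamma_x": 9.50e5, "gamma_r": 2.50e5, "theta_x0": 0.010, "theta_r0": 0.060},
    "ramp_exp":   {"gamma_x": 8.00e5, "gamma_r": 5.00e5, "theta_x0": 0.020, "theta_r0": 0.060},
    "ramp_sim":   {"gamma_x": 10.50e5, "gamma_r": 8.50e5, "theta_x0": 0.080, "theta_r0": 0.060},
    "square_exp": {"gamma_x": 8.00e5, "gamma_r": 5.00e5, "theta_x0": 0.020, "theta_r0": 0.060},
    "square_sim": {"gamma_x": 1.00e5, "gamma_r": 1.00e5, "theta_x0": 0.025, "theta_r0": 0.040},
}

# rows: kP, kI, a, b, Gamma_K (both diagonal entries), Gamma_W (all four)
ADPPI_PRESETS: dict[str, dict[str, float]] = {
    "step_exp":   {"kp": 0.050, "ki": 0.75, "a": -11.55, "b": 2.89, "Gamma_K": 0.10e-1, "Gamma_W": 0.10e-4},
    "step_sim":   {"kp": 0.090, "ki": 0.40, "a": -3.50,  "b": 8.50, "Gamma_K": 0.10e-1, "Gamma_W": 0.10e-4},
    "sine_exp":   {"kp": 0.055, "ki": 1.00, "a": -11.55, "b": 2.89, "Gamma_K": 1.00e-1, "Gamma_W": 1.00e-4},
    "sine_sim":   {"kp": 0.400, "ki": 0.25, "a": -1.50,  "b": 12.50, "Gamma_K": 1.00e-1, "Gamma_W": 1.00e-4},
    "ramp_exp":   {"kp": 0.035, "ki": 0.90, "a": -57.75, "b": 2.89, "Gamma_K": 1.00e-1, "Gamma_W": 1.00e-4},
    "ramp_sim":   {"kp": 0.080, "ki": 0.90, "a": -3.50,  "b": 8.50, "Gamma_K": 1.00e-1, "Gamma_W": 1.00e-4},
    "square_exp": {"kp": 0.055, "ki": 1.00, "a": -50.0,  "b": 2.89, "Gamma_K": 1.00e-1, "Gamma_W": 1.00e-4},
    "square_sim": {"kp": 0.075, "ki": 0.37, "a": -3.50,  "b": 10.50, "Gamma_K": 1.00e-1, "Gamma_W": 1.00e-4},
}


def mrac_preset(name: str) -> tuple[MRACParams, MRACState]:
    """Controller parameters and initial adaptive gains for a named preset."""
    row = MRAC_PRESETS[name]
    params = MRACParams(
        gamma_x=row["gamma_x"],
        gamma_r=row["gamma_r"],
        reference=ReferenceParams(**_REF),
    )
    state = MRACState(theta_x=row["theta_x0"], theta_r=row["theta_r0"])
    return params, state


def adppi_preset(name: str) -> ADPPIParams:
    row = ADPPI_PRESETS[name]
    return ADPPIParams(
        kp=row["kp"],
        ki=row["ki"],
        a_lin=row["a"],
        b_lin=row["b"],
        Gamma_K=np.full(2, row["Gamma_K"]),
        Gamma_W=np.full(4, row["Gamma_W"]),
    )


def pi_preset(name: str) -> PIGains:
    """PI gains: the linear-gain pair of the matching adaptive-PI preset."""
    row = ADPPI_PRESETS[name]
    return PIGains(kp=row["kp"], ki=row["ki"])
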
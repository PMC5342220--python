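"""Desired trajectories and the first-order reference model.

Trajectory generators produce the desired displacement ``xd(t)`` for the
step, sine, ramp and square shapes.  The muscle can only pull, so every
shape is nonnegative (the sine is offset to start from zero).

The adaptive controllers do not chase ``xd`` directly; they chase a
stable first-order reference model

    x_r' = a_r x_r + b_r r(t),     a_r < 0,

whose input is the desired trajectory, ``r(t) = xd(t)``.  With the
conventional choice ``a_r = -b_r`` the model has unit DC gain, so for a
constant command the reference settles exactly on the desired value.
The model is advanced by the exact discretization of the linear ODE
over each controller tick (zero-order hold on ``r``), which removes
integration drift from this part of the loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TrajectorySpec",
    "ReferenceParams",
    "ReferenceState",
    "generate_trajectory",
    "reference_step",
]

_SHAPES = ("step", "sine", "ramp", "square")


@dataclass
class TrajectorySpec:
    """Definition of a desired trajectory.

    amplitude : peak displacement (m).  For the sine shape the waveform
        oscillates around ``offset`` with this amplitude.
    period    : seconds per cycle (sine, square).
    slope     : ramp slope (m/s); None means "reach amplitude at the end
        of the run".
    duty      : high fraction of each square period.
    """

    shape: str = "step"
    amplitude: float = 1.0e-3
    duration: float = 8.0
    onset: float = 0.0
    period: float = 4.0
    slope: float | None = None
    offset: float | None = None
    duty: float = 0.5

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown trajectory shape {self.shape!r}")
        if not self.duration > 0.0:
            raise ValueError("duration must be positive")
        if self.amplitude < 0.0:
            raise ValueError("amplitude must be nonnegative")
        if self.shape in ("sine", "square") and not self.period > 0.0:
            raise ValueError("period must be positive")
        if not 0.0 < self.duty < 1.0:
            raise ValueError("duty must lie in (0, 1)")


def generate_trajectory(spec: TrajectorySpec, t):
    """Evaluate ``xd`` at time(s) ``t`` (scalar or array), in meters."""
    t_arr = np.asarray(t, dtype=float)
    tau = t_arr - spec.onset
    active = tau >= 0.0
    if spec.shape == "step":
        xd = np.where(active, spec.amplitude, 0.0)
    elif spec.shape == "sine":
        offset = spec.amplitude if spec.offset is None else spec.offset
        omega = 2.0 * math.pi / spec.period
        # phase chosen so the waveform starts at its minimum (offset - A)
        xd = np.where(active, offset - spec.amplitude * np.cos(omega * tau), 0.0)
    elif spec.shape == "ramp":
        if spec.slope is None:
            rise = max(spec.duration - spec.onset, 1e-12)
            slope = spec.amplitude / rise
        else:
            slope = spec.slope
        xd = np.where(active, np.minimum(slope * tau, spec.amplitude), 0.0)
    else:  # square
        phase = np.mod(tau, spec.period) / spec.period
        xd = np.where(active & (phase < spec.duty), spec.amplitude, 0.0)
    if xd.ndim == 0:
        return float(xd)
    return xd


@dataclass
class ReferenceParams:
    """First-order reference model ``x_r' = a_r x_r + b_r r``."""

    a_r: float = -2.0
    b_r: float = 2.0

    def __post_init__(self) -> None:
        if not self.a_r < 0.0:
            raise ValueError("reference pole a_r must be negative (stable)")


@dataclass
class ReferenceState:
    xr: float = 0.0
    r: float = 0.0


def reference_step(
    state: ReferenceState, r: float, dt: float, params: ReferenceParams
) -> ReferenceState:
    """Advance the reference model by ``dt`` with ``r`` held constant.

    Uses the exact solution of the linear ODE:
    ``xr(t+dt) = e^(a_r dt) xr + (e^(a_r dt) - 1)/a_r * b_r r``.
    """
    if not dt > 0.0:
        raise ValueError("dt must be positive")
    phi = math.exp(params.a_r * dt)
    xr = phi * state.xr + (phi - 1.0) / params.a_r * params.b_r * r
    return ReferenceState(xr=xr, r=r)
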
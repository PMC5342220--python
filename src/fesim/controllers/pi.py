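"""Proportional-integral position controller.

The tracking error follows the hardware sign convention of the rig,
``e = x - xd``; a positive stimulation pulse shortens the muscle and
moves the mass toward positive ``x``, so the effort applied to the
stimulation channel is the negated PI law, ``u = -(kP e + kI int(e))``.
``output_sign`` holds that single global sign so the convention lives in
one place.

``kI`` is the integral gain ``kP / Ti`` with ``Ti`` the integral time.
Optional anti-windup uses conditional integration: while the actuator
saturates and the error would push the integral further into
saturation, the accumulation is skipped.  It is off by default, which
matches the plain textbook law.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["PIGains", "PIState", "pi_update"]


@dataclass
class PIGains:
    kp: float = 0.090        # proportional gain (s/m)
    ki: float = 0.40         # integral gain kP/Ti (1/m)
    output_sign: float = -1.0
    anti_windup: bool = False

    def __post_init__(self) -> None:
        if self.kp < 0.0 or self.ki < 0.0:
            raise ValueError("PI gains must be nonnegative")
        if self.output_sign not in (-1.0, 1.0):
            raise ValueError("output_sign must be +1 or -1")


@dataclass
class PIState:
    integral: float = 0.0    # accumulated error integral (m s)


def pi_update(
    state: PIState,
    x: float,
    xd: float,
    dt: float,
    gains: PIGains,
    saturated: bool = False,
) -> tuple[float, PIState]:
    """One controller tick; returns (effort, new state).

    ``saturated`` reports whether the actuator clipped the previous
    effort (used only when anti-windup is enabled).
    """
    if not dt > 0.0:
        raise ValueError("dt must be positive")
    e = x - xd
    integral = state.integral
    if not (gains.anti_windup and saturated and e * state.integral > 0.0):
        integral = integral + e * dt
    effort = gains.output_sign * (gains.kp * e + gains.ki * integral)
    return effort, PIState(integral=integral)
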
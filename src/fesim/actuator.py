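"""Stimulation channel: control effort -> saturated PWM pulse width -> excitation.

The stimulator delivers pulse trains at a fixed frequency (100 Hz); the
controller sets only the pulse duration, saturated between ``pw_min``
and ``pw_max`` microseconds.  In simulation the pulse width is converted
to the normalized muscle excitation by its duty fraction ``pw/pw_max``,
held constant over each PWM frame (zero-order hold).  The linear duty
proxy is the single declared modelling assumption of this channel and
is isolated here so a sigmoidal recruitment curve could be substituted.

Controller gains carry units of s/m, so the control effort is a time
(seconds); ``effort_to_pw_gain`` converts it to microseconds.  Its
default is calibrated so the channel's steady-state gain at the 1 mm
operating point matches the first-order muscle model the controllers
are designed against (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ActuatorParams", "effort_to_pulsewidth", "pulsewidth_to_excitation"]


@dataclass
class ActuatorParams:
    pwm_freq: float = 100.0          # stimulation frequency (Hz)
    pw_min: float = 0.0              # minimum pulse width (us)
    pw_max: float = 200.0            # saturation pulse width (us)
    effort_to_pw_gain: float = 4.92e4   # us per unit effort (effort in s)

    def __post_init__(self) -> None:
        if not self.pwm_freq > 0.0:
            raise ValueError("pwm_freq must be positive")
        frame_us = 1e6 / self.pwm_freq
        if not 0.0 <= self.pw_min < self.pw_max <= frame_us:
            raise ValueError(
                "need 0 <= pw_min < pw_max <= PWM frame length "
                f"({frame_us:.0f} us)"
            )
        if not self.effort_to_pw_gain > 0.0:
            raise ValueError("effort_to_pw_gain must be positive")


def effort_to_pulsewidth(u: float, params: ActuatorParams) -> float:
    """Saturated pulse width (us) for control effort ``u``; monotone in ``u``."""
    pw = params.effort_to_pw_gain * u
    return min(max(pw, params.pw_min), params.pw_max)


def pulsewidth_to_excitation(pw: float, params: ActuatorParams) -> float:
    """Normalized excitation in [0, 1]: the duty fraction ``pw / pw_max``."""
    if not params.pw_min <= pw <= params.pw_max:
        raise ValueError(
            f"pulse width {pw!r} outside [{params.pw_min}, {params.pw_max}] us"
        )
    return pw / params.pw_max
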
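"""Closed-loop simulation engine.

Orchestrates the multirate loop of the testbed:

* the muscle-tendon actuator and the stick-slip load are integrated
  continuously with fixed-step RK4 (default 0.1 ms step),
* the controller runs at 250 Hz on the sampled (optionally quantized)
  position,
* the stimulation channel updates the pulse width at the 100 Hz PWM
  frame boundaries, holding the excitation constant in between.

The two clocks are aligned at t = 0 and the controller tick is
processed first when they coincide.  All runs are deterministic; a seed
only matters when measurement noise is enabled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import presets as presets_mod
from .actuator import ActuatorParams, effort_to_pulsewidth, pulsewidth_to_excitation
from .controllers import (
    ADPPIParams,
    ADPPIState,
    MRACParams,
    MRACState,
    OpenLoopSchedule,
    PIGains,
    PIState,
    adppi_update,
    mrac_update,
    openloop_update,
    pi_update,
)
from .controllers.adppi import advance_xlin
from .metrics import (
    M2_TO_MM2,
    MetricReport,
    settling_time_to_target,
    squared_tracking_error,
    summarize,
)
from .muscle import MuscleParams, init_muscle_state, mtu_rates
from .plant import PlantParams, derivatives_core, static_threshold
from .trajectories import (
    ReferenceState,
    TrajectorySpec,
    generate_trajectory,
    reference_step,
)

__all__ = [
    "SimConfig",
    "SimResult",
    "SimulationDiverged",
    "run_simulation",
    "run_batch",
    "tune_openloop_effort",
]

_CONTROLLERS = ("openloop", "pi", "mrac", "adppi")


class SimulationDiverged(RuntimeError):
    """Raised when the simulated state leaves the physical envelope."""

    def __init__(self, message: str, last_stable_time: float):
        super().__init__(f"{message} (last stable time {last_stable_time:.4f} s)")
        self.last_stable_time = last_stable_time


@dataclass
class SimConfig:
    """Complete description of one closed-loop run."""

    controller: str = "pi"
    preset: str | None = None            # named preset (overrides gains below)
    trajectory: TrajectorySpec = field(default_factory=TrajectorySpec)
    muscle: MuscleParams = field(default_factory=MuscleParams)
    plant: PlantParams = field(default_factory=PlantParams)
    actuator: ActuatorParams = field(default_factory=ActuatorParams)
    pi_gains: PIGains | None = None
    mrac_params: MRACParams | None = None
    mrac_state0: MRACState | None = None
    adppi_params: ADPPIParams | None = None
    openloop: OpenLoopSchedule | None = None
    dt_plant: float = 1e-4               # inner integration step (s)
    controller_rate: float = 250.0       # feedback sampling rate (Hz)
    duration: float | None = None        # seconds; default = trajectory duration
    encoder_sim: bool = False            # quantize the measured position
    encoder_resolution: float = 5e-6     # encoder step (m)
    noise_std: float = 0.0               # measurement noise sd (m)
    seed: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.controller not in _CONTROLLERS:
            raise ValueError(f"unknown controller {self.controller!r}")
        if self.duration is None:
            self.duration = self.trajectory.duration
        if not 0.0 < self.duration <= 60.0:
            raise ValueError("duration must lie in (0, 60] s")
        if not self.dt_plant > 0.0 or self.dt_plant > 1.0 / self.controller_rate:
            raise ValueError("need 0 < dt_plant <= 1/controller_rate")
        for rate, name in ((self.controller_rate, "controller"),
                           (self.actuator.pwm_freq, "PWM")):
            n = 1.0 / (rate * self.dt_plant)
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"dt_plant must divide the {name} interval 1/{rate} s"
                )


@dataclass
class SimResult:
    """Synchronized time series (one row per controller tick) + metrics."""

    df: pd.DataFrame
    config: SimConfig
    metrics: MetricReport

    def to_csv(self, path: str) -> None:
        self.df.to_csv(path, index=False, float_format="%.12g")


def _resolve_controller(config: SimConfig):
    """Controller parameters and initial state from config/preset."""
    kind = config.controller
    if kind == "pi":
        gains = config.pi_gains
        if gains is None:
            gains = presets_mod.pi_preset(config.preset or "step_sim")
        return gains, PIState()
    if kind == "mrac":
        if config.mrac_params is not None:
            return config.mrac_params, config.mrac_state0 or MRACState()
        params, state = presets_mod.mrac_preset(config.preset or "step_sim")
        return params, config.mrac_state0 or state
    if kind == "adppi":
        params = config.adppi_params
        if params is None:
            params = presets_mod.adppi_preset(config.preset or "step_sim")
        return params, ADPPIState()
    return config.openloop or OpenLoopSchedule(), None


def _rk4_step(x, v, a, lM, sticking, u_exc, dt, lMT_rest, mp, pp):
    """One fixed-step RK4 update of (x, v, a, lM); regime frozen in-step."""

    def deriv(x_, v_, a_, lM_):
        a_c = min(max(a_, 0.0), 1.0)
        da, vM, F_MT = mtu_rates(a_c, lM_, lMT_rest - x_, u_exc, mp)
        dx, dv = derivatives_core(x_, v_, sticking, F_MT, pp)
        return dx, dv, da, vM

    k1 = deriv(x, v, a, lM)
    h = 0.5 * dt
    k2 = deriv(x + h * k1[0], v + h * k1[1], a + h * k1[2], lM + h * k1[3])
    k3 = deriv(x + h * k2[0], v + h * k2[1], a + h * k2[2], lM + h * k2[3])
    k4 = deriv(x + dt * k3[0], v + dt * k3[1], a + dt * k3[2], lM + dt * k3[3])
    sixth = dt / 6.0
    return (
        x + sixth * (k1[0] + 2.0 * k2[0] + 2.0 * k3[0] + k4[0]),
        v + sixth * (k1[1] + 2.0 * k2[1] + 2.0 * k3[1] + k4[1]),
        a + sixth * (k1[2] + 2.0 * k2[2] + 2.0 * k3[2] + k4[2]),
        lM + sixth * (k1[3] + 2.0 * k2[3] + 2.0 * k3[3] + k4[3]),
    )


def run_simulation(config: SimConfig) -> SimResult:
    """Run one closed-loop simulation and compute its tracking metrics."""
    mp, pp, ap = config.muscle, config.plant, config.actuator
    ctrl_params, ctrl_state = _resolve_controller(config)
    kind = config.controller

    dt = config.dt_plant
    steps_per_tick = round(1.0 / (config.controller_rate * dt))
    steps_per_pwm = round(1.0 / (ap.pwm_freq * dt))
    n_steps = round(config.duration / dt)

    rng = np.random.default_rng(config.seed) if config.noise_std > 0.0 else None

    muscle0 = init_muscle_state(mp)
    lMT_rest = muscle0.lMT_rest
    x, v, a, lM = 0.0, 0.0, muscle0.a, muscle0.lM
    sticking = True
    thresh = static_threshold(pp)

    ref_state = ReferenceState()
    xlin = np.zeros(2)
    effort = 0.0
    pw = 0.0
    u_exc = 0.0

    rows: list[tuple] = []
    gain_log: list[tuple] = []
    t = 0.0

    for i in range(n_steps + 1):
        t = i * dt
        tick = i % steps_per_tick == 0
        if tick:
            # --- measurement path ---
            x_meas = x
            if rng is not None:
                x_meas += rng.normal(0.0, config.noise_std)
            if config.encoder_sim:
                q = config.encoder_resolution
                x_meas = math.floor(x_meas / q) * q
            if not math.isfinite(x) or abs(x) > 0.1:
                raise SimulationDiverged(
                    f"state diverged (x={x!r})", last_stable_time=t - dt
                )
            xd = float(generate_trajectory(config.trajectory, t))
            tick_dt = 1.0 / config.controller_rate
            # --- controller ---
            if kind == "pi":
                effort, ctrl_state = pi_update(
                    ctrl_state, x_meas, xd, tick_dt, ctrl_params,
                    saturated=(pw <= ap.pw_min or pw >= ap.pw_max),
                )
                xr = xd
                gains = ()
            elif kind == "mrac":
                if i > 0:
                    ref_state = reference_step(
                        ref_state, xd, tick_dt, ctrl_params.reference
                    )
                xr = ref_state.xr
                effort, ctrl_state = mrac_update(
                    ctrl_state, x_meas, xr, xd, tick_dt, ctrl_params
                )
                gains = (ctrl_state.theta_x, ctrl_state.theta_r)
            elif kind == "adppi":
                if i > 0:
                    xlin = advance_xlin(xlin, xd, tick_dt, ctrl_params)
                xr = float(xlin[0])
                effort, ctrl_state = adppi_update(
                    ctrl_state, x_meas, xd, xlin, tick_dt, ctrl_params
                )
                gains = (*ctrl_state.K_hat, *ctrl_state.W_hat)
            else:  # open loop
                effort = openloop_update(t, ctrl_params)
                xr = xd
                gains = ()
        if i % steps_per_pwm == 0:
            pw = effort_to_pulsewidth(effort, ap)
            u_exc = pulsewidth_to_excitation(pw, ap)
        if tick:
            F_MT = mtu_rates(a, lM, lMT_rest - x, u_exc, mp)[2]
            rows.append((t, xd, xr, x, v, a, lM, F_MT, effort, pw))
            gain_log.append(gains)
        if i == n_steps:
            break
        # --- continuous dynamics over one plant step ---
        x_new, v_new, a_new, lM_new = _rk4_step(
            x, v, a, lM, sticking, u_exc, dt, lMT_rest, mp, pp
        )
        a_new = min(max(a_new, 0.0), 1.0)
        lM_new = min(max(lM_new, 1e-6), lMT_rest - x_new)
        if sticking:
            x_new, v_new = x, 0.0
            F_MT = mtu_rates(a_new, lM_new, lMT_rest - x, u_exc, mp)[2]
            F_net = F_MT - pp.ks * (x - pp.x_star)
            if abs(F_net) >= thresh:
                sticking = False
        else:
            crossed = v_new * v < 0.0 or abs(v_new) <= pp.v_tol
            if crossed:
                v_new = 0.0
                F_MT = mtu_rates(a_new, lM_new, lMT_rest - x_new, u_exc, mp)[2]
                F_net = F_MT - pp.ks * (x_new - pp.x_star)
                if abs(F_net) < thresh:
                    sticking = True
        x, v, a, lM = x_new, v_new, a_new, lM_new

    df = pd.DataFrame(
        rows,
        columns=["t", "xd", "xr", "x", "xdot", "a", "lM", "F_MT",
                 "effort", "pulse_width"],
    )
    if kind == "mrac":
        gcols = ["theta_x", "theta_r"]
    elif kind == "adppi":
        gcols = ["K_hat_1", "K_hat_2", "W_hat_1", "W_hat_2", "W_hat_3", "W_hat_4"]
    else:
        gcols = []
    for j, col in enumerate(gcols):
        df[col] = [g[j] for g in gain_log]

    metrics = _compute_metrics(df, config)
    return SimResult(df=df, config=config, metrics=metrics)


def _compute_metrics(df: pd.DataFrame, config: SimConfig) -> MetricReport:
    """STE against the controller's target and, for steps, settling time."""
    adaptive = config.controller in ("mrac", "adppi")
    target = df["xr"] if adaptive else df["xd"]
    ste = squared_tracking_error(df["x"].to_numpy(), target.to_numpy())
    ts = None
    if config.trajectory.shape == "step" and config.trajectory.amplitude > 0.0:
        ts = settling_time_to_target(
            df["x"].to_numpy(), target.to_numpy(), df["t"].to_numpy(),
            final_value=config.trajectory.amplitude, band=0.02,
        )
    return MetricReport(
        ste_mm2=ste * M2_TO_MM2,
        settling_time=ts,
        final_error=float(df["x"].iloc[-1] - target.iloc[-1]),
        band=0.02,
        reference_kind="reference" if adaptive else "desired",
    )


@dataclass
class BatchResult:
    results: list[SimResult | None]
    errors: dict[int, str]
    summary: pd.DataFrame


def run_batch(configs: list[SimConfig]) -> BatchResult:
    """Run independent simulations; per-run failures do not abort the batch."""
    if not configs:
        raise ValueError("batch must be nonempty")
    results: list[SimResult | None] = []
    errors: dict[int, str] = {}
    groups: dict[tuple[str, str], list[MetricReport]] = {}
    for i, cfg in enumerate(configs):
        try:
            res = run_simulation(cfg)
        except Exception as exc:  # collected, not fatal
            results.append(None)
            errors[i] = str(exc)
            continue
        results.append(res)
        key = (cfg.label or cfg.controller, cfg.trajectory.shape)
        groups.setdefault(key, []).append(res.metrics)
    summary = summarize(groups) if groups else pd.DataFrame()
    return BatchResult(results=results, errors=errors, summary=summary)


def tune_openloop_effort(
    config: SimConfig,
    target: float | None = None,
    effort_hi: float | None = None,
    tol: float = 1e-7,
    max_iter: int = 40,
) -> float:
    """Bisect the constant open-loop effort so the final displacement hits
    the step amplitude.

    Mirrors tuning "by inspection": the steady-state map from constant
    effort to final position is monotone, so bisection on the end-of-run
    position converges to the effort whose response settles on the
    target.  ``tol`` is on the final-position mismatch (m).
    """
    if target is None:
        target = config.trajectory.amplitude
    if effort_hi is None:
        # full saturation of the stimulation channel
        effort_hi = config.actuator.pw_max / config.actuator.effort_to_pw_gain

    def final_x(effort: float) -> float:
        cfg = replace(
            config,
            controller="openloop",
            openloop=OpenLoopSchedule(
                effort=effort, onset=config.trajectory.onset
            ),
        )
        res = run_simulation(cfg)
        return float(res.df["x"].iloc[-1])

    lo, hi = 0.0, effort_hi
    f_hi = final_x(hi)
    if f_hi < target:
        raise ValueError(
            f"effort_hi={effort_hi} cannot reach the target displacement "
            f"(final x {f_hi:.2e} m < {target:.2e} m)"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = final_x(mid)
        if abs(f_mid - target) <= tol:
            return mid
        if f_mid < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
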
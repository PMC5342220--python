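"""YAML/JSON configuration loading and saving for simulation runs.

A config file is a flat mapping of sections; every key has the same
name and unit as the corresponding dataclass field::

    controller: adppi
    preset: step_sim
    trajectory: {shape: step, amplitude: 1.0e-3, duration: 8.0}
    muscle:     {F0M: 0.40, l0M: 4.59e-3}     # overrides of the defaults
    plant:      {ks: 35.025}
    engine:     {dt_plant: 1.0e-4, duration: 8.0}

Sections that are omitted fall back to the package defaults; explicit
controller gains can be given in ``pi``, ``mrac``, ``adppi`` or
``openloop`` sections instead of a preset.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Any

import numpy as np
import yaml

from .actuator import ActuatorParams
from .controllers import (
    ADPPIParams,
    MRACParams,
    MRACState,
    OpenLoopSchedule,
    PIGains,
)
from .engine import SimConfig
from .muscle import MuscleParams
from .plant import PlantParams
from .trajectories import ReferenceParams, TrajectorySpec

__all__ = ["load_config", "config_to_dict", "config_hash", "save_config"]

_ENGINE_KEYS = (
    "dt_plant", "controller_rate", "duration", "encoder_sim",
    "encoder_resolution", "noise_std", "seed", "label",
)


def load_config(path_or_dict: str | dict[str, Any]) -> SimConfig:
    """Build a :class:`SimConfig` from a YAML/JSON file path or a dict."""
    if isinstance(path_or_dict, str):
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(path_or_dict)
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")

    kwargs: dict[str, Any] = {
        "controller": raw.get("controller", "pi"),
        "preset": raw.get("preset"),
        "trajectory": TrajectorySpec(**raw.get("trajectory", {})),
        "muscle": MuscleParams(**raw.get("muscle", {})),
        "plant": PlantParams(**raw.get("plant", {})),
        "actuator": ActuatorParams(**raw.get("actuator", {})),
    }
    if "pi" in raw:
        kwargs["pi_gains"] = PIGains(**raw["pi"])
    if "mrac" in raw:
        sec = dict(raw["mrac"])
        state = {}
        for key, fld in (("theta_x0", "theta_x"), ("theta_r0", "theta_r")):
            if key in sec:
                state[fld] = sec.pop(key)
        ref = {k: sec.pop(k) for k in ("a_r", "b_r") if k in sec}
        if ref:
            sec["reference"] = ReferenceParams(**ref)
        kwargs["mrac_params"] = MRACParams(**sec)
        if state:
            kwargs["mrac_state0"] = MRACState(**state)
    if "adppi" in raw:
        sec = dict(raw["adppi"])
        for key in ("Gamma_K", "Gamma_W", "Q"):
            if key in sec:
                sec[key] = np.asarray(sec[key], dtype=float)
        kwargs["adppi_params"] = ADPPIParams(**sec)
    if "openloop" in raw:
        sec = dict(raw["openloop"])
        if "table" in sec and sec["table"] is not None:
            sec["table"] = [tuple(row) for row in sec["table"]]
        kwargs["openloop"] = OpenLoopSchedule(**sec)
    for key in _ENGINE_KEYS:
        if key in raw.get("engine", {}):
            kwargs[key] = raw["engine"][key]
    return SimConfig(**kwargs)


def _clean(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _clean(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
            if f.init and not f.name.startswith("_")
        }
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    return obj


def config_to_dict(config: SimConfig) -> dict[str, Any]:
    """JSON-serializable plain-dict view of a config (numpy -> lists)."""
    return _clean(config)


def config_hash(config: SimConfig) -> str:
    """Stable short hash identifying a configuration."""
    blob = json.dumps(config_to_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def save_config(config: SimConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
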
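"""Shared fixtures: default parameter sets and the four step-response runs."""

from __future__ import annotations

import pytest

import fesim
from fesim import (
    MuscleParams,
    OpenLoopSchedule,
    PlantParams,
    SimConfig,
    TrajectorySpec,
)


@pytest.fixture(scope="session")
def muscle_params() -> MuscleParams:
    return MuscleParams()


@pytest.fixture(scope="session")
def plant_params() -> PlantParams:
    return PlantParams()


@pytest.fixture(scope="session")
def step_trajectory() -> TrajectorySpec:
    return TrajectorySpec(shape="step", amplitude=1e-3, duration=8.0)


@pytest.fixture(scope="session")
def openloop_effort(step_trajectory) -> float:
    """Constant open-loop effort bisected to a 1 mm steady state."""
    cfg = SimConfig(controller="openloop", trajectory=step_trajectory)
    return fesim.tune_openloop_effort(cfg)


@pytest.fixture(scope="session")
def step_runs(step_trajectory, openloop_effort) -> dict[str, fesim.SimResult]:
    """The four 8 s step-response simulations with the tuned presets."""
    runs = {}
    for kind in ("openloop", "pi", "mrac", "adppi"):
        cfg = SimConfig(
            controller=kind,
            preset="step_sim",
            trajectory=step_trajectory,
            openloop=OpenLoopSchedule(effort=openloop_effort)
            if kind == "openloop" else None,
        )
        runs[kind] = fesim.run_simulation(cfg)
    return runs
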
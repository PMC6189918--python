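"""Minimal particle-motion simulator under a voltage schedule.

A cell in the channel experiences gravity, buoyancy, Stokes drag and the
dielectrophoretic force.  At cell scale the Reynolds and Stokes numbers
are tiny, so the default integrator is overdamped: inertia is dropped and
the velocity is the instantaneous balance of the non-drag forces against
Stokes drag, v = F/(6πηr).  A full Newton (inertial) explicit integrator
is available behind a flag for completeness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .force import ForceVector, dep_force
from .fourier import FourierModel
from .geometry import (
    DriveCondition,
    MediumProperties,
    ParticleProperties,
    VoltagePattern,
)

__all__ = [
    "ParticleState",
    "FluidProperties",
    "net_force",
    "simulate_trajectory",
]

GRAVITY = 9.80665  # m/s^2, acting along -z


@dataclass(frozen=True)
class FluidProperties:
    """Suspending fluid: dynamic viscosity η (Pa·s) and density (kg/m³)."""

    dynamic_viscosity: float = 1.0e-3
    density: float = 1000.0

    def __post_init__(self) -> None:
        if self.dynamic_viscosity <= 0 or self.density <= 0:
            raise ValueError("viscosity and density must be positive")


@dataclass(frozen=True)
class ParticleState:
    """Kinematic state of one particle in the dual-array frame."""

    y: float
    z: float
    v_y: float = 0.0
    v_z: float = 0.0
    time: float = 0.0


def _check_in_channel(state: ParticleState, model: FourierModel) -> None:
    g = model.geometry
    if not (0.0 <= state.y <= g.width_L) or not (
        -g.height_h / 2 <= state.z <= g.height_h / 2
    ):
        raise ValueError(
            f"particle at (y={state.y}, z={state.z}) is outside the channel"
        )


def net_force(
    state: ParticleState,
    particle: ParticleProperties,
    particle_density: float,
    fluid: FluidProperties,
    model: FourierModel,
    voltages: VoltagePattern,
    medium: MediumProperties,
    drive: DriveCondition,
) -> ForceVector:
    """Sum of DEP force, buoyant weight and Stokes drag (newtons).

    Gravity acts along −z; the buoyant weight is (ρp − ρf)·(4/3)πr³·g and
    vanishes for a neutrally buoyant particle.  Drag is −6πηr·v and always
    opposes the velocity.
    """
    _check_in_channel(state, model)
    f_dep = dep_force(state.y, state.z, model, voltages, particle, medium, drive)
    volume = 4.0 / 3.0 * np.pi * particle.radius_r**3
    f_gz = -(particle_density - fluid.density) * volume * GRAVITY
    drag = 6.0 * np.pi * fluid.dynamic_viscosity * particle.radius_r
    return ForceVector(
        f_y=f_dep.f_y - drag * state.v_y,
        f_z=f_dep.f_z + f_gz - drag * state.v_z,
    )


def simulate_trajectory(
    initial: ParticleState,
    schedule: Callable[[float], VoltagePattern],
    duration: float,
    step: float,
    model: FourierModel,
    particle: ParticleProperties,
    medium: MediumProperties,
    drive: DriveCondition,
    fluid: FluidProperties = FluidProperties(),
    particle_density: float | None = None,
    overdamped: bool = True,
) -> pd.DataFrame:
    """Explicit first-order integration of the particle motion.

    ``schedule`` maps time (s) to the voltage pattern applied at that
    instant.  In the overdamped default the velocity is the drag balance
    v = (F_DEP + F_gravity+buoyancy)/(6πηr); with ``overdamped=False`` a
    symplectic-Euler Newton step is taken instead.  Integration stops with
    a ``wall_hit`` flag when the particle reaches a channel wall, and a
    step that would move the particle by more than a channel dimension
    raises (step-size instability).

    Returns a DataFrame with columns t, y, z, v_y, v_z, f_y, f_z and the
    attribute-like final column ``wall_hit``.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if particle_density is None:
        particle_density = fluid.density  # neutral buoyancy default
    g = model.geometry
    drag = 6.0 * np.pi * fluid.dynamic_viscosity * particle.radius_r
    volume = 4.0 / 3.0 * np.pi * particle.radius_r**3
    f_gz = -(particle_density - fluid.density) * volume * GRAVITY
    mass = particle_density * volume

    state = initial
    rows = []
    wall_hit = False
    n_steps = int(np.ceil(duration / step))
    for _ in range(n_steps + 1):
        voltages = schedule(state.time)
        f_dep = dep_force(state.y, state.z, model, voltages, particle, medium, drive)
        fy_ext = f_dep.f_y
        fz_ext = f_dep.f_z + f_gz
        if overdamped:
            vy, vz = fy_ext / drag, fz_ext / drag
        else:
            vy = state.v_y + step * (fy_ext - drag * state.v_y) / mass
            vz = state.v_z + step * (fz_ext - drag * state.v_z) / mass
        rows.append(
            {
                "t": state.time,
                "y": state.y,
                "z": state.z,
                "v_y": vy,
                "v_z": vz,
                "f_y": fy_ext,
                "f_z": fz_ext,
                "wall_hit": wall_hit,
            }
        )
        if wall_hit or state.time >= duration:
            break
        dy, dz = vy * step, vz * step
        if abs(dy) > g.width_L or abs(dz) > g.height_h:
            raise RuntimeError(
                "integration step moves the particle by more than a channel "
                "dimension; reduce the step size"
            )
        ny = state.y + dy
        nz = state.z + dz
        if not (0.0 < ny < g.width_L) or not (-g.height_h / 2 < nz < g.height_h / 2):
            ny = min(max(ny, 0.0), g.width_L)
            nz = min(max(nz, -g.height_h / 2), g.height_h / 2)
            wall_hit = True
        state = ParticleState(y=ny, z=nz, v_y=vy, v_z=vz, time=state.time + step)
    return pd.DataFrame(rows)
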
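"""Velocity-Verlet MD for the polymer and the hybrid MD + SRD loop.

Bead equations of motion are integrated with velocity Verlet at time step
``dt`` (default 0.005 tau, stable for the default FENE, wall and motor
stiffnesses up to T* = 1.2).  Every ``srd_timestep`` MD steps the solvent
streams ballistically over the same interval and one SRD collision couples
beads and solvent; with hydrodynamics off, solvent velocities are then
redrawn from the Maxwell–Boltzmann distribution.

All randomness flows from a single :class:`numpy.random.Generator` per
replicate, so trajectories are bit-for-bit reproducible for a fixed
(config, seed, build).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels, srd as srd_mod
from .config import SimulationConfig
from .errors import IntegratorInstabilityError
from .geometry import CapsidAssembly
from .potentials import InteractionParams, total_forces
from .srd import SolventState


@dataclass
class SystemState:
    """The single evolving object: polymer + solvent + clock."""

    bead_positions: np.ndarray
    bead_velocities: np.ndarray
    bead_mass: float = 1.0
    solvent: Optional[SolventState] = None
    step: int = 0
    dt: float = 0.005

    @property
    def time(self) -> float:
        return self.step * self.dt

    @property
    def n_beads(self) -> int:
        return len(self.bead_positions)

    def copy(self) -> "SystemState":
        return SystemState(
            self.bead_positions.copy(),
            self.bead_velocities.copy(),
            self.bead_mass,
            self.solvent.copy() if self.solvent is not None else None,
            self.step,
            self.dt,
        )


def velocity_verlet_step(
    state: SystemState,
    params: InteractionParams,
    assembly: CapsidAssembly | None = None,
    motor_on: bool = False,
    dt: float | None = None,
    reduced_temperature: float = 1.0,
) -> SystemState:
    """One velocity-Verlet step on the beads (reference implementation).

    Solvent particles are untouched (they advance via streaming in the
    hybrid loop).  Raises :class:`IntegratorInstabilityError` on an
    overstretched bond or non-finite force.
    """
    dt = state.dt if dt is None else dt
    if dt <= 0:
        raise IntegratorInstabilityError("time step must be positive")
    try:
        f0 = total_forces(
            state.bead_positions, params, assembly, motor_on, reduced_temperature
        )
        half = 0.5 * dt / state.bead_mass
        state.bead_velocities += half * f0
        state.bead_positions += dt * state.bead_velocities
        f1 = total_forces(
            state.bead_positions, params, assembly, motor_on, reduced_temperature
        )
        state.bead_velocities += half * f1
    except Exception as err:
        raise IntegratorInstabilityError(
            f"force evaluation failed at step {state.step}: {err}", step=state.step
        ) from err
    if not np.all(np.isfinite(state.bead_positions)):
        bead = int(np.argwhere(~np.isfinite(state.bead_positions))[0][0])
        raise IntegratorInstabilityError(
            f"non-finite coordinate at step {state.step}", step=state.step, bead=bead
        )
    state.step += 1
    return state


def hybrid_advance(
    state: SystemState,
    config: SimulationConfig,
    n_steps: int,
    rng: np.random.Generator,
    motor_on: bool = False,
    assembly: CapsidAssembly | None = None,
    anchor: int = -1,
) -> SystemState:
    """Advance ``n_steps`` MD steps with interleaved SRD solvent coupling.

    Repeats [``srd_timestep`` bead MD steps + solvent streaming over the
    same interval + grid-shifted collision (+ Maxwell–Boltzmann resampling
    when hydrodynamics is off)] until ``n_steps`` MD steps have elapsed.
    ``anchor`` >= 0 pins that bead in place (used during equilibration).
    Deterministic for a fixed generator state.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if n_steps == 0:
        return state

    params = config.interaction
    if assembly is None and config.geometry is not None:
        assembly = config.build_assembly()
    p = _kernels.pack_params(params, assembly, config.reduced_temperature, motor_on)
    sp = config.srd
    dt = config.dt
    solvent = state.solvent
    ncell = sp.n_cells_per_edge
    n_cells_total = ncell**3
    cos_a = math.cos(sp.rotation_angle)
    sin_a = math.sin(sp.rotation_angle)
    target_t = config.reduced_temperature

    forces = np.empty_like(state.bead_positions)
    status = _kernels.bead_forces(state.bead_positions, forces, p)
    _check(status, state.step)

    if solvent is None:
        done = 0
        while done < n_steps:
            n_sub = min(sp.srd_timestep, n_steps - done)
            status = _kernels.md_chunk(
                state.bead_positions, state.bead_velocities, forces,
                n_sub, dt, state.bead_mass, p, anchor,
            )
            _check(status, state.step + done)
            done += n_sub
    else:
        # one fused compiled loop; its internal RNG is re-seeded from the
        # caller's generator so trajectories stay reproducible
        _kernels.seed_kernel_rng(int(rng.integers(0, 2**31 - 1)))
        status = _kernels.advance_hybrid(
            state.bead_positions, state.bead_velocities, forces,
            solvent.positions, solvent.velocities,
            n_steps, sp.srd_timestep, dt, state.bead_mass, solvent.particle_mass,
            p, anchor, ncell, sp.cell_size, sp.box_edge, cos_a, sin_a,
            sp.grid_shift, not sp.hydrodynamics,
            sp.thermostat == "berendsen", target_t, sp.thermostat_tau,
        )
        _check(status, state.step)
    state.step += n_steps
    return state


def _check(status: int, step: int) -> None:
    if status != 0:
        raise IntegratorInstabilityError(
            f"integrator instability (overstretched bond or non-finite coordinate) "
            f"at bead {status - 1}, step {step}",
            step=step,
            bead=status - 1,
        )
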
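"""Stochastic rotation dynamics (multiparticle collision dynamics) solvent.

The solvent is a gas of point particles in a periodic cubic box.  Between
collisions particles stream ballistically; at each collision step all
particles (solvent and polymer beads together) are sorted into cubic cells
of side ``a`` and, cell by cell, every member's velocity relative to the
cell's mass-weighted center-of-mass velocity is rotated by a fixed angle
about a random axis.  This conserves momentum and kinetic energy per cell
exactly while exchanging momentum between beads and solvent — a
hydrodynamic thermostat.  A random grid shift restores Galilean
invariance.

Switching ``hydrodynamics`` off replaces every solvent velocity after each
collision by a fresh Maxwell–Boltzmann draw, which destroys the velocity
correlations that carry hydrodynamic interactions while leaving
equilibrium (static) polymer properties untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import AnalysisError, ConfigValidationError


@dataclass(frozen=True)
class SRDParams:
    """Solvent discretization parameters (reduced units).

    ``srd_timestep`` is the coupling interval in MD steps; the collision
    interval in reduced time is ``srd_timestep * dt``.  ``mean_density``
    (gamma) is the average number of solvent particles per cell; the
    solvent particle mass is ``1 / mean_density`` so that one bead weighs
    as much as the average cell content.  ``thermostat`` is "none" (pure
    SRD; energy conserving) or "berendsen" (gentle global rescaling of
    solvent velocity fluctuations toward the target temperature, used to
    drain the heat injected by the motor in driven runs).
    """

    cell_size: float = 1.0
    rotation_angle: float = math.radians(130.0)
    srd_timestep: int = 20
    mean_density: float = 5.0
    grid_shift: bool = True
    box_edge: float = 16.0
    hydrodynamics: bool = True
    thermostat: str = "berendsen"
    thermostat_tau: float = 10.0  # in collision steps

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ConfigValidationError("SRD cell size must be positive")
        if not (0 < self.rotation_angle < math.pi):
            raise ConfigValidationError("SRD rotation angle must lie in (0, pi)")
        n = self.box_edge / self.cell_size
        if abs(n - round(n)) > 1e-9:
            raise ConfigValidationError("box edge must be an integer multiple of the cell size")
        if self.srd_timestep < 1:
            raise ConfigValidationError("SRD coupling interval must be >= 1 MD step")
        if self.thermostat not in ("none", "berendsen"):
            raise ConfigValidationError(f"unknown thermostat {self.thermostat!r}")

    @property
    def n_cells_per_edge(self) -> int:
        return int(round(self.box_edge / self.cell_size))

    @property
    def particle_mass(self) -> float:
        return 1.0 / self.mean_density


@dataclass
class SolventState:
    """Positions and velocities of the solvent particles.

    Positions are kept wrapped into ``[-L/2, L/2)``; the particle count is
    constant over a run.
    """

    positions: np.ndarray
    velocities: np.ndarray
    particle_mass: float

    @property
    def count(self) -> int:
        return len(self.positions)

    def copy(self) -> "SolventState":
        return SolventState(self.positions.copy(), self.velocities.copy(), self.particle_mass)


def wrap_positions(positions: np.ndarray, box_edge: float) -> np.ndarray:
    """Wrap coordinates into the primary box [-L/2, L/2)."""
    return (positions + box_edge / 2.0) % box_edge - box_edge / 2.0


def initialize_solvent(params: SRDParams, reduced_temperature: float, rng: np.random.Generator) -> SolventState:
    """Uniform positions; Maxwell–Boltzmann velocities at exactly T*.

    The net momentum is zeroed and the speeds rescaled so the kinetic
    temperature equals the target exactly at step 0 (temperature control
    with hydrodynamics on is by initialization; pure SRD conserves energy).
    """
    n = int(round(params.mean_density * params.n_cells_per_edge**3))
    pos = rng.uniform(-params.box_edge / 2.0, params.box_edge / 2.0, size=(n, 3))
    vel = rng.normal(0.0, math.sqrt(reduced_temperature / params.particle_mass), size=(n, 3))
    vel -= vel.mean(axis=0)
    current_t = measure_kinetic_temperature(vel, params.particle_mass)
    vel *= math.sqrt(reduced_temperature / current_t)
    return SolventState(pos, vel, params.particle_mass)


def stream(solvent: SolventState, dt: float, box_edge: float) -> SolventState:
    """Ballistic update pos <- pos + v dt with periodic wrapping (in place)."""
    if dt <= 0:
        raise ConfigValidationError("streaming interval must be positive")
    solvent.positions += solvent.velocities * dt
    solvent.positions[:] = wrap_positions(solvent.positions, box_edge)
    return solvent


def grid_shift(params: SRDParams, rng: np.random.Generator) -> np.ndarray:
    """Random cell-grid offset, uniform in [-a/2, a/2)^3 (zero if disabled)."""
    if not params.grid_shift:
        return np.zeros(3)
    return rng.uniform(-params.cell_size / 2.0, params.cell_size / 2.0, size=3)


def _cell_indices(positions: np.ndarray, shift: np.ndarray, params: SRDParams) -> np.ndarray:
    """Flat cell index per particle after applying the grid shift."""
    ncell = params.n_cells_per_edge
    shifted = wrap_positions(positions + shift, params.box_edge)
    ijk = np.floor((shifted + params.box_edge / 2.0) / params.cell_size).astype(np.int64)
    ijk = np.clip(ijk, 0, ncell - 1)  # guard against rounding at the box edge
    return (ijk[:, 0] * ncell + ijk[:, 1]) * ncell + ijk[:, 2]


def _rotation_apply(v_rel: np.ndarray, axes: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of each row of ``v_rel`` about its own unit axis."""
    cos_a = math.cos(angle)
    sin_a = math.sin(angle)
    dot = np.einsum("ij,ij->i", axes, v_rel)[:, None]
    cross = np.cross(axes, v_rel)
    return v_rel * cos_a + cross * sin_a + axes * dot * (1.0 - cos_a)


def collide(
    solvent: SolventState,
    bead_positions: np.ndarray | None,
    bead_velocities: np.ndarray | None,
    bead_mass: float,
    params: SRDParams,
    rng: np.random.Generator,
    target_temperature: float | None = None,
) -> None:
    """One SRD collision step over solvent particles and polymer beads.

    All participants are binned into (randomly shifted) cells; in each
    occupied cell every member's velocity relative to the mass-weighted
    cell center-of-mass velocity is rotated by ``rotation_angle`` about a
    random axis drawn per cell.  Per-cell momentum and kinetic energy are
    conserved exactly.  Velocities are updated in place.

    When the Berendsen thermostat is enabled and ``target_temperature`` is
    given, solvent velocity fluctuations are afterwards rescaled toward the
    target with time constant ``thermostat_tau`` collisions.
    """
    n_solv = solvent.count
    if bead_positions is not None and len(bead_positions) > 0:
        bead_pos_wrapped = wrap_positions(np.asarray(bead_positions, dtype=float), params.box_edge)
        positions = np.vstack([solvent.positions, bead_pos_wrapped])
        velocities = np.vstack([solvent.velocities, bead_velocities])
        masses = np.concatenate(
            [np.full(n_solv, solvent.particle_mass), np.full(len(bead_positions), bead_mass)]
        )
    else:
        positions = solvent.positions
        velocities = np.vstack([solvent.velocities])
        masses = np.full(n_solv, solvent.particle_mass)

    shift = grid_shift(params, rng)
    cells = _cell_indices(positions, shift, params)
    n_cells_total = params.n_cells_per_edge**3

    mom = np.zeros((n_cells_total, 3))
    np.add.at(mom, cells, velocities * masses[:, None])
    mass_tot = np.bincount(cells, weights=masses, minlength=n_cells_total)
    occupied = mass_tot > 0
    vcm = np.zeros((n_cells_total, 3))
    vcm[occupied] = mom[occupied] / mass_tot[occupied, None]

    axes = rng.normal(size=(n_cells_total, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)

    v_rel = velocities - vcm[cells]
    velocities = vcm[cells] + _rotation_apply(v_rel, axes[cells], params.rotation_angle)

    solvent.velocities[:] = velocities[:n_solv]
    if bead_velocities is not None and len(velocities) > n_solv:
        bead_velocities[:] = velocities[n_solv:]

    if params.thermostat == "berendsen" and target_temperature is not None:
        _berendsen_rescale(solvent, params, target_temperature)


def _berendsen_rescale(solvent: SolventState, params: SRDParams, target: float) -> None:
    """Rescale solvent velocity fluctuations toward the target temperature."""
    vcm = solvent.velocities.mean(axis=0)
    rel = solvent.velocities - vcm
    t_inst = solvent.particle_mass * np.einsum("ij,ij->", rel, rel) / (3.0 * solvent.count)
    if t_inst <= 0:
        return
    lam = math.sqrt(max(1.0 + (target / t_inst - 1.0) / params.thermostat_tau, 0.0))
    solvent.velocities[:] = vcm + lam * rel


def resample_velocities_no_hydro(
    solvent: SolventState, reduced_temperature: float, rng: np.random.Generator
) -> None:
    """Replace every solvent velocity by a fresh Maxwell–Boltzmann draw.

    Called after each collision step when hydrodynamics is switched off:
    each component is an independent normal of variance k_B T* / m.  Bead
    velocities are untouched, so momentum still transfers to the polymer
    during the collision itself, but solvent velocity correlations — the
    carriers of hydrodynamic interactions — are erased.
    """
    solvent.velocities[:] = rng.normal(
        0.0, math.sqrt(reduced_temperature / solvent.particle_mass), size=solvent.velocities.shape
    )


def measure_kinetic_temperature(velocities: np.ndarray, mass: float) -> float:
    """Kinetic temperature T* = m <v^2> / 3 per particle (k_B = 1)."""
    velocities = np.atleast_2d(np.asarray(velocities, dtype=float))
    if len(velocities) < 1:
        raise AnalysisError("kinetic temperature of an empty particle set")
    return float(mass * np.einsum("ij,ij->", velocities, velocities) / (3.0 * len(velocities)))
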
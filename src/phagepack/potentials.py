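"""Intra-polymer energies and forces.

Four terms act between polymer beads:

* FENE bonds between consecutive beads,
  U(r) = -(1/2) k R0^2 ln(1 - (r/R0)^2) — finitely extensible, divergent
  at R0 so bonds cannot break or cross;
* excluded volume: Lennard-Jones truncated at 2^(1/6) sigma and shifted to
  zero (purely repulsive — good-solvent conditions);
* bending rigidity, U = kappa (1 - cos theta) per interior joint, which
  sets the persistence length;
* screened electrostatics (charged polymer only),
  U(r) = T* A exp(-r / lambda_D) / r, truncated at ``elec_cutoff``.
  The prefactor A collects the Bjerrum length and the squared effective
  bead charge; writing the energy proportional to T* makes the
  electrostatic forces grow with temperature at fixed screening.

Scalar pair functions return ``(energy, f)`` with ``f = -dU/dr``: positive
f is repulsive (pushes the pair apart), negative attractive.

The bonded (1-2) pairs are included in the excluded-volume sum (the
Kremer–Grest convention); the FENE + repulsion balance then puts the
equilibrium bond length near 0.97 sigma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry as geom
from .errors import (
    BondOverstretchError,
    ConfigValidationError,
    DegenerateGeometryError,
    SingularSeparationError,
)

#: Default bending constant, in epsilon per joint.  Chosen by
#: :func:`phagepack.observables.calibrate_bending_rigidity` so that the free
#: semiflexible chain has persistence length 10 sigma at T* = 1.
DEFAULT_BEND_KAPPA = 10.8

#: Default electrostatic prefactor A = l_B Z_eff^2 in sigma units.  Set so
#: that, tailless, full packing of the charged chain succeeds at T* = 1.0
#: but is frustrated at T* = 1.2 (see docs/methods.md for the calibration).
DEFAULT_CHARGE_PREFACTOR = 6.0


@dataclass(frozen=True)
class InteractionParams:
    """All intra-polymer potential constants, in reduced units."""

    fene_k: float = 30.0
    fene_r0: float = 1.5
    lj_epsilon: float = 1.0
    lj_sigma: float = 1.0
    lj_cutoff: float = 2.0 ** (1.0 / 6.0)
    bend_kappa: float = DEFAULT_BEND_KAPPA
    charged: bool = False
    charge_prefactor: float = DEFAULT_CHARGE_PREFACTOR
    debye_length: float = 0.75
    elec_cutoff: float = 3.0

    def __post_init__(self):
        if self.fene_r0 <= 1.0:
            raise ConfigValidationError(
                f"FENE maximum extension must exceed the bead diameter, got {self.fene_r0}"
            )
        for name in ("fene_k", "lj_epsilon", "bend_kappa", "charge_prefactor"):
            if getattr(self, name) < 0:
                raise ConfigValidationError(f"{name} must be >= 0")
        if self.debye_length <= 0:
            raise ConfigValidationError("Debye length must be positive")
        if self.elec_cutoff <= self.debye_length:
            raise ConfigValidationError(
                "electrostatic cutoff must be much greater than the Debye length"
            )


def fene_bond(r: float, params: InteractionParams) -> tuple[float, float]:
    """FENE bond energy and scalar force -dU/dr at separation ``r``.

    Raises :class:`BondOverstretchError` for r >= R0 (the potential
    diverges there; reaching it signals integrator instability).
    """
    r0 = params.fene_r0
    if r >= r0:
        raise BondOverstretchError(r, r0)
    x2 = (r / r0) ** 2
    energy = -0.5 * params.fene_k * r0**2 * np.log1p(-x2)
    force = -params.fene_k * r / (1.0 - x2)
    return energy, force


def excluded_volume(r: float, params: InteractionParams) -> tuple[float, float]:
    """Truncated-and-shifted Lennard-Jones energy and force -dU/dr."""
    if r <= 0:
        raise SingularSeparationError("excluded volume evaluated at r <= 0")
    if r >= params.lj_cutoff:
        return 0.0, 0.0
    eps, sig = params.lj_epsilon, params.lj_sigma
    sr6 = (sig / r) ** 6
    sc6 = (sig / params.lj_cutoff) ** 6
    shift = -4.0 * eps * (sc6**2 - sc6)
    energy = 4.0 * eps * (sr6**2 - sr6) + shift
    force = 24.0 * eps * (2.0 * sr6**2 - sr6) / r
    return energy, force


def bending(r1, r2, r3, params: InteractionParams) -> tuple[float, np.ndarray]:
    """Bending energy kappa (1 - cos theta) and forces on the triplet.

    ``theta`` is the angle between the consecutive bond vectors r2-r1 and
    r3-r2 (zero for a straight chain).  Returns ``(energy, forces)`` with
    ``forces`` of shape (3, 3); the three force vectors sum to zero and
    exert no net torque about the center bead.
    """
    r1, r2, r3 = (np.asarray(x, dtype=float) for x in (r1, r2, r3))
    b1 = r2 - r1
    b2 = r3 - r2
    n1 = np.linalg.norm(b1)
    n2 = np.linalg.norm(b2)
    if n1 == 0.0 or n2 == 0.0:
        raise DegenerateGeometryError("zero-length bond in bending triplet")
    e1 = b1 / n1
    e2 = b2 / n2
    c = float(e1 @ e2)
    energy = params.bend_kappa * (1.0 - c)
    # dU/dr_i = -kappa * d(cos theta)/dr_i; F_i = +kappa * d(cos theta)/dr_i
    dc_db1 = (e2 - c * e1) / n1
    dc_db2 = (e1 - c * e2) / n2
    f1 = -params.bend_kappa * dc_db1
    f2 = params.bend_kappa * (dc_db1 - dc_db2)
    f3 = params.bend_kappa * dc_db2
    return energy, np.stack([f1, f2, f3])


def electrostatic(r: float, reduced_temperature: float, params: InteractionParams) -> tuple[float, float]:
    """Screened-Coulomb pair energy and force -dU/dr.

    U(r) = T* A exp(-r / lambda_D) / r below the cutoff, zero beyond.  Both
    energy and force scale linearly with the reduced temperature.
    """
    if r <= 0:
        raise SingularSeparationError("electrostatic potential evaluated at r <= 0")
    if r >= params.elec_cutoff:
        return 0.0, 0.0
    lam = params.debye_length
    pref = reduced_temperature * params.charge_prefactor
    energy = pref * np.exp(-r / lam) / r
    force = energy * (1.0 / r + 1.0 / lam)
    return energy, force


def total_forces(
    bead_positions: np.ndarray,
    params: InteractionParams,
    assembly: geom.CapsidAssembly | None = None,
    motor_on: bool = False,
    reduced_temperature: float = 1.0,
) -> np.ndarray:
    """Per-bead total force: bonded + bending + nonbonded + geometry + motor.

    Reference (pure NumPy/Python) implementation; the production integrator
    uses an equivalent compiled kernel, and the two are held together by a
    consistency test.  Errors in pair terms are re-raised with the bead
    indices attached.
    """
    pos = np.asarray(bead_positions, dtype=float)
    n = len(pos)
    forces = np.zeros_like(pos)

    for i in range(n - 1):
        rij = pos[i + 1] - pos[i]
        r = float(np.linalg.norm(rij))
        try:
            _, f = fene_bond(r, params)
        except BondOverstretchError as err:
            raise BondOverstretchError(r, params.fene_r0, bead=i) from err
        # f = -dU/dr acts along the pair axis: positive pushes apart
        fvec = f * rij / r
        forces[i] -= fvec
        forces[i + 1] += fvec

    for i in range(1, n - 1):
        _, triplet = bending(pos[i - 1], pos[i], pos[i + 1], params)
        forces[i - 1] += triplet[0]
        forces[i] += triplet[1]
        forces[i + 1] += triplet[2]

    cutoff = max(params.lj_cutoff, params.elec_cutoff if params.charged else 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            rij = pos[j] - pos[i]
            r = float(np.linalg.norm(rij))
            if r >= cutoff:
                continue
            try:
                _, f = excluded_volume(r, params)
            except SingularSeparationError as err:
                raise SingularSeparationError(f"beads {i} and {j} coincide") from err
            if params.charged:
                f += electrostatic(r, reduced_temperature, params)[1]
            fvec = f * rij / r
            forces[i] -= fvec
            forces[j] += fvec

    if assembly is not None:
        for i in range(n):
            forces[i] += geom.wall_force(pos[i], assembly)
            forces[i] += geom.tail_retention_force(pos[i], assembly)
            forces[i] += geom.motor_force(pos[i], assembly, motor_on)
        # the wall repels the chain contour, not only bead centers: a bond
        # is longer (up to R0 = 1.5 sigma) than the wall shell is thick
        # (1 sigma), so two beads on opposite sides can bracket the wall
        # with neither feeling it, leaving the bond threaded through the
        # capsid — a stable, unphysical trap.  Evaluating the wall at each
        # bond midpoint (force split between the endpoints) makes any such
        # crossing unstable, since the midpoint always lies in the shell.
        for i in range(n - 1):
            mid_force = geom.wall_force(0.5 * (pos[i] + pos[i + 1]), assembly)
            forces[i] += 0.5 * mid_force
            forces[i + 1] += 0.5 * mid_force

    return forces


def total_energy(
    bead_positions: np.ndarray,
    params: InteractionParams,
    reduced_temperature: float = 1.0,
) -> float:
    """Total internal (bonded + bending + nonbonded) potential energy."""
    pos = np.asarray(bead_positions, dtype=float)
    n = len(pos)
    energy = 0.0
    for i in range(n - 1):
        energy += fene_bond(float(np.linalg.norm(pos[i + 1] - pos[i])), params)[0]
    for i in range(1, n - 1):
        energy += bending(pos[i - 1], pos[i], pos[i + 1], params)[0]
    for i in range(n):
        for j in range(i + 1, n):
            r = float(np.linalg.norm(pos[j] - pos[i]))
            energy += excluded_volume(min(r, params.lj_cutoff), params)[0] if r < params.lj_cutoff else 0.0
            if params.charged and r < params.elec_cutoff:
                energy += electrostatic(r, reduced_temperature, params)[0]
    return energy
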
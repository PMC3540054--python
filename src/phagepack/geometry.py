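"""Capsid geometry and geometry-derived forces.

The capsid is a rigid sphere of radius 3.02 sigma centered at the origin,
with a single pore on the +z axis wide enough for one bead at a time.  An
optional cylindrical tail (length 6 sigma, radius 0.7 sigma) is attached at
the pore, collinear with the pore axis.  The packaging motor is modeled as
a constant force applied to any bead near the capsid entrance, directed
toward the capsid center.

All geometry forces act on polymer beads only; the capsid is permeable to
the solvent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

from .errors import ConfigValidationError


class Region(str, Enum):
    """Mutually exclusive location classes for a bead center."""

    INSIDE_CAPSID = "inside_capsid"
    IN_PORE = "in_pore"
    IN_TAIL = "in_tail"
    OUTSIDE = "outside"


@dataclass(frozen=True)
class TailGeometry:
    """Cylindrical tail attached to the capsid opening, along +z.

    The axial extent runs from the capsid surface (z = R) to z = R + length.
    A bead is held inside by a linear restoring force once its radial
    distance from the axis exceeds ``radius - sigma/2``.
    """

    length: float = 6.0
    radius: float = 0.7
    retention_stiffness: float = 30.0

    def __post_init__(self):
        if self.length <= 0:
            raise ConfigValidationError(f"tail length must be positive, got {self.length}")
        if not (0 < self.radius < 1.0):
            raise ConfigValidationError(
                f"tail radius must lie in (0, sigma) for single-file transport, got {self.radius}"
            )


@dataclass(frozen=True)
class MotorSpec:
    """Constant-force motor at the capsid entrance.

    Any bead within ``capture_radius`` of the pore mouth feels a force of
    ``magnitude`` directed from the bead toward the capsid center.
    """

    magnitude: float = 80.0
    capture_radius: float = 1.5

    def __post_init__(self):
        if self.magnitude < 0:
            raise ConfigValidationError(f"motor force must be >= 0, got {self.magnitude}")


@dataclass(frozen=True)
class CapsidAssembly:
    """Capsid sphere + pore + optional tail + motor; owns geometry forces.

    The pore channel is the cylinder of radius ``pore_radius`` around +z
    spanning the wall shell; the capsid wall force is suppressed there so
    beads can translocate.
    """

    capsid_radius: float = 3.02
    pore_radius: float = 0.6
    wall_stiffness: float = 400.0
    wall_range: float = 0.5
    channel_centering: float = 300.0
    tail: Optional[TailGeometry] = None
    motor: MotorSpec = field(default_factory=MotorSpec)

    def __post_init__(self):
        if self.capsid_radius <= 0:
            raise ConfigValidationError("capsid radius must be positive")
        if not (0 < self.pore_radius < 1.0):
            raise ConfigValidationError(
                f"pore radius must lie in (0, sigma) to admit one bead at a time, got {self.pore_radius}"
            )

    @property
    def pore_center(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.capsid_radius])

    def _in_pore_channel(self, pos: np.ndarray) -> bool:
        rho = np.hypot(pos[0], pos[1])
        r = np.linalg.norm(pos)
        return (
            rho < self.pore_radius
            and pos[2] > 0
            and abs(r - self.capsid_radius) < self.wall_range
        )


def classify_position(pos, assembly: CapsidAssembly) -> Region:
    """Assign a bead center to exactly one region.

    Precedence: pore channel, then capsid interior (|pos| < R), then the
    tail cylinder (when present), else outside.
    """
    pos = np.asarray(pos, dtype=float)
    if assembly._in_pore_channel(pos):
        return Region.IN_PORE
    r = np.linalg.norm(pos)
    if r < assembly.capsid_radius:
        return Region.INSIDE_CAPSID
    tail = assembly.tail
    if tail is not None:
        rho = np.hypot(pos[0], pos[1])
        z0 = assembly.capsid_radius
        if rho <= tail.radius and z0 <= pos[2] <= z0 + tail.length:
            return Region.IN_TAIL
    return Region.OUTSIDE


def wall_force(pos, assembly: CapsidAssembly) -> np.ndarray:
    """Repulsive capsid-wall force on a bead at ``pos``.

    Zero outside a shell of half-width ``wall_range`` around the sphere
    surface and inside the pore channel.  Within the shell the force is
    radial with magnitude ``wall_stiffness * (wall_range - |d|)`` where d
    is the signed distance to the surface: beads inside are pushed toward
    the center, beads outside are pushed away (a hard wall approached from
    either side).
    """
    pos = np.asarray(pos, dtype=float)
    r = np.linalg.norm(pos)
    if r == 0.0:
        return np.zeros(3)
    d = r - assembly.capsid_radius
    if abs(d) >= assembly.wall_range:
        return np.zeros(3)
    if assembly._in_pore_channel(pos):
        # inside the channel the radial wall is off; a gentle centering
        # force keeps the translocating bead on the pore axis so chain
        # tension cannot drag it sideways out through the channel boundary
        rho = np.hypot(pos[0], pos[1])
        if rho == 0.0:
            return np.zeros(3)
        return assembly.channel_centering * -np.array([pos[0], pos[1], 0.0])
    if assembly.tail is not None:
        # the tail opening replaces the wall over its cross-section
        rho = np.hypot(pos[0], pos[1])
        if rho <= assembly.tail.radius and pos[2] > 0:
            return np.zeros(3)
    magnitude = assembly.wall_stiffness * (assembly.wall_range - abs(d))
    direction = pos / r * (-1.0 if d < 0 else 1.0)
    return magnitude * direction


def tail_retention_force(pos, assembly: CapsidAssembly) -> np.ndarray:
    """Restoring force confining a bead to the tail cylinder.

    Within the tail's axial extent, the force is zero for a bead within
    ``radius - sigma/2`` of the axis and otherwise points toward the axis
    with magnitude ``retention_stiffness * (rho - (radius - sigma/2))``, up
    to ``radius + sigma/2`` away; beyond that the bead is outside the
    tail's reach.  The one-sided inward pull both confines beads filing
    through the tube and guides a chain segment arriving at the tube onto
    its axis (the conduit actively engages the genome; without this, the
    sharp bend a coil must make at the tail tip is an absolute barrier to
    feeding at realistic forces).
    """
    tail = assembly.tail
    if tail is None:
        return np.zeros(3)
    pos = np.asarray(pos, dtype=float)
    z0 = assembly.capsid_radius
    if not (z0 <= pos[2] <= z0 + tail.length):
        return np.zeros(3)
    rho = np.hypot(pos[0], pos[1])
    free_radius = tail.radius - 0.5
    if rho <= free_radius or rho >= tail.radius + 0.5:
        return np.zeros(3)
    rho_hat = np.array([pos[0], pos[1], 0.0]) / rho
    return tail.retention_stiffness * (rho - free_radius) * -rho_hat


def motor_force(pos, assembly: CapsidAssembly, motor_on: bool) -> np.ndarray:
    """Constant motor force feeding captured beads into the capsid.

    Applied when ``motor_on`` and the bead lies within the capture sphere
    of radius ``capture_radius`` centered on the pore mouth (0, 0, R).
    Beads already inside the capsid are pulled toward the capsid center;
    a captured bead still outside is pulled toward a point just inside the
    pore, so the motor feeds it through the mouth instead of pinning it
    against the wall beside the opening.  At the pore mouth both rules give
    a force along the inward pore axis.
    """
    if not motor_on or assembly.motor.magnitude == 0.0:
        return np.zeros(3)
    pos = np.asarray(pos, dtype=float)
    if np.linalg.norm(pos - assembly.pore_center) >= assembly.motor.capture_radius:
        return np.zeros(3)
    r = np.linalg.norm(pos)
    if r == 0.0:
        return np.zeros(3)
    if r < assembly.capsid_radius:
        direction = -pos / r
    else:
        rho = np.hypot(pos[0], pos[1])
        # off-axis captured beads slide along the wall toward the mouth;
        # beads over the opening are fed down into the pore
        z_target = assembly.capsid_radius if rho > assembly.pore_radius \
            else assembly.capsid_radius - 0.5
        delta = np.array([0.0, 0.0, z_target]) - pos
        norm = np.linalg.norm(delta)
        if norm == 0.0:
            return np.zeros(3)
        direction = delta / norm
    return assembly.motor.magnitude * direction


def count_occupancy(bead_positions, assembly: CapsidAssembly) -> tuple[int, int]:
    """(beads inside the capsid sphere, beads in the tail).

    A bead counts as inside the capsid when its center lies strictly inside
    the sphere, including beads in the inner half of the pore channel.
    """
    pos = np.atleast_2d(np.asarray(bead_positions, dtype=float))
    n_inside = 0
    n_tail = 0
    for p in pos:
        region = classify_position(p, assembly)
        if region is Region.INSIDE_CAPSID:
            n_inside += 1
        elif region is Region.IN_PORE and np.linalg.norm(p) < assembly.capsid_radius:
            n_inside += 1
        elif region is Region.IN_TAIL:
            n_tail += 1
    return n_inside, n_tail
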
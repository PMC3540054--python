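"""Reduced-unit system and physical-unit conversions.

The simulation uses standard reduced (Lennard-Jones) units: the bead
diameter sigma is the unit of length, the excluded-volume well depth
epsilon the unit of energy, the bead mass the unit of mass, and
``tau = sigma * sqrt(m / epsilon)`` the unit of time.  The reduced
temperature is ``T* = k_B T / epsilon``, with ``T* = 1`` mapped to 37 degC
(310.15 K).

The physical anchors are:

* one reduced force unit = 1.6 pN,
* the capsid radius 3.02 sigma corresponds to 7.5 nm, fixing
  sigma = 7.5 / 3.02 nm (2.48 nm, nominally "2.5 nm" of double-stranded
  DNA diameter),
* the energy unit is k_B T at 37 degC, i.e. 4.28 pN nm (approx 4.3).

Note the force anchor is quoted independently of sigma and epsilon, so
``epsilon / sigma`` (1.72 pN) and the stated 1.6 pN force unit differ by
about 8%; both are kept as stated, and the force conversion always uses
the 1.6 pN anchor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from .errors import UnknownUnitKindError

#: Boltzmann constant, J/K (SI, exact by definition since 2019).
BOLTZMANN_J_PER_K = 1.380649e-23
#: Elementary charge, C (exact).
ELEMENTARY_CHARGE_C = 1.602176634e-19
#: Vacuum permittivity, F/m.
VACUUM_PERMITTIVITY_F_PER_M = 8.8541878128e-12
#: Reference absolute temperature for T* = 1 (37 degC).
REFERENCE_TEMPERATURE_K = 310.15


class PhysicalQuantity(NamedTuple):
    """A converted value together with its unit label."""

    value: float
    unit: str


@dataclass(frozen=True)
class UnitSystem:
    """Constants mapping reduced simulation units to physical units.

    Attributes
    ----------
    sigma_nm:
        Bead diameter in nm (7.5 / 3.02, from the 3.02-sigma, 7.5-nm capsid).
    epsilon_pNnm:
        Energy unit in pN nm; k_B * 310.15 K expressed in pN nm.
    force_unit_pN:
        One reduced force unit in pN.
    mass_unit:
        Bead mass in reduced units (always 1; physical mass not anchored).
    """

    sigma_nm: float = 7.5 / 3.02
    epsilon_pNnm: float = BOLTZMANN_J_PER_K * REFERENCE_TEMPERATURE_K * 1e21  # J -> pN nm
    force_unit_pN: float = 1.6
    mass_unit: float = 1.0

    @property
    def tau(self) -> float:
        """Reduced time unit sigma * sqrt(m / epsilon); equals 1 in reduced units."""
        return 1.0

    def to_physical(self, value: float, kind: str) -> PhysicalQuantity:
        """Convert a reduced quantity to physical units.

        ``kind`` is one of ``force`` (-> pN), ``length`` (-> nm), ``energy``
        (-> pN nm) or ``temperature`` (T* -> degC, with T* = 1 at 37 degC).
        """
        if kind == "force":
            return PhysicalQuantity(value * self.force_unit_pN, "pN")
        if kind == "length":
            return PhysicalQuantity(value * self.sigma_nm, "nm")
        if kind == "energy":
            return PhysicalQuantity(value * self.epsilon_pNnm, "pN nm")
        if kind == "temperature":
            return PhysicalQuantity(value * REFERENCE_TEMPERATURE_K - 273.15, "degC")
        raise UnknownUnitKindError(kind)

    def from_physical(self, value: float, kind: str) -> float:
        """Inverse of :meth:`to_physical` (takes the bare physical number)."""
        if kind == "force":
            return value / self.force_unit_pN
        if kind == "length":
            return value / self.sigma_nm
        if kind == "energy":
            return value / self.epsilon_pNnm
        if kind == "temperature":
            return (value + 273.15) / REFERENCE_TEMPERATURE_K
        raise UnknownUnitKindError(kind)


def thermal_energy_pNnm(temperature_celsius: float = 37.0) -> float:
    """k_B T in pN nm at the given temperature (4.28 pN nm at 37 degC)."""
    return BOLTZMANN_J_PER_K * (temperature_celsius + 273.15) * 1e21


def bjerrum_length_nm(temperature_celsius: float = 37.0, relative_permittivity: float = 80.0) -> float:
    """Bjerrum length l_B = e^2 / (4 pi eps0 eps_r k_B T), in nm.

    The separation at which two elementary charges interact with energy
    k_B T; about 0.7 nm in water at 37 degC.
    """
    t_kelvin = temperature_celsius + 273.15
    l_b_m = ELEMENTARY_CHARGE_C**2 / (
        4.0 * 3.141592653589793 * VACUUM_PERMITTIVITY_F_PER_M * relative_permittivity
        * BOLTZMANN_J_PER_K * t_kelvin
    )
    return l_b_m * 1e9


DEFAULT_UNITS = UnitSystem()
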
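"""Exception hierarchy.

Every failure mode that a caller may want to catch separately gets its own
named class; all inherit from :class:`PhagepackError`.
"""


class PhagepackError(Exception):
    """Base class for all package-specific errors."""


class ConfigFileNotFoundError(PhagepackError, FileNotFoundError):
    """The configuration file does not exist."""


class MalformedConfigError(PhagepackError, ValueError):
    """The configuration file could not be parsed, or contains unknown keys."""


class ConfigValidationError(PhagepackError, ValueError):
    """A configuration value violates a domain constraint (e.g. T* <= 0)."""


class UnknownUnitKindError(PhagepackError, KeyError):
    """Unit conversion requested for an unrecognized quantity kind."""


class BondOverstretchError(PhagepackError, ArithmeticError):
    """A FENE bond reached or exceeded its maximum extension R0."""

    def __init__(self, r: float, r0: float, bead: int | None = None, step: int | None = None):
        self.r, self.r0, self.bead, self.step = r, r0, bead, step
        loc = "" if bead is None else f" (bead {bead}" + ("" if step is None else f", step {step}") + ")"
        super().__init__(f"FENE bond length {r:.4g} >= maximum extension {r0:.4g}{loc}")


class SingularSeparationError(PhagepackError, ZeroDivisionError):
    """Pair potential evaluated at zero separation."""


class DegenerateGeometryError(PhagepackError, ArithmeticError):
    """Zero-length bond in a bending triplet (angle undefined)."""


class IntegratorInstabilityError(PhagepackError, ArithmeticError):
    """Non-finite force/coordinate or overstretched bond during integration."""

    def __init__(self, message: str, step: int | None = None, bead: int | None = None):
        self.step, self.bead = step, bead
        super().__init__(message)


class PlacementError(PhagepackError, RuntimeError):
    """Initial-configuration builder failed after bounded retries."""


class AnalysisError(PhagepackError, RuntimeError):
    """An observable could not be computed from the given data."""
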
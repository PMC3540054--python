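"""Validated run configuration.

A run is fully described by a :class:`SimulationConfig`: global physics
switches (temperature, charge, tail, hydrodynamics, motor force), run
lengths, replicate count and master seed, plus three nested parameter
blocks — ``interaction`` (:class:`~phagepack.potentials.InteractionParams`),
``geometry`` (capsid/pore/tail/motor constants) and ``srd``
(:class:`~phagepack.srd.SRDParams`).  Configurations load from flat YAML
files; every key is optional and takes the documented default.

Example YAML::

    reduced_temperature: 1.2
    charged: true
    tail_present: true
    n_replicates: 20
    interaction:
      bend_kappa: 10.5
    srd:
      box_edge: 12.0
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .errors import ConfigFileNotFoundError, ConfigValidationError, MalformedConfigError
from .geometry import CapsidAssembly, MotorSpec, TailGeometry
from .potentials import InteractionParams
from .srd import SRDParams


@dataclass(frozen=True)
class GeometryParams:
    """Capsid/pore/tail geometry constants (reduced units)."""

    capsid_radius: float = 3.02
    pore_radius: float = 0.6
    wall_stiffness: float = 400.0
    wall_range: float = 0.5
    channel_centering: float = 300.0
    tail_length: float = 6.0
    tail_radius: float = 0.7
    tail_stiffness: float = 30.0
    motor_capture_radius: float = 1.5


@dataclass(frozen=True)
class SimulationConfig:
    """Complete, validated description of one simulation experiment."""

    reduced_temperature: float = 1.0
    n_beads: int = 100
    charged: bool = False
    tail_present: bool = False
    hydrodynamics: bool = True
    motor_force: float = 80.0
    dt: float = 0.005
    equilibration_steps: int = 100_000
    max_steps: int = 2_000_000
    sampling_stride: int = 1_000
    n_replicates: int = 100
    seed: int = 0
    interaction: InteractionParams = field(default_factory=InteractionParams)
    geometry: GeometryParams = field(default_factory=GeometryParams)
    srd: SRDParams = field(default_factory=SRDParams)

    def __post_init__(self):
        if self.reduced_temperature <= 0:
            raise ConfigValidationError(
                f"reduced temperature must be positive, got {self.reduced_temperature}"
            )
        if self.n_beads < 3:
            raise ConfigValidationError(f"need at least 3 beads, got {self.n_beads}")
        if self.motor_force < 0:
            raise ConfigValidationError(f"motor force must be >= 0, got {self.motor_force}")
        if not (self.max_steps > self.equilibration_steps > 0):
            raise ConfigValidationError(
                "step counts must satisfy max_steps > equilibration_steps > 0"
            )
        if self.dt <= 0 or self.sampling_stride < 1 or self.n_replicates < 1:
            raise ConfigValidationError("dt, sampling_stride and n_replicates must be positive")
        # keep the flag pair coherent regardless of which block the user set
        object.__setattr__(self, "interaction", replace(self.interaction, charged=self.charged))
        object.__setattr__(self, "srd", replace(self.srd, hydrodynamics=self.hydrodynamics))

    def build_assembly(self, motor_force: float | None = None) -> CapsidAssembly:
        """Materialize the capsid assembly this configuration describes."""
        g = self.geometry
        tail = (
            TailGeometry(g.tail_length, g.tail_radius, g.tail_stiffness)
            if self.tail_present
            else None
        )
        motor = MotorSpec(
            magnitude=self.motor_force if motor_force is None else motor_force,
            capture_radius=g.motor_capture_radius,
        )
        return CapsidAssembly(
            capsid_radius=g.capsid_radius,
            pore_radius=g.pore_radius,
            wall_stiffness=g.wall_stiffness,
            wall_range=g.wall_range,
            channel_centering=g.channel_centering,
            tail=tail,
            motor=motor,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["srd"]["rotation_angle_deg"] = math.degrees(self.srd.rotation_angle)
        return d


_BLOCK_TYPES = {
    "interaction": InteractionParams,
    "geometry": GeometryParams,
    "srd": SRDParams,
}


def _build_block(cls, data: dict, block: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    if block == "srd" and "rotation_angle_deg" in data:
        data = dict(data)
        data["rotation_angle"] = math.radians(data.pop("rotation_angle_deg"))
    unknown = set(data) - fields
    if unknown:
        raise MalformedConfigError(f"unknown keys in '{block}' block: {sorted(unknown)}")
    return cls(**data)


def config_from_dict(data: dict) -> SimulationConfig:
    """Build a validated :class:`SimulationConfig` from a nested dict."""
    if not isinstance(data, dict):
        raise MalformedConfigError(f"configuration root must be a mapping, got {type(data).__name__}")
    data = dict(data)
    kwargs = {}
    for block, cls in _BLOCK_TYPES.items():
        if block in data:
            block_data = data.pop(block)
            if not isinstance(block_data, dict):
                raise MalformedConfigError(f"'{block}' must be a mapping")
            kwargs[block] = _build_block(cls, block_data, block)
    top_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(data) - top_fields
    if unknown:
        raise MalformedConfigError(f"unknown configuration keys: {sorted(unknown)}")
    kwargs.update(data)
    return SimulationConfig(**kwargs)


def load_config(path: str | Path) -> SimulationConfig:
    """Load and validate a YAML configuration file.

    Missing file, unparseable text, unknown keys and domain violations each
    raise their own error class (see :mod:`phagepack.errors`).  An empty
    file yields the all-defaults configuration.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigFileNotFoundError(f"configuration file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as err:
        raise MalformedConfigError(f"could not parse {path}: {err}") from err
    if data is None:
        data = {}
    return config_from_dict(data)
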
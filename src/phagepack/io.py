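"""Trajectory/time-series output, checkpoints and run manifests.

Trajectories are plain multi-frame XYZ (readable by any molecular viewer):
one element tag per bead role — ``C`` for ordinary beads, ``N`` for the
first (leading) bead, ``O`` for an anchored bead — with the step count and
occupancy on the comment line.  Time series and ensemble curves are CSV;
run manifests are JSON carrying everything needed to reproduce a run
bit-for-bit with the same build (config echo, master and derived seeds,
package version, output checksums).
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .errors import AnalysisError
from .geometry import CapsidAssembly, count_occupancy
from .integrator import SystemState
from .protocols import EnsembleResult, RunRecord, config_hash, derive_replicate_seeds


def write_trajectory(
    states: Sequence[SystemState],
    path: str | Path,
    assembly: Optional[CapsidAssembly] = None,
    anchor: int = -1,
) -> Path:
    """Write sampled states as multi-frame XYZ (beads only by default)."""
    if len(states) == 0:
        raise AnalysisError("no frames to write")
    path = Path(path)
    lines = []
    for state in states:
        n = state.n_beads
        if assembly is not None:
            n_in, n_tail = count_occupancy(state.bead_positions, assembly)
            comment = f"step={state.step} beads_inside={n_in} beads_in_tail={n_tail}"
        else:
            comment = f"step={state.step}"
        lines.append(str(n))
        lines.append(comment)
        for i, (x, y, z) in enumerate(state.bead_positions):
            tag = "O" if i == anchor else ("N" if i == 0 else "C")
            lines.append(f"{tag} {x:.6f} {y:.6f} {z:.6f}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_trajectory(path: str | Path) -> list[np.ndarray]:
    """Read a multi-frame XYZ file back into coordinate arrays."""
    lines = Path(path).read_text().splitlines()
    frames = []
    i = 0
    while i < len(lines):
        n = int(lines[i])
        coords = np.array(
            [[float(v) for v in ln.split()[1:4]] for ln in lines[i + 2 : i + 2 + n]]
        )
        frames.append(coords)
        i += 2 + n
    return frames


def write_timeseries(record: RunRecord, path: str | Path, dt: float = 0.005) -> Path:
    """Per-replicate CSV: step, time, beads_inside, beads_in_tail."""
    if len(record.steps) == 0:
        raise AnalysisError("empty time series")
    path = Path(path)
    df = pd.DataFrame(
        {
            "step": record.steps,
            "time": record.steps * dt,
            "beads_inside": record.beads_inside,
            "beads_in_tail": record.beads_in_tail,
        }
    )
    df.to_csv(path, index=False)
    return path


def write_ensemble_timeseries(result: EnsembleResult, path: str | Path, dt: float = 0.005) -> Path:
    """Ensemble CSV: time, mean, sem, n_active."""
    if len(result.time_grid) == 0:
        raise AnalysisError("empty ensemble")
    path = Path(path)
    df = pd.DataFrame(
        {
            "step": result.time_grid,
            "time": result.time_grid * dt,
            "mean": result.mean_inside,
            "sem": result.sem_inside,
            "n_active": result.n_active,
        }
    )
    df.to_csv(path, index=False)
    return path


def save_checkpoint(state: SystemState, path: str | Path) -> Path:
    """Full system state (beads + solvent + clock) as a compressed npz."""
    path = Path(path)
    payload = {
        "bead_positions": state.bead_positions,
        "bead_velocities": state.bead_velocities,
        "bead_mass": np.array(state.bead_mass),
        "step": np.array(state.step),
        "dt": np.array(state.dt),
    }
    if state.solvent is not None:
        payload["solvent_positions"] = state.solvent.positions
        payload["solvent_velocities"] = state.solvent.velocities
        payload["solvent_mass"] = np.array(state.solvent.particle_mass)
    np.savez_compressed(path, **payload)
    return path


def load_checkpoint(path: str | Path) -> SystemState:
    from .srd import SolventState

    with np.load(path) as data:
        solvent = None
        if "solvent_positions" in data:
            solvent = SolventState(
                data["solvent_positions"].copy(),
                data["solvent_velocities"].copy(),
                float(data["solvent_mass"]),
            )
        return SystemState(
            data["bead_positions"].copy(),
            data["bead_velocities"].copy(),
            float(data["bead_mass"]),
            solvent,
            int(data["step"]),
            float(data["dt"]),
        )


@dataclass
class RunManifest:
    """Provenance record written alongside every output directory."""

    config: dict
    config_hash: str
    master_seed: int
    replicate_seeds: list[int]
    version: str
    started: str
    finished: Optional[str] = None
    outputs: dict[str, str] = field(default_factory=dict)  # filename -> sha256

    @classmethod
    def start(cls, config: SimulationConfig) -> "RunManifest":
        from . import __version__

        return cls(
            config=config.to_dict(),
            config_hash=config_hash(config),
            master_seed=config.seed,
            replicate_seeds=derive_replicate_seeds(config.seed, config.n_replicates),
            version=__version__,
            started=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        )

    def register(self, path: Path) -> None:
        self.outputs[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()

    def finish(self, path: str | Path) -> Path:
        self.finished = datetime.datetime.now(datetime.timezone.utc).isoformat()
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str) + "\n")
        return path
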
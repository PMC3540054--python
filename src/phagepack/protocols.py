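"""Experiment drivers: initial states, equilibration, packing, ejection,
replicate ensembles.

The packing protocol follows the sequence: build an initial state with one
bead just inside the pore and the rest threaded outward, equilibrate with
that bead pinned and the motor off, then switch the motor on and advance
until every bead is inside the capsid or the step budget runs out.

Ejection starts from a packed state: the chain end nearest the pore is
pulled out to just beyond the pore (or the tail mouth, when a tail is
present) by a slow steered extraction, the system is re-equilibrated with
that bead pinned, and the run proceeds with the motor off until no bead
remains in the capsid or tail.

A replicate ensemble runs independent copies with seeds derived from the
master seed via ``numpy.random.SeedSequence.spawn``, and aggregates mean
+/- SEM occupancy curves on a common time grid (last observation carried
forward once a replicate finishes: N for completed packing, 0 for
completed ejection).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .config import SimulationConfig
from .errors import IntegratorInstabilityError, PlacementError
from .geometry import CapsidAssembly, count_occupancy
from .integrator import SystemState, hybrid_advance
from .srd import initialize_solvent

_BOND = 0.97  # construction bond length (the FENE + excluded-volume minimum)


@dataclass
class RunRecord:
    """One replicate's occupancy time series and outcome."""

    replicate_id: int
    mode: str  # "packing" | "ejection"
    steps: np.ndarray  # MD steps since the production phase started
    beads_inside: np.ndarray
    beads_in_tail: np.ndarray
    event_time: Optional[int]  # steps to completion, None if not reached
    status: str  # "completed" | "timeout" | "failed"
    seed: int
    config_hash: str
    error: Optional[str] = None
    final_state: Optional[SystemState] = field(default=None, repr=False)


@dataclass
class EnsembleResult:
    """Replicate collection with mean +/- SEM curves and event times."""

    records: list[RunRecord]
    mode: str
    time_grid: np.ndarray
    mean_inside: np.ndarray
    sem_inside: np.ndarray
    n_active: np.ndarray
    event_times: np.ndarray  # completed replicates only
    completion_fraction: float
    max_steps: int
    n_beads: int = 0

    def mean_event_time(self, include_timeouts: bool = False) -> float:
        """Mean completion time; timeouts optionally counted at the budget."""
        times = list(self.event_times)
        if include_timeouts:
            times += [self.max_steps] * sum(1 for r in self.records if r.status == "timeout")
        return float(np.mean(times)) if times else math.nan

    def completion_fraction_at(self, budget: int) -> float:
        """Fraction of replicates completed within ``budget`` steps."""
        ok = [r for r in self.records if r.status != "failed"]
        if not ok:
            return math.nan
        done = sum(1 for r in ok if r.event_time is not None and r.event_time <= budget)
        return done / len(ok)

    def slowness_area(self, horizon: int | None = None) -> float:
        """Integral measure of how slowly the process ran, in bead-steps.

        For packing, the area under (N - mean beads inside) up to
        ``horizon``; for ejection, the area under the mean occupancy.
        Larger = slower.  Far less noisy than single event times for
        ordering comparisons between conditions, because it averages the
        whole trajectory.  Beyond the recorded grid the mean curve is
        extended at its final value.
        """
        horizon = self.max_steps if horizon is None else horizon
        grid = self.time_grid
        curve = self.mean_inside
        if grid[-1] < horizon:
            grid = np.append(grid, horizon)
            curve = np.append(curve, curve[-1])
        else:
            keep = grid <= horizon
            grid, curve = grid[keep], curve[keep]
        deficit = (self.n_beads - curve) if self.mode == "packing" else curve
        return float(np.trapezoid(deficit, grid))


def config_hash(config: SimulationConfig) -> str:
    """Stable short hash of the full configuration (for provenance)."""
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def derive_replicate_seeds(master_seed: int, n: int) -> list[int]:
    """Independent per-replicate seeds from the master seed (documented
    splitting rule: ``SeedSequence(master).spawn(n)``, one child each)."""
    return [int(ss.generate_state(1)[0]) for ss in np.random.SeedSequence(master_seed).spawn(n)]


# ---------------------------------------------------------------------------
# initial states


def _thread_chain(config: SimulationConfig, assembly: CapsidAssembly, rng: np.random.Generator) -> np.ndarray:
    """Bead 1 just inside the pore, the rest single-file through the pore
    (and tail) then a clash-free persistent coil outside."""
    n = config.n_beads
    r_capsid = assembly.capsid_radius
    tail_len = assembly.tail.length if assembly.tail is not None else 0.0
    pos = np.zeros((n, 3))
    pos[0] = (0.0, 0.0, r_capsid - 0.6)
    # single-file region: through the pore and past the tail tip
    z_free = r_capsid + tail_len + 1.0
    i = 1
    while i < n and pos[i - 1, 2] < z_free:
        pos[i] = pos[i - 1] + (0.0, 0.0, _BOND)
        i += 1
    direction = np.array([0.0, 0.0, 1.0])
    while i < n:
        placed = False
        for _ in range(200):
            trial_dir = direction + 0.45 * rng.normal(size=3)
            trial_dir /= np.linalg.norm(trial_dir)
            trial = pos[i - 1] + _BOND * trial_dir
            if np.linalg.norm(trial) < r_capsid + 0.6:
                continue
            rho = math.hypot(trial[0], trial[1])
            if tail_len and trial[2] < z_free and rho < (assembly.tail.radius + 1.0):
                continue
            if i > 1 and np.min(np.linalg.norm(pos[: i - 1] - trial, axis=1)) < 0.9:
                continue
            pos[i] = trial
            direction = trial_dir
            placed = True
            break
        if not placed:
            # fall back to continuing straight along the previous direction
            pos[i] = pos[i - 1] + _BOND * direction
        i += 1
    return pos


def build_initial_packing_state(
    config: SimulationConfig, assembly: CapsidAssembly, rng: np.random.Generator
) -> SystemState:
    """Initial condition for packing: one bead inside, the rest outside.

    Bead velocities are Maxwell–Boltzmann at the target temperature; the
    solvent fills the periodic box uniformly at the same temperature.
    """
    for _ in range(20):
        pos = _thread_chain(config, assembly, rng)
        d = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(d, axis=-1) + np.eye(config.n_beads) * 10.0
        if dist.min() >= 0.9:
            break
    else:
        raise PlacementError("could not build a clash-free initial chain")
    vel = rng.normal(0.0, math.sqrt(config.reduced_temperature), size=pos.shape)
    vel -= vel.mean(axis=0)
    solvent = initialize_solvent(config.srd, config.reduced_temperature, rng)
    return SystemState(pos, vel, 1.0, solvent, step=0, dt=config.dt)


def equilibrate(
    state: SystemState,
    config: SimulationConfig,
    rng: np.random.Generator,
    anchor: int = 0,
    n_steps: int | None = None,
) -> SystemState:
    """Relax the chain with the motor off and ``anchor`` pinned in place.

    The anchor (bead 1 inside the capsid for packing; the extracted end
    bead for ejection) does not move; it is released on return.
    """
    n_steps = config.equilibration_steps if n_steps is None else n_steps
    return hybrid_advance(state, config, n_steps, rng, motor_on=False, anchor=anchor)


# ---------------------------------------------------------------------------
# production runs


def _production_run(
    state: SystemState,
    config: SimulationConfig,
    rng: np.random.Generator,
    mode: str,
    replicate_id: int,
    seed: int,
) -> RunRecord:
    assembly = config.build_assembly()
    motor_on = mode == "packing"
    n = config.n_beads
    stride = config.sampling_stride
    chash = config_hash(config)

    steps = [0]
    n_in, n_tail = count_occupancy(state.bead_positions, assembly)
    inside = [n_in]
    in_tail = [n_tail]
    event_time = None
    status = "timeout"
    error = None
    elapsed = 0
    try:
        while elapsed < config.max_steps:
            chunk = min(stride, config.max_steps - elapsed)
            hybrid_advance(state, config, chunk, rng, motor_on=motor_on, assembly=assembly)
            elapsed += chunk
            n_in, n_tail = count_occupancy(state.bead_positions, assembly)
            steps.append(elapsed)
            inside.append(n_in)
            in_tail.append(n_tail)
            if mode == "packing" and n_in == n:
                event_time, status = elapsed, "completed"
                break
            if mode == "ejection" and n_in + n_tail == 0:
                event_time, status = elapsed, "completed"
                break
    except IntegratorInstabilityError as err:
        status, error = "failed", str(err)

    return RunRecord(
        replicate_id=replicate_id,
        mode=mode,
        steps=np.asarray(steps),
        beads_inside=np.asarray(inside),
        beads_in_tail=np.asarray(in_tail),
        event_time=event_time,
        status=status,
        seed=seed,
        config_hash=chash,
        error=error,
        final_state=state,
    )


def run_packing(
    state: SystemState,
    config: SimulationConfig,
    rng: np.random.Generator,
    replicate_id: int = 0,
    seed: int = -1,
) -> RunRecord:
    """Motor on; advance until all beads are inside or the budget is hit."""
    return _production_run(state, config, rng, "packing", replicate_id, seed)


def run_ejection(
    state: SystemState,
    config: SimulationConfig,
    rng: np.random.Generator,
    replicate_id: int = 0,
    seed: int = -1,
) -> RunRecord:
    """Motor off; advance until capsid and tail are empty or budget is hit."""
    return _production_run(state, config, rng, "ejection", replicate_id, seed)


def build_initial_ejection_state(
    packed_state: SystemState,
    config: SimulationConfig,
    rng: np.random.Generator,
    equilibration_steps: int | None = None,
) -> SystemState:
    """Pull one chain end out of a packed capsid to initiate ejection.

    The chain end nearest the pore is extracted by a slow steered pull
    (small axial displacements of the pinned end bead, each followed by a
    short relaxation) to just beyond the pore — or beyond the tail mouth
    when a tail is present — then the system is equilibrated with that
    bead pinned.  The pin is released on return.
    """
    assembly = config.build_assembly()
    state = packed_state.copy()
    n = state.n_beads
    pore = assembly.pore_center
    end = 0 if np.linalg.norm(state.bead_positions[0] - pore) <= np.linalg.norm(
        state.bead_positions[n - 1] - pore
    ) else n - 1

    tail_len = assembly.tail.length if assembly.tail is not None else 0.0
    z_exit = assembly.capsid_radius + tail_len + 0.35
    # waypoints: straight to the pore mouth from inside, then out along the axis
    targets = [np.array([0.0, 0.0, assembly.capsid_radius - 0.45])]
    z = assembly.capsid_radius - 0.45
    while z < z_exit:
        z = min(z + 0.35, z_exit)
        targets.append(np.array([0.0, 0.0, z]))

    step_size = 0.06
    relax_steps = 60
    for target in targets:
        while True:
            delta = target - state.bead_positions[end]
            dist = np.linalg.norm(delta)
            if dist < 1e-9:
                break
            state.bead_positions[end] += delta * min(1.0, step_size / dist)
            state.bead_velocities[end] = 0.0
            hybrid_advance(state, config, relax_steps, rng, motor_on=False,
                           assembly=assembly, anchor=end)
            if dist <= step_size:
                break

    equilibrate(state, config, rng, anchor=end, n_steps=equilibration_steps)
    return state


def pack_replicate(config: SimulationConfig, seed: int, replicate_id: int = 0) -> RunRecord:
    """Full packing protocol for one replicate: build, equilibrate, pack."""
    rng = np.random.default_rng(seed)
    assembly = config.build_assembly()
    state = build_initial_packing_state(config, assembly, rng)
    equilibrate(state, config, rng, anchor=0)
    return run_packing(state, config, rng, replicate_id, seed)


def eject_replicate(
    config: SimulationConfig,
    seed: int,
    replicate_id: int = 0,
    packing_temperature: float = 1.0,
    packed_state: SystemState | None = None,
) -> RunRecord:
    """Full ejection protocol for one replicate.

    The packed initial state is produced by running the packing protocol
    first (at ``packing_temperature``, where full packing is reliable —
    the charged chain does not pack at high T*), unless a cached
    ``packed_state`` is supplied.  Ejection itself runs at the configured
    temperature.
    """
    rng = np.random.default_rng(seed)
    if packed_state is None:
        pack_config = replace(config, reduced_temperature=packing_temperature)
        record = pack_replicate(pack_config, seed, replicate_id)
        if record.status != "completed":
            return RunRecord(
                replicate_id=replicate_id,
                mode="ejection",
                steps=np.array([0]),
                beads_inside=np.array([config.n_beads]),
                beads_in_tail=np.array([0]),
                event_time=None,
                status="failed",
                seed=seed,
                config_hash=config_hash(config),
                error=f"packing stage did not complete (status={record.status})",
            )
        packed_state = record.final_state
    state = build_initial_ejection_state(packed_state, config, rng)
    return run_ejection(state, config, rng, replicate_id, seed)


# ---------------------------------------------------------------------------
# ensembles


def run_ensemble(
    config: SimulationConfig,
    mode: str = "packing",
    packing_temperature: float = 1.0,
    progress: bool = False,
) -> EnsembleResult:
    """Independent replicates with derived seeds, aggregated mean +/- SEM.

    ``mode`` is "packing" or "ejection".  Failed replicates are reported
    in the records but excluded from the curves.
    """
    if mode not in ("packing", "ejection"):
        raise ValueError(f"unknown mode {mode!r}")
    seeds = derive_replicate_seeds(config.seed, config.n_replicates)
    iterator = enumerate(seeds)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(list(iterator), desc=f"{mode} ensemble")
    records = []
    for rep, seed in iterator:
        if mode == "packing":
            records.append(pack_replicate(config, seed, rep))
        else:
            records.append(eject_replicate(config, seed, rep, packing_temperature))
    return aggregate_records(records, mode, config)


def aggregate_records(
    records: list[RunRecord], mode: str, config: SimulationConfig
) -> EnsembleResult:
    """Mean/SEM occupancy curves on the union time grid (LOCF after
    completion: N for packing, 0 for ejection)."""
    ok = [r for r in records if r.status != "failed"]
    if not ok:
        grid = np.array([0])
        nanrow = np.array([math.nan])
        return EnsembleResult(records, mode, grid, nanrow, nanrow, np.array([0]),
                              np.array([]), 0.0, config.max_steps, config.n_beads)
    stride = config.sampling_stride
    horizon = max(int(r.steps[-1]) for r in ok)
    grid = np.arange(0, horizon + stride, stride)
    curves = np.full((len(ok), len(grid)), math.nan)
    for k, r in enumerate(ok):
        occupied = r.beads_inside + (r.beads_in_tail if mode == "ejection" else 0)
        idx = np.searchsorted(grid, r.steps)
        curves[k, idx] = occupied
        last = idx[-1]
        if r.status == "completed":
            curves[k, last:] = config.n_beads if mode == "packing" else 0
        else:
            curves[k, last:] = occupied[-1]
    n_active = np.sum(~np.isnan(curves), axis=0)
    mean = np.nanmean(curves, axis=0)
    with np.errstate(invalid="ignore"):
        sem = np.nanstd(curves, axis=0, ddof=1) / np.sqrt(np.maximum(n_active, 1))
    sem = np.where(n_active > 1, sem, 0.0)
    event_times = np.array([r.event_time for r in ok if r.event_time is not None], dtype=float)
    completion = len(event_times) / len(ok)
    return EnsembleResult(records, mode, grid, mean, sem, n_active,
                          event_times, completion, config.max_steps, config.n_beads)
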
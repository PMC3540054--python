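"""Scaled-down study conditions shared by the qualitative-ordering tests.

The full-size experiments (N = 100 beads, capsid radius 3.02 sigma,
16-sigma box, 100 replicates, ~2e6-step budgets) are cluster-scale.  The
orderings are instead checked on a scaled system chosen to preserve the
driving physics (see docs/methods.md): N = 40 beads in a 12-sigma box
with a 2.25-sigma capsid (same packing fraction as full scale), dt =
0.004 tau, and per-comparison motor forces scaled so that each mechanism
— entropic tail guidance, electrostatic frustration, conduit drag — is
rate-limiting rather than drowned by the drive, mirroring the balance the
full-size system has at motor force 80.

Each comparison uses paired replicate seeds (the same initial chains and
solvent across the compared conditions) for variance reduction, and
packed states are prepared once per seed and shared across the ejection
conditions that start from them.
"""

from __future__ import annotations

import numpy as np

from phagepack.config import SimulationConfig, config_from_dict
from phagepack import protocols as prot

N_BEADS = 40
PACK_BUDGET = 400_000
EJECT_BUDGET = 300_000
EJECT_BUDGET_TAIL_PAIR = 600_000
CHARGE_PREFACTOR = 12.0
CHARGE_PREFACTOR_STALL = 24.0  # electrostatic-frustration comparison
MOTOR_NEUTRAL_PAIR = 12.0      # entropy-limited regime for the neutral tail pair
MOTOR_STANDARD = 20.0
SEEDS_8 = list(range(1, 9))
SEEDS_10 = list(range(1, 11))


def scaled_config(**overrides) -> SimulationConfig:
    base = {
        "n_beads": N_BEADS,
        "dt": 0.004,
        "motor_force": MOTOR_STANDARD,
        "equilibration_steps": 30_000,
        "max_steps": PACK_BUDGET,
        "sampling_stride": 5_000,
        "interaction": {"charge_prefactor": CHARGE_PREFACTOR},
        "geometry": {"capsid_radius": 2.25},
        "srd": {"box_edge": 12.0},
    }
    for key, value in overrides.items():
        if key in ("interaction", "geometry", "srd"):
            base[key].update(value)
        else:
            base[key] = value
    return config_from_dict(base)


def pack_ensemble(seeds, **overrides):
    """Paired-seed packing ensemble; returns (config, result, records)."""
    config = scaled_config(**overrides)
    records = [prot.pack_replicate(config, seed=s, replicate_id=i)
               for i, s in enumerate(seeds)]
    result = prot.aggregate_records(records, "packing", config)
    return config, result, records


def eject_ensemble(packed_records, seeds, **overrides):
    """Ejections from cached packed states (shared across conditions)."""
    config = scaled_config(**overrides)
    records = []
    for i, (s, packed) in enumerate(zip(seeds, packed_records)):
        if packed.status != "completed":
            continue
        records.append(prot.eject_replicate(
            config, seed=s + 5_000, replicate_id=i, packed_state=packed.final_state
        ))
    result = prot.aggregate_records(records, "ejection", config)
    return config, result, records


def mean_event_time(result) -> float:
    """Mean completion time with timeouts counted at the budget."""
    return result.mean_event_time(include_timeouts=True)


def record_slowness(record, n_beads: int, horizon: int) -> float:
    """Per-replicate packing slowness: area under (N - beads inside) up to
    ``horizon`` (completed runs contribute zero deficit after the event)."""
    steps = record.steps
    deficit = n_beads - record.beads_inside
    if steps[-1] < horizon:
        steps = np.append(steps, horizon)
        deficit = np.append(deficit, 0 if record.status == "completed" else deficit[-1])
    keep = steps <= horizon
    return float(np.trapezoid(deficit[keep], steps[keep]))


def paired_gap(records_a, records_b, n_beads: int, horizon: int) -> float:
    """Mean paired difference of per-replicate slowness (a minus b)."""
    diffs = [
        record_slowness(ra, n_beads, horizon) - record_slowness(rb, n_beads, horizon)
        for ra, rb in zip(records_a, records_b)
        if ra.status != "failed" and rb.status != "failed"
    ]
    return float(np.mean(diffs))
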
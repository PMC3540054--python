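"""Ejection from a capsid with and without a tail.

Packs a short chain, then releases the motor and follows ejection.  The
cylindrical tail slows ejection: beads must file through it, and the last
few can linger there — compare the two final-stage curves.
"""

import numpy as np

from phagepack import eject_replicate
from phagepack.config import config_from_dict

base = {
    "n_beads": 20,
    "reduced_temperature": 1.0,
    "equilibration_steps": 10_000,
    "max_steps": 300_000,
    "sampling_stride": 10_000,
    "srd": {"box_edge": 8.0},
}

for tail in (False, True):
    config = config_from_dict({**base, "tail_present": tail})
    times = []
    for seed in (11, 12, 13):
        rec = eject_replicate(config, seed=seed)
        times.append(rec.event_time if rec.event_time is not None else config.max_steps)
    label = "with tail " if tail else "tailless  "
    print(f"{label}: ejection times {times}  mean {np.mean(times):.0f} steps")

# Ejection is driven only by confinement entropy (and electrostatics for a
# charged chain): with a tail the chain must also thread a narrow conduit,
# so mean ejection time grows and the spread widens.
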
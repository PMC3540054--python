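"""Protocol drivers on a small, fast system: initial states, equilibration
pinning, packing/ejection termination, ensemble aggregation."""

import numpy as np
import pytest

from phagepack import count_occupancy
from phagepack.config import config_from_dict
from phagepack import protocols as prot


def tiny_config(**overrides):
    base = {
        "n_beads": 12,
        "equilibration_steps": 2_000,
        "max_steps": 60_000,
        "sampling_stride": 1_000,
        "n_replicates": 2,
        "motor_force": 80.0,
        "srd": {"box_edge": 8.0},
    }
    base.update(overrides)
    return config_from_dict(base)


@pytest.fixture(scope="module")
def packed_record():
    """One completed packing run shared by the ejection tests."""
    cfg = tiny_config()
    rec = prot.pack_replicate(cfg, seed=11)
    assert rec.status == "completed"
    return cfg, rec


class TestInitialState:
    def test_one_bead_inside_rest_outside(self, rng):
        cfg = tiny_config()
        assembly = cfg.build_assembly()
        state = prot.build_initial_packing_state(cfg, assembly, rng)
        assert count_occupancy(state.bead_positions, assembly) == (1, 0)

    def test_bond_lengths_in_construction_window(self, rng):
        cfg = tiny_config(n_beads=30)
        assembly = cfg.build_assembly()
        state = prot.build_initial_packing_state(cfg, assembly, rng)
        bonds = np.linalg.norm(np.diff(state.bead_positions, axis=0), axis=1)
        assert np.all((bonds > 0.8) & (bonds < 1.2))

    def test_no_clashes(self, rng):
        cfg = tiny_config(n_beads=30)
        assembly = cfg.build_assembly()
        state = prot.build_initial_packing_state(cfg, assembly, rng)
        d = np.linalg.norm(
            state.bead_positions[:, None] - state.bead_positions[None, :], axis=-1
        )
        d += np.eye(len(d)) * 10
        assert d.min() >= 0.9

    def test_seeds_differ_in_coil_not_first_bead(self):
        cfg = tiny_config(n_beads=20)
        assembly = cfg.build_assembly()
        s1 = prot.build_initial_packing_state(cfg, assembly, np.random.default_rng(1))
        s2 = prot.build_initial_packing_state(cfg, assembly, np.random.default_rng(2))
        assert np.array_equal(s1.bead_positions[0], s2.bead_positions[0])
        assert not np.array_equal(s1.bead_positions[-1], s2.bead_positions[-1])

    def test_tail_threading_single_file(self, rng):
        cfg = tiny_config(tail_present=True, n_beads=20)
        assembly = cfg.build_assembly()
        state = prot.build_initial_packing_state(cfg, assembly, rng)
        in_tail_extent = [
            p for p in state.bead_positions
            if assembly.capsid_radius <= p[2] <= assembly.capsid_radius + assembly.tail.length
        ]
        assert all(np.hypot(p[0], p[1]) < assembly.tail.radius for p in in_tail_extent)


class TestEquilibrate:
    def test_anchor_fixed_and_occupancy_kept(self, rng):
        cfg = tiny_config()
        assembly = cfg.build_assembly()
        state = prot.build_initial_packing_state(cfg, assembly, rng)
        anchored = state.bead_positions[0].copy()
        prot.equilibrate(state, cfg, rng, anchor=0)
        assert np.array_equal(state.bead_positions[0], anchored)
        n_in, _ = count_occupancy(state.bead_positions, assembly)
        assert n_in == 1


class TestPacking:
    def test_completed_run_reaches_full_occupancy(self, packed_record):
        cfg, rec = packed_record
        assert rec.beads_inside[-1] == cfg.n_beads
        assert rec.event_time is not None and rec.event_time <= cfg.max_steps

    def test_zero_motor_force_makes_no_progress(self):
        cfg = tiny_config(motor_force=0.0, max_steps=20_000, equilibration_steps=1_000)
        rec = prot.pack_replicate(cfg, seed=3)
        assert rec.status == "timeout"
        # a few beads may diffuse through the pore thermally, but without
        # the motor there is no net packing drive
        assert rec.beads_inside[-1] <= cfg.n_beads // 2

    def test_timeseries_monotone_steps(self, packed_record):
        _, rec = packed_record
        assert np.all(np.diff(rec.steps) > 0)


class TestEjection:
    def test_initial_ejection_state_has_one_bead_out(self, packed_record):
        cfg, rec = packed_record
        rng = np.random.default_rng(5)
        state = prot.build_initial_ejection_state(
            rec.final_state, cfg, rng, equilibration_steps=500
        )
        assembly = cfg.build_assembly()
        n_in, n_tail = count_occupancy(state.bead_positions, assembly)
        assert n_in == cfg.n_beads - 1 and n_tail == 0
        bonds = np.linalg.norm(np.diff(state.bead_positions, axis=0), axis=1)
        assert np.all(bonds < cfg.interaction.fene_r0)

    def test_ejection_terminates_empty_or_timeout(self, packed_record):
        cfg, rec = packed_record
        rng = np.random.default_rng(6)
        state = prot.build_initial_ejection_state(
            rec.final_state, cfg, rng, equilibration_steps=500
        )
        out = prot.run_ejection(state, cfg, rng)
        if out.status == "completed":
            assert out.beads_inside[-1] == 0 and out.beads_in_tail[-1] == 0
        else:
            assert out.status == "timeout"


class TestEnsemble:
    def test_seed_derivation_deterministic_and_distinct(self):
        a = prot.derive_replicate_seeds(123, 5)
        b = prot.derive_replicate_seeds(123, 5)
        assert a == b and len(set(a)) == 5

    def test_hand_constructed_curves_aggregate(self):
        cfg = tiny_config(n_beads=40, n_replicates=2)
        recs = []
        for rep, level in enumerate((10, 20)):
            recs.append(prot.RunRecord(
                replicate_id=rep, mode="packing",
                steps=np.array([0, 1000, 2000]),
                beads_inside=np.full(3, level),
                beads_in_tail=np.zeros(3, dtype=int),
                event_time=None, status="timeout", seed=rep, config_hash="x",
            ))
        res = prot.aggregate_records(recs, "packing", cfg)
        assert np.allclose(res.mean_inside, 15.0)
        assert np.allclose(res.sem_inside, 5.0)
        assert res.completion_fraction == 0.0

    def test_single_replicate_sem_zero(self):
        cfg = tiny_config(n_replicates=1)
        rec = prot.RunRecord(
            replicate_id=0, mode="packing",
            steps=np.array([0, 1000]), beads_inside=np.array([1, 2]),
            beads_in_tail=np.zeros(2, dtype=int),
            event_time=None, status="timeout", seed=0, config_hash="x",
        )
        res = prot.aggregate_records([rec], "packing", cfg)
        assert np.allclose(res.mean_inside, [1, 2])
        assert np.allclose(res.sem_inside, 0.0)

    def test_locf_after_completion(self):
        cfg = tiny_config(n_beads=5)
        done = prot.RunRecord(
            replicate_id=0, mode="packing",
            steps=np.array([0, 1000]), beads_inside=np.array([4, 5]),
            beads_in_tail=np.zeros(2, dtype=int),
            event_time=1000, status="completed", seed=0, config_hash="x",
        )
        slow = prot.RunRecord(
            replicate_id=1, mode="packing",
            steps=np.array([0, 1000, 2000, 3000]),
            beads_inside=np.array([1, 2, 3, 4]),
            beads_in_tail=np.zeros(4, dtype=int),
            event_time=None, status="timeout", seed=1, config_hash="x",
        )
        res = prot.aggregate_records([done, slow], "packing", cfg)
        # completed run contributes N after its event time
        assert np.allclose(res.mean_inside, [(4 + 1) / 2, (5 + 2) / 2, (5 + 3) / 2, (5 + 4) / 2])
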
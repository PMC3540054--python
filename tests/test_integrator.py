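"""Velocity-Verlet and hybrid MD/SRD loop: closed-form trajectories,
energy conservation, determinism, thermostat physics."""

import numpy as np
import pytest

from phagepack import (
    CapsidAssembly,
    InteractionParams,
    MotorSpec,
    SystemState,
    hybrid_advance,
    measure_kinetic_temperature,
    velocity_verlet_step,
)
from phagepack.config import config_from_dict
from phagepack.errors import IntegratorInstabilityError
from phagepack.potentials import total_energy
from phagepack import _kernels
from .conftest import make_chain


def small_config(**overrides):
    base = {
        "n_beads": 10,
        "equilibration_steps": 100,
        "max_steps": 10_000,
        "srd": {"box_edge": 6.0, "thermostat": "none"},
    }
    base.update(overrides)
    return config_from_dict(base)


class TestVelocityVerlet:
    def test_fixed_point(self):
        # no forces, no velocities: the state is a fixed point
        params = InteractionParams(
            fene_k=0.0, fene_r0=1e6, lj_epsilon=0.0, bend_kappa=0.0
        )
        pos = np.array([[0.0, 0, 0], [0, 0, 5.0], [0, 0, 10.0]])
        state = SystemState(pos.copy(), np.zeros_like(pos))
        velocity_verlet_step(state, params)
        assert np.allclose(state.bead_positions, pos)
        assert state.step == 1

    def test_constant_force_ballistic(self):
        # single bead under the constant motor force: x(t) = f t^2 / 2m
        params = InteractionParams(
            fene_k=0.0, fene_r0=1e6, lj_epsilon=0.0, bend_kappa=0.0
        )
        assembly = CapsidAssembly(
            wall_stiffness=0.0, motor=MotorSpec(magnitude=2.0, capture_radius=100.0)
        )
        pos = np.array([[0.0, 0.0, 1.0], [50.0, 0, 0], [100.0, 0, 0]])
        state = SystemState(pos.copy(), np.zeros_like(pos), dt=0.001)
        n = 100
        for _ in range(n):
            velocity_verlet_step(state, params, assembly, motor_on=True)
        t = n * state.dt
        # force points from (0,0,1) toward the origin: -z, magnitude 2
        expected = 1.0 - 0.5 * 2.0 * t**2
        assert state.bead_positions[0, 2] == pytest.approx(expected, abs=1e-4)

    def test_instability_reports_bead(self, rng):
        pos = make_chain(5, rng)
        state = SystemState(pos, np.zeros_like(pos))
        state.bead_positions[2] += 100.0  # overstretched bond
        with pytest.raises(IntegratorInstabilityError):
            velocity_verlet_step(state, InteractionParams())

    def test_nve_energy_conservation(self, rng):
        # isolated neutral chain, no solvent/geometry: secular drift of the
        # total energy < 1e-4 relative over 1e4 steps at dt = 0.005 tau
        # (velocity Verlet is symplectic: the energy oscillates within a
        # bounded band, so drift is the fitted linear trend, not the band)
        params = InteractionParams()
        pos = make_chain(20, rng, jitter=0.05)
        vel = rng.normal(0.0, 0.5, size=pos.shape)
        vel -= vel.mean(axis=0)
        p = _kernels.pack_params(params, None, 1.0, False)
        forces = np.empty_like(pos)
        assert _kernels.bead_forces(pos, forces, p) == 0

        energies = []
        for _ in range(100):
            assert _kernels.md_chunk(pos, vel, forces, 100, 0.005, 1.0, p, -1) == 0
            energies.append(total_energy(pos, params) + 0.5 * (vel**2).sum())
        energies = np.asarray(energies)
        slope = np.polyfit(np.arange(len(energies)), energies, 1)[0]
        drift = abs(slope) * len(energies) / abs(energies.mean())
        assert drift < 1e-4

    def test_momentum_conserved_exactly(self, rng):
        params = InteractionParams(charged=True)
        pos = make_chain(15, rng)
        vel = rng.normal(0.0, 0.3, size=pos.shape)
        p0 = vel.sum(axis=0)
        p = _kernels.pack_params(params, None, 1.0, False)
        forces = np.empty_like(pos)
        _kernels.bead_forces(pos, forces, p)
        _kernels.md_chunk(pos, vel, forces, 2_000, 0.005, 1.0, p, -1)
        assert np.allclose(vel.sum(axis=0), p0, atol=1e-9)


class TestHybridAdvance:
    def make_state(self, config, rng):
        from phagepack.srd import initialize_solvent

        pos = make_chain(config.n_beads, rng, offset=(0, 0, -2.0))
        vel = rng.normal(0.0, 1.0, size=pos.shape)
        solvent = initialize_solvent(config.srd, config.reduced_temperature, rng)
        return SystemState(pos, vel, solvent=solvent, dt=config.dt)

    def test_zero_steps_is_identity(self, rng):
        config = small_config()
        state = self.make_state(config, rng)
        before = state.bead_positions.copy()
        hybrid_advance(state, config, 0, rng)
        assert np.array_equal(state.bead_positions, before)

    def test_deterministic_under_seed(self):
        config = small_config()
        finals = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            state = self.make_state(config, np.random.default_rng(1))
            hybrid_advance(state, config, 500, rng)
            finals.append(state.bead_positions.copy())
        assert np.array_equal(finals[0], finals[1])

    def test_global_momentum_conserved_with_hydrodynamics(self, rng):
        config = small_config(motor_force=0.0)
        state = self.make_state(config, rng)
        # geometry off: pass a no-interaction assembly region by zeroing walls
        config = config_from_dict({
            "n_beads": 10, "equilibration_steps": 100, "max_steps": 10000,
            "geometry": {"wall_stiffness": 0.0, "channel_centering": 0.0}, "motor_force": 0.0,
            "srd": {"box_edge": 6.0, "thermostat": "none"},
        })
        p0 = state.solvent.particle_mass * state.solvent.velocities.sum(axis=0) + \
            state.bead_velocities.sum(axis=0)
        hybrid_advance(state, config, 200, rng)
        p1 = state.solvent.particle_mass * state.solvent.velocities.sum(axis=0) + \
            state.bead_velocities.sum(axis=0)
        assert np.allclose(p0, p1, atol=1e-9)

    def test_bead_temperature_equilibrates_to_target(self):
        # free chain in the SRD bath: bead kinetic temperature within 5%
        config = config_from_dict({
            "n_beads": 20, "reduced_temperature": 1.0,
            "equilibration_steps": 100, "max_steps": 200000, "motor_force": 0.0,
            "geometry": {"wall_stiffness": 0.0},
            "srd": {"box_edge": 8.0},
        })
        rng = np.random.default_rng(5)
        state = self.make_state(config, rng)
        state.bead_velocities[:] = 0.0  # start cold; the bath must heat it
        hybrid_advance(state, config, 10_000, rng)
        temps = []
        for _ in range(40):
            hybrid_advance(state, config, 1_000, rng)
            temps.append(measure_kinetic_temperature(state.bead_velocities, state.bead_mass))
        assert np.mean(temps) == pytest.approx(1.0, rel=0.05)

    def test_anchor_is_pinned(self, rng):
        config = small_config()
        state = self.make_state(config, rng)
        anchored = state.bead_positions[3].copy()
        hybrid_advance(state, config, 400, rng, anchor=3)
        assert np.array_equal(state.bead_positions[3], anchored)
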
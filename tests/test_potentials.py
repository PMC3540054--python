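"""Pair/triplet potentials: closed-form values, gradient consistency,
momentum conservation, and the compiled-kernel equivalence."""

import numpy as np
import pytest

from phagepack import (
    CapsidAssembly,
    InteractionParams,
    TailGeometry,
    bending,
    electrostatic,
    excluded_volume,
    fene_bond,
    total_energy,
    total_forces,
)
from phagepack import _kernels
from phagepack.errors import (
    BondOverstretchError,
    DegenerateGeometryError,
    SingularSeparationError,
)
from .conftest import make_chain


def central_diff(f, x, h=1e-6):
    return (f(x + h) - f(x - h)) / (2 * h)


class TestFene:
    def test_zero_at_origin(self, params):
        e, f = fene_bond(0.0, params)
        assert e == 0.0 and f == 0.0

    def test_closed_form_at_097(self, params):
        e, _ = fene_bond(0.97, params)
        # -0.5 * 30 * 1.5^2 * ln(1 - (0.97/1.5)^2)
        assert e == pytest.approx(18.28, abs=0.01)

    def test_overstretch_raises(self, params):
        with pytest.raises(BondOverstretchError):
            fene_bond(1.5, params)

    def test_force_matches_gradient(self, params, rng):
        for r in rng.uniform(0.2, 1.4, size=100):
            _, f = fene_bond(r, params)
            fd = -central_diff(lambda x: fene_bond(x, params)[0], r)
            assert f == pytest.approx(fd, rel=1e-6)


class TestExcludedVolume:
    def test_zero_at_and_beyond_cutoff(self, params):
        assert excluded_volume(params.lj_cutoff, params) == (0.0, 0.0)
        assert excluded_volume(3.0, params) == (0.0, 0.0)

    def test_shifted_value_at_sigma(self, params):
        e, _ = excluded_volume(1.0, params)
        assert e == pytest.approx(params.lj_epsilon)

    def test_singularity(self, params):
        with pytest.raises(SingularSeparationError):
            excluded_volume(0.0, params)

    def test_force_matches_gradient(self, params, rng):
        for r in rng.uniform(0.85, 1.11, size=100):
            _, f = excluded_volume(r, params)
            fd = -central_diff(lambda x: excluded_volume(x, params)[0], r)
            assert f == pytest.approx(fd, rel=1e-5)


class TestBending:
    def test_collinear_is_ground_state(self, params):
        e, forces = bending([0, 0, 0], [0, 0, 1], [0, 0, 2], params)
        assert e == pytest.approx(0.0, abs=1e-14)
        assert np.allclose(forces, 0.0, atol=1e-12)

    def test_right_angle_energy(self, params):
        e, _ = bending([0, 0, 0], [1, 0, 0], [1, 1, 0], params)
        assert e == pytest.approx(params.bend_kappa)

    def test_degenerate_bond(self, params):
        with pytest.raises(DegenerateGeometryError):
            bending([0, 0, 0], [0, 0, 0], [1, 0, 0], params)

    def test_forces_sum_to_zero_and_match_gradient(self, params, rng):
        for _ in range(25):
            triplet = rng.normal(scale=1.0, size=(3, 3))
            triplet[1] += [0, 0, 1.0]
            triplet[2] += [0, 0, 2.0]
            e, forces = bending(*triplet, params)
            assert np.allclose(forces.sum(axis=0), 0.0, atol=1e-10)
            # net torque about the center bead vanishes
            torque = np.cross(triplet[0] - triplet[1], forces[0]) + np.cross(
                triplet[2] - triplet[1], forces[2]
            )
            assert np.allclose(torque, 0.0, atol=1e-10)
            for bead in range(3):
                for coord in range(3):
                    def e_of(x, bead=bead, coord=coord):
                        t = triplet.copy()
                        t[bead, coord] = x
                        return bending(*t, params)[0]
                    fd = -central_diff(e_of, triplet[bead, coord])
                    assert forces[bead, coord] == pytest.approx(fd, rel=1e-5, abs=1e-8)


class TestElectrostatic:
    def test_truncation(self, charged_params):
        assert electrostatic(charged_params.elec_cutoff, 1.0, charged_params) == (0.0, 0.0)

    def test_linear_in_temperature(self, charged_params, rng):
        for r in rng.uniform(0.5, 2.5, size=20):
            e1, f1 = electrostatic(r, 1.0, charged_params)
            e2, f2 = electrostatic(r, 2.0, charged_params)
            assert e2 == pytest.approx(2 * e1) and f2 == pytest.approx(2 * f1)

    def test_closed_form_at_debye_length(self, charged_params):
        lam = charged_params.debye_length
        e, _ = electrostatic(lam, 1.2, charged_params)
        assert e == pytest.approx(1.2 * charged_params.charge_prefactor * np.exp(-1) / lam)

    def test_force_matches_gradient(self, charged_params, rng):
        for r in rng.uniform(0.5, 2.9, size=100):
            _, f = electrostatic(r, 1.1, charged_params)
            fd = -central_diff(lambda x: electrostatic(x, 1.1, charged_params)[0], r)
            assert f == pytest.approx(fd, rel=1e-5)


class TestTotalForces:
    def test_no_interactions_beyond_cutoffs(self, charged_params):
        pos = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.2]])
        # bonded pair only: push them apart beyond all nonbonded cutoffs is
        # impossible for a bond, so use two beads with huge separation in a
        # 3-bead chain is invalid; instead check two beads at nonbonded range
        chain = np.array([[0, 0, 0.0], [0, 0, 0.97], [0, 0, 1.94], [0, 0, 2.91]], dtype=float)
        f = total_forces(chain, charged_params)
        # collinear chain: bending zero; bonds at equilibrium-ish produce
        # only axial forces; end-to-end beads beyond elec cutoff 3.0
        assert np.allclose(f[:, :2], 0.0, atol=1e-12)

    def test_neutral_vs_charged_differ_by_electrostatics(self, rng):
        pos = make_chain(12, rng)
        neutral = total_forces(pos, InteractionParams(charged=False))
        charged = total_forces(pos, InteractionParams(charged=True), reduced_temperature=1.1)
        diff = charged - neutral
        expected = np.zeros_like(pos)
        p = InteractionParams(charged=True)
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                rij = pos[j] - pos[i]
                r = np.linalg.norm(rij)
                if r < p.elec_cutoff:
                    f = electrostatic(r, 1.1, p)[1] * rij / r
                    expected[i] -= f
                    expected[j] += f
        assert np.allclose(diff, expected, atol=1e-10)

    def test_internal_forces_conserve_momentum(self, rng):
        pos = make_chain(30, rng)
        for p in (InteractionParams(), InteractionParams(charged=True)):
            f = total_forces(pos, p)
            assert np.abs(f.sum(axis=0)).max() < 1e-10

    def test_matches_energy_gradient(self, rng):
        pos = make_chain(8, rng)
        p = InteractionParams(charged=True)
        f = total_forces(pos, p, reduced_temperature=1.0)
        h = 1e-6
        for bead in range(8):
            for coord in range(3):
                pp = pos.copy()
                pp[bead, coord] += h
                pm = pos.copy()
                pm[bead, coord] -= h
                fd = -(total_energy(pp, p) - total_energy(pm, p)) / (2 * h)
                assert f[bead, coord] == pytest.approx(fd, rel=2e-5, abs=1e-6)


class TestKernelEquivalence:
    """The compiled production kernel must match the reference forces."""

    @pytest.mark.parametrize("charged,geom,motor", [
        (False, False, False),
        (True, False, False),
        (True, True, True),
        (False, True, True),
    ])
    def test_kernel_matches_reference(self, rng, charged, geom, motor):
        pos = make_chain(25, rng)
        params = InteractionParams(charged=charged)
        assembly = CapsidAssembly(tail=TailGeometry()) if geom else None
        ref = total_forces(pos, params, assembly, motor, reduced_temperature=1.2)
        p = _kernels.pack_params(params, assembly, 1.2, motor)
        out = np.empty_like(pos)
        status = _kernels.bead_forces(pos, out, p)
        assert status == 0
        assert np.allclose(out, ref, atol=1e-10)
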
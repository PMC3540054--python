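"""Compiled (numba) inner loops.

The public modules (:mod:`potentials`, :mod:`srd`) expose readable NumPy
reference implementations; the kernels here evaluate the same physics in
tight nopython loops for the production integrator.  The test suite pins
kernel output to the reference implementations, so any edit here must keep
them in lockstep.

Interaction + geometry parameters travel as a flat float64 vector with the
named offsets below (numba-friendly, and one signature for every kernel).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# -- parameter-vector layout -------------------------------------------------
P_FENE_K = 0
P_FENE_R0 = 1
P_LJ_EPS = 2
P_LJ_SIG = 3
P_LJ_CUT = 4
P_KAPPA = 5
P_CHARGED = 6       # 0/1
P_ELEC_PREF = 7     # T* * charge_prefactor
P_DEBYE = 8
P_ELEC_CUT = 9
P_GEOM_ON = 10      # 0/1: capsid wall/tail/motor active
P_CAPSID_R = 11
P_PORE_R = 12
P_WALL_K = 13
P_WALL_W = 14
P_TAIL_ON = 15      # 0/1
P_TAIL_LEN = 16
P_TAIL_RAD = 17
P_TAIL_K = 18
P_MOTOR_ON = 19     # 0/1
P_MOTOR_F = 20
P_CAPTURE_R = 21
P_CHAN_CENTER = 22
N_PARAMS = 23


def pack_params(interaction, assembly=None, reduced_temperature=1.0, motor_on=False) -> np.ndarray:
    """Flatten InteractionParams + CapsidAssembly into the kernel vector."""
    p = np.zeros(N_PARAMS)
    p[P_FENE_K] = interaction.fene_k
    p[P_FENE_R0] = interaction.fene_r0
    p[P_LJ_EPS] = interaction.lj_epsilon
    p[P_LJ_SIG] = interaction.lj_sigma
    p[P_LJ_CUT] = interaction.lj_cutoff
    p[P_KAPPA] = interaction.bend_kappa
    p[P_CHARGED] = 1.0 if interaction.charged else 0.0
    p[P_ELEC_PREF] = reduced_temperature * interaction.charge_prefactor
    p[P_DEBYE] = interaction.debye_length
    p[P_ELEC_CUT] = interaction.elec_cutoff
    if assembly is not None:
        p[P_GEOM_ON] = 1.0
        p[P_CAPSID_R] = assembly.capsid_radius
        p[P_PORE_R] = assembly.pore_radius
        p[P_WALL_K] = assembly.wall_stiffness
        p[P_WALL_W] = assembly.wall_range
        if assembly.tail is not None:
            p[P_TAIL_ON] = 1.0
            p[P_TAIL_LEN] = assembly.tail.length
            p[P_TAIL_RAD] = assembly.tail.radius
            p[P_TAIL_K] = assembly.tail.retention_stiffness
        p[P_MOTOR_ON] = 1.0 if motor_on else 0.0
        p[P_MOTOR_F] = assembly.motor.magnitude
        p[P_CAPTURE_R] = assembly.motor.capture_radius
        p[P_CHAN_CENTER] = assembly.channel_centering
    return p


@njit(cache=True)
def bead_forces(pos, forces, p):
    """Total per-bead force into ``forces``.  Returns 0 or (bead index + 1)
    of the first overstretched bond / non-finite coordinate."""
    n = pos.shape[0]
    for i in range(n):
        for k in range(3):
            forces[i, k] = 0.0
            if not math.isfinite(pos[i, k]):
                return i + 1

    fene_k = p[P_FENE_K]
    r0 = p[P_FENE_R0]
    r0sq = r0 * r0
    lj_eps = p[P_LJ_EPS]
    lj_sig = p[P_LJ_SIG]
    lj_cut = p[P_LJ_CUT]
    sc6 = (lj_sig / lj_cut) ** 6
    kappa = p[P_KAPPA]
    charged = p[P_CHARGED] > 0.5
    elec_pref = p[P_ELEC_PREF]
    debye = p[P_DEBYE]
    elec_cut = p[P_ELEC_CUT]
    pair_cut = lj_cut if not charged else max(lj_cut, elec_cut)
    pair_cut_sq = pair_cut * pair_cut

    # FENE bonds
    for i in range(n - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        rsq = dx * dx + dy * dy + dz * dz
        if rsq >= r0sq:
            return i + 1
        fac = -fene_k / (1.0 - rsq / r0sq)  # f/r along pair axis
        forces[i, 0] -= fac * dx
        forces[i, 1] -= fac * dy
        forces[i, 2] -= fac * dz
        forces[i + 1, 0] += fac * dx
        forces[i + 1, 1] += fac * dy
        forces[i + 1, 2] += fac * dz

    # bending
    for i in range(1, n - 1):
        b1x = pos[i, 0] - pos[i - 1, 0]
        b1y = pos[i, 1] - pos[i - 1, 1]
        b1z = pos[i, 2] - pos[i - 1, 2]
        b2x = pos[i + 1, 0] - pos[i, 0]
        b2y = pos[i + 1, 1] - pos[i, 1]
        b2z = pos[i + 1, 2] - pos[i, 2]
        n1 = math.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
        n2 = math.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        if n1 == 0.0 or n2 == 0.0:
            return i + 1
        e1x, e1y, e1z = b1x / n1, b1y / n1, b1z / n1
        e2x, e2y, e2z = b2x / n2, b2y / n2, b2z / n2
        c = e1x * e2x + e1y * e2y + e1z * e2z
        d1x = (e2x - c * e1x) / n1
        d1y = (e2y - c * e1y) / n1
        d1z = (e2z - c * e1z) / n1
        d2x = (e1x - c * e2x) / n2
        d2y = (e1y - c * e2y) / n2
        d2z = (e1z - c * e2z) / n2
        forces[i - 1, 0] -= kappa * d1x
        forces[i - 1, 1] -= kappa * d1y
        forces[i - 1, 2] -= kappa * d1z
        forces[i, 0] += kappa * (d1x - d2x)
        forces[i, 1] += kappa * (d1y - d2y)
        forces[i, 2] += kappa * (d1z - d2z)
        forces[i + 1, 0] += kappa * d2x
        forces[i + 1, 1] += kappa * d2y
        forces[i + 1, 2] += kappa * d2z

    # nonbonded pairs (bonded pairs included: Kremer-Grest convention)
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            rsq = dx * dx + dy * dy + dz * dz
            if rsq >= pair_cut_sq or rsq == 0.0:
                continue
            r = math.sqrt(rsq)
            f_over_r = 0.0
            if r < lj_cut:
                sr6 = (lj_sig * lj_sig / rsq) ** 3
                f_over_r += 24.0 * lj_eps * (2.0 * sr6 * sr6 - sr6) / rsq
            if charged and r < elec_cut:
                u = elec_pref * math.exp(-r / debye) / r
                f_over_r += u * (1.0 / r + 1.0 / debye) / r
            forces[i, 0] -= f_over_r * dx
            forces[i, 1] -= f_over_r * dy
            forces[i, 2] -= f_over_r * dz
            forces[j, 0] += f_over_r * dx
            forces[j, 1] += f_over_r * dy
            forces[j, 2] += f_over_r * dz

    if p[P_GEOM_ON] > 0.5:
        capsid_r = p[P_CAPSID_R]
        pore_r = p[P_PORE_R]
        wall_k = p[P_WALL_K]
        wall_w = p[P_WALL_W]
        tail_on = p[P_TAIL_ON] > 0.5
        tail_len = p[P_TAIL_LEN]
        tail_rad = p[P_TAIL_RAD]
        tail_k = p[P_TAIL_K]
        motor_on = p[P_MOTOR_ON] > 0.5
        motor_f = p[P_MOTOR_F]
        capture_r = p[P_CAPTURE_R]
        chan_k = p[P_CHAN_CENTER]
        for i in range(n):
            x, y, z = pos[i, 0], pos[i, 1], pos[i, 2]
            r = math.sqrt(x * x + y * y + z * z)
            rho = math.sqrt(x * x + y * y)
            # capsid wall (channel centering in the pore; suppressed over
            # the tail opening)
            if r > 0.0:
                d = r - capsid_r
                if abs(d) < wall_w:
                    in_channel = rho < pore_r and z > 0.0
                    in_opening = tail_on and rho <= tail_rad and z > 0.0
                    if in_channel:
                        forces[i, 0] -= chan_k * x
                        forces[i, 1] -= chan_k * y
                    elif not in_opening:
                        mag = wall_k * (wall_w - abs(d))
                        s = -1.0 if d < 0.0 else 1.0
                        forces[i, 0] += mag * s * x / r
                        forces[i, 1] += mag * s * y / r
                        forces[i, 2] += mag * s * z / r
            # tail retention: one-sided pull toward the axis within reach
            if tail_on and capsid_r <= z <= capsid_r + tail_len:
                free_r = tail_rad - 0.5
                if free_r < rho < tail_rad + 0.5:
                    mag = tail_k * (rho - free_r)
                    forces[i, 0] -= mag * x / rho
                    forces[i, 1] -= mag * y / rho
            # motor: captured beads outside are fed toward a point just
            # inside the pore; beads inside are pulled toward the center
            if motor_on and r > 0.0:
                ddx = x
                ddy = y
                ddz = z - capsid_r
                if math.sqrt(ddx * ddx + ddy * ddy + ddz * ddz) < capture_r:
                    if r < capsid_r:
                        forces[i, 0] -= motor_f * x / r
                        forces[i, 1] -= motor_f * y / r
                        forces[i, 2] -= motor_f * z / r
                    else:
                        tx = -x
                        ty = -y
                        tz = (capsid_r - (0.0 if rho > pore_r else 0.5)) - z
                        tn = math.sqrt(tx * tx + ty * ty + tz * tz)
                        if tn > 0.0:
                            forces[i, 0] += motor_f * tx / tn
                            forces[i, 1] += motor_f * ty / tn
                            forces[i, 2] += motor_f * tz / tn
        # wall force on bond midpoints (chain-contour repulsion): prevents
        # bonds bracketing the thin wall shell with neither endpoint inside
        for i in range(n - 1):
            x = 0.5 * (pos[i, 0] + pos[i + 1, 0])
            y = 0.5 * (pos[i, 1] + pos[i + 1, 1])
            z = 0.5 * (pos[i, 2] + pos[i + 1, 2])
            r = math.sqrt(x * x + y * y + z * z)
            if r == 0.0:
                continue
            d = r - capsid_r
            if abs(d) >= wall_w:
                continue
            rho = math.sqrt(x * x + y * y)
            in_channel = rho < pore_r and z > 0.0
            if in_channel:
                fx = -0.5 * chan_k * x
                fy = -0.5 * chan_k * y
                fz = 0.0
            elif tail_on and rho <= tail_rad and z > 0.0:
                continue
            else:
                mag = wall_k * (wall_w - abs(d))
                s = -1.0 if d < 0.0 else 1.0
                fx = 0.5 * mag * s * x / r
                fy = 0.5 * mag * s * y / r
                fz = 0.5 * mag * s * z / r
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[i + 1, 0] += fx
            forces[i + 1, 1] += fy
            forces[i + 1, 2] += fz
    return 0


@njit(cache=True)
def md_chunk(pos, vel, forces, n_sub, dt, mass, p, anchor):
    """``n_sub`` velocity-Verlet steps in place.  ``forces`` must hold the
    forces for the entering ``pos`` and holds the exiting forces on return.
    ``anchor`` >= 0 pins that bead (zero displacement and velocity).
    Returns 0 or (bead index + 1) on instability."""
    n = pos.shape[0]
    half = 0.5 * dt / mass
    for _ in range(n_sub):
        for i in range(n):
            if i == anchor:
                vel[i, 0] = 0.0
                vel[i, 1] = 0.0
                vel[i, 2] = 0.0
                continue
            vel[i, 0] += half * forces[i, 0]
            vel[i, 1] += half * forces[i, 1]
            vel[i, 2] += half * forces[i, 2]
            pos[i, 0] += dt * vel[i, 0]
            pos[i, 1] += dt * vel[i, 1]
            pos[i, 2] += dt * vel[i, 2]
        status = bead_forces(pos, forces, p)
        if status != 0:
            return status
        for i in range(n):
            if i == anchor:
                continue
            vel[i, 0] += half * forces[i, 0]
            vel[i, 1] += half * forces[i, 1]
            vel[i, 2] += half * forces[i, 2]
    return 0


@njit(cache=True)
def srd_collide(solv_pos, solv_vel, bead_pos, bead_vel, m_solv, m_bead,
                shift, axes, ncell, cell_size, box_edge, cos_a, sin_a, anchor):
    """One SRD collision over solvent + beads with pre-drawn grid shift and
    per-cell rotation axes.  Velocities updated in place."""
    n_cells_total = ncell * ncell * ncell
    mom = np.zeros((n_cells_total, 3))
    mass_tot = np.zeros(n_cells_total)
    n_solv = solv_pos.shape[0]
    n_bead = bead_pos.shape[0]
    cells = np.empty(n_solv + n_bead, dtype=np.int64)

    half = box_edge / 2.0
    for idx in range(n_solv + n_bead):
        if idx < n_solv:
            x = solv_pos[idx, 0]
            y = solv_pos[idx, 1]
            z = solv_pos[idx, 2]
            m = m_solv
            vx, vy, vz = solv_vel[idx, 0], solv_vel[idx, 1], solv_vel[idx, 2]
        else:
            b = idx - n_solv
            x = bead_pos[b, 0]
            y = bead_pos[b, 1]
            z = bead_pos[b, 2]
            m = m_bead
            vx, vy, vz = bead_vel[b, 0], bead_vel[b, 1], bead_vel[b, 2]
        ix = int(((x + shift[0] + half) % box_edge) / cell_size)
        iy = int(((y + shift[1] + half) % box_edge) / cell_size)
        iz = int(((z + shift[2] + half) % box_edge) / cell_size)
        if ix >= ncell:
            ix = ncell - 1
        if iy >= ncell:
            iy = ncell - 1
        if iz >= ncell:
            iz = ncell - 1
        c = (ix * ncell + iy) * ncell + iz
        cells[idx] = c
        mom[c, 0] += m * vx
        mom[c, 1] += m * vy
        mom[c, 2] += m * vz
        mass_tot[c] += m

    for idx in range(n_solv + n_bead):
        c = cells[idx]
        cx = mom[c, 0] / mass_tot[c]
        cy = mom[c, 1] / mass_tot[c]
        cz = mom[c, 2] / mass_tot[c]
        if idx < n_solv:
            vx = solv_vel[idx, 0] - cx
            vy = solv_vel[idx, 1] - cy
            vz = solv_vel[idx, 2] - cz
        else:
            b = idx - n_solv
            vx = bead_vel[b, 0] - cx
            vy = bead_vel[b, 1] - cy
            vz = bead_vel[b, 2] - cz
        ax, ay, az = axes[c, 0], axes[c, 1], axes[c, 2]
        dot = ax * vx + ay * vy + az * vz
        rx = vx * cos_a + (ay * vz - az * vy) * sin_a + ax * dot * (1.0 - cos_a)
        ry = vy * cos_a + (az * vx - ax * vz) * sin_a + ay * dot * (1.0 - cos_a)
        rz = vz * cos_a + (ax * vy - ay * vx) * sin_a + az * dot * (1.0 - cos_a)
        if idx < n_solv:
            solv_vel[idx, 0] = cx + rx
            solv_vel[idx, 1] = cy + ry
            solv_vel[idx, 2] = cz + rz
        else:
            b = idx - n_solv
            if b == anchor:
                continue
            bead_vel[b, 0] = cx + rx
            bead_vel[b, 1] = cy + ry
            bead_vel[b, 2] = cz + rz


@njit(cache=True)
def langevin_chunk(pos, vel, forces, noise, dt, mass, gamma, temperature, p):
    """Langevin (BAOAB) steps for a free chain; ``noise`` is (n_steps, n, 3)
    standard normals.  Returns 0 or (bead index + 1) on instability."""
    n_steps = noise.shape[0]
    n = pos.shape[0]
    half = 0.5 * dt / mass
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(temperature / mass * (1.0 - c1 * c1))
    for s in range(n_steps):
        for i in range(n):
            vel[i, 0] += half * forces[i, 0]
            vel[i, 1] += half * forces[i, 1]
            vel[i, 2] += half * forces[i, 2]
            pos[i, 0] += 0.5 * dt * vel[i, 0]
            pos[i, 1] += 0.5 * dt * vel[i, 1]
            pos[i, 2] += 0.5 * dt * vel[i, 2]
            vel[i, 0] = c1 * vel[i, 0] + c2 * noise[s, i, 0]
            vel[i, 1] = c1 * vel[i, 1] + c2 * noise[s, i, 1]
            vel[i, 2] = c1 * vel[i, 2] + c2 * noise[s, i, 2]
            pos[i, 0] += 0.5 * dt * vel[i, 0]
            pos[i, 1] += 0.5 * dt * vel[i, 1]
            pos[i, 2] += 0.5 * dt * vel[i, 2]
        status = bead_forces(pos, forces, p)
        if status != 0:
            return status
        for i in range(n):
            vel[i, 0] += half * forces[i, 0]
            vel[i, 1] += half * forces[i, 1]
            vel[i, 2] += half * forces[i, 2]
    return 0


@njit(cache=True)
def seed_kernel_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def advance_hybrid(pos, vel, forces, solv_pos, solv_vel, n_steps, srd_sub, dt,
                   mass, m_solv, p, anchor, ncell, cell_size, box_edge,
                   cos_a, sin_a, do_shift, hydro_off, berendsen, t_target, tau):
    """Fused hybrid loop: [srd_sub MD bead steps + solvent streaming +
    grid-shifted collision (+ resampling / thermostat)] until n_steps MD
    steps elapse.  Uses numba's internal RNG (seed via seed_kernel_rng).
    Returns 0 or (bead index + 1) on instability."""
    n_solv = solv_pos.shape[0]
    n_bead = pos.shape[0]
    n_cells_total = ncell * ncell * ncell
    half_box = box_edge / 2.0
    inv_cell = 1.0 / cell_size
    sd_resample = math.sqrt(t_target / m_solv)
    done = 0
    sx = 0.0
    sy = 0.0
    sz = 0.0
    axes = np.empty((n_cells_total, 3))
    mom = np.empty((n_cells_total, 3))
    mass_tot = np.empty(n_cells_total)
    cells = np.empty(n_solv + n_bead, dtype=np.int64)
    while done < n_steps:
        n_sub = srd_sub if (n_steps - done) >= srd_sub else (n_steps - done)
        status = md_chunk(pos, vel, forces, n_sub, dt, mass, p, anchor)
        if status != 0:
            return status
        done += n_sub
        t_int = n_sub * dt
        if do_shift:
            sx = (np.random.random() - 0.5) * cell_size
            sy = (np.random.random() - 0.5) * cell_size
            sz = (np.random.random() - 0.5) * cell_size
        for c in range(n_cells_total):
            mom[c, 0] = 0.0
            mom[c, 1] = 0.0
            mom[c, 2] = 0.0
            mass_tot[c] = 0.0
            # uniform random rotation axis from two uniforms
            zc = 2.0 * np.random.random() - 1.0
            phi = 6.283185307179586 * np.random.random()
            sq = math.sqrt(1.0 - zc * zc)
            axes[c, 0] = sq * math.cos(phi)
            axes[c, 1] = sq * math.sin(phi)
            axes[c, 2] = zc
        # stream solvent, wrap, bin, accumulate cell momentum
        for i in range(n_solv):
            x = solv_pos[i, 0] + solv_vel[i, 0] * t_int
            y = solv_pos[i, 1] + solv_vel[i, 1] * t_int
            z = solv_pos[i, 2] + solv_vel[i, 2] * t_int
            if x >= half_box or x < -half_box:
                x = ((x + half_box) % box_edge) - half_box
            if y >= half_box or y < -half_box:
                y = ((y + half_box) % box_edge) - half_box
            if z >= half_box or z < -half_box:
                z = ((z + half_box) % box_edge) - half_box
            solv_pos[i, 0] = x
            solv_pos[i, 1] = y
            solv_pos[i, 2] = z
            xs = x + sx + half_box
            ys = y + sy + half_box
            zs = z + sz + half_box
            if xs < 0.0:
                xs += box_edge
            elif xs >= box_edge:
                xs -= box_edge
            if ys < 0.0:
                ys += box_edge
            elif ys >= box_edge:
                ys -= box_edge
            if zs < 0.0:
                zs += box_edge
            elif zs >= box_edge:
                zs -= box_edge
            ix = int(xs * inv_cell)
            iy = int(ys * inv_cell)
            iz = int(zs * inv_cell)
            if ix >= ncell:
                ix = ncell - 1
            if iy >= ncell:
                iy = ncell - 1
            if iz >= ncell:
                iz = ncell - 1
            c = (ix * ncell + iy) * ncell + iz
            cells[i] = c
            mom[c, 0] += m_solv * solv_vel[i, 0]
            mom[c, 1] += m_solv * solv_vel[i, 1]
            mom[c, 2] += m_solv * solv_vel[i, 2]
            mass_tot[c] += m_solv
        for b in range(n_bead):
            xs = ((pos[b, 0] + sx + half_box) % box_edge)
            ys = ((pos[b, 1] + sy + half_box) % box_edge)
            zs = ((pos[b, 2] + sz + half_box) % box_edge)
            ix = int(xs * inv_cell)
            iy = int(ys * inv_cell)
            iz = int(zs * inv_cell)
            if ix >= ncell:
                ix = ncell - 1
            if iy >= ncell:
                iy = ncell - 1
            if iz >= ncell:
                iz = ncell - 1
            c = (ix * ncell + iy) * ncell + iz
            cells[n_solv + b] = c
            mom[c, 0] += mass * vel[b, 0]
            mom[c, 1] += mass * vel[b, 1]
            mom[c, 2] += mass * vel[b, 2]
            mass_tot[c] += mass
        one_m_cos = 1.0 - cos_a
        for i in range(n_solv + n_bead):
            c = cells[i]
            inv_m = 1.0 / mass_tot[c]
            cx = mom[c, 0] * inv_m
            cy = mom[c, 1] * inv_m
            cz = mom[c, 2] * inv_m
            if i < n_solv:
                vx = solv_vel[i, 0] - cx
                vy = solv_vel[i, 1] - cy
                vz = solv_vel[i, 2] - cz
            else:
                b = i - n_solv
                if b == anchor:
                    continue
                vx = vel[b, 0] - cx
                vy = vel[b, 1] - cy
                vz = vel[b, 2] - cz
            ax = axes[c, 0]
            ay = axes[c, 1]
            az = axes[c, 2]
            dot = ax * vx + ay * vy + az * vz
            rx = vx * cos_a + (ay * vz - az * vy) * sin_a + ax * dot * one_m_cos
            ry = vy * cos_a + (az * vx - ax * vz) * sin_a + ay * dot * one_m_cos
            rz = vz * cos_a + (ax * vy - ay * vx) * sin_a + az * dot * one_m_cos
            if i < n_solv:
                solv_vel[i, 0] = cx + rx
                solv_vel[i, 1] = cy + ry
                solv_vel[i, 2] = cz + rz
            else:
                b = i - n_solv
                vel[b, 0] = cx + rx
                vel[b, 1] = cy + ry
                vel[b, 2] = cz + rz
        if hydro_off:
            for i in range(n_solv):
                solv_vel[i, 0] = sd_resample * np.random.normal()
                solv_vel[i, 1] = sd_resample * np.random.normal()
                solv_vel[i, 2] = sd_resample * np.random.normal()
        elif berendsen:
            cx = 0.0
            cy = 0.0
            cz = 0.0
            for i in range(n_solv):
                cx += solv_vel[i, 0]
                cy += solv_vel[i, 1]
                cz += solv_vel[i, 2]
            cx /= n_solv
            cy /= n_solv
            cz /= n_solv
            ke = 0.0
            for i in range(n_solv):
                dx = solv_vel[i, 0] - cx
                dy = solv_vel[i, 1] - cy
                dz = solv_vel[i, 2] - cz
                ke += dx * dx + dy * dy + dz * dz
            t_inst = m_solv * ke / (3.0 * n_solv)
            if t_inst > 0.0:
                arg = 1.0 + (t_target / t_inst - 1.0) / tau
                lam = math.sqrt(arg) if arg > 0.0 else 0.0
                for i in range(n_solv):
                    solv_vel[i, 0] = cx + lam * (solv_vel[i, 0] - cx)
                    solv_vel[i, 1] = cy + lam * (solv_vel[i, 1] - cy)
                    solv_vel[i, 2] = cz + lam * (solv_vel[i, 2] - cz)
    return 0
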
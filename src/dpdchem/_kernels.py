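"""Numba kernels for the DPD engine.

Reduced units throughout: lengths in r_c, energies in kBT, masses 1.
The pairwise thermostat uses the standard weight functions
w_R(r) = 1 - r/R_ij and w_D = w_R^2 so that sigma^2 = 2 gamma kBT holds
the kBT = 1 set point.  Pair noise is generated from a counter-based
hash of (seed, step, i, j): trajectories are bitwise reproducible and
the noise is symmetric in the pair without storing per-pair state.  The
deviates are uniform with unit variance (only the second moment matters
for the thermostat), which keeps the hash cost low.
"""

from __future__ import annotations

import numpy as np
from numba import njit

U64 = np.uint64
_C1 = U64(0x9E3779B97F4A7C15)
_C2 = U64(0xBF58476D1CE4E5B9)
_C3 = U64(0x94D049BB133111EB)
_SQRT3 = 1.7320508075688772

# 13 forward neighbour offsets + the home cell (half neighbour list)
_OFFS = np.array([[0, 0, 0],
                  [1, 0, 0], [0, 1, 0], [0, 0, 1],
                  [1, 1, 0], [1, -1, 0], [1, 0, 1], [1, 0, -1],
                  [0, 1, 1], [0, 1, -1],
                  [1, 1, 1], [1, 1, -1], [1, -1, 1], [1, -1, -1]],
                 dtype=np.int64)


@njit(cache=True, inline="always")
def _splitmix(z):
    z = U64(z) + _C1
    z = (z ^ (z >> U64(30))) * _C2
    z = (z ^ (z >> U64(27))) * _C3
    return z ^ (z >> U64(31))


@njit(cache=True, fastmath=True, inline="always")
def _pair_noise(seed, step, i, j):
    """Zero-mean unit-variance deviate, symmetric in (i, j)."""
    lo = U64(min(i, j))
    hi = U64(max(i, j))
    h = _splitmix(U64(seed) ^ _splitmix(U64(step)) ^ _splitmix(lo * U64(2654435761) + hi))
    u = np.float64(h >> U64(11)) * 1.1102230246251565e-16  # [0, 1)
    return _SQRT3 * (2.0 * u - 1.0)


@njit(cache=True, inline="always")
def _min_image(d, L):
    return d - L * np.rint(d / L)


@njit(cache=True, fastmath=True, inline="always")
def _pair_force(f, pos, vel, types, A, R, L, gamma, sigma_sqdt, seed, step,
                i, j, with_thermostat):
    dx = _min_image(pos[i, 0] - pos[j, 0], L)
    dy = _min_image(pos[i, 1] - pos[j, 1], L)
    dz = _min_image(pos[i, 2] - pos[j, 2], L)
    r2 = dx * dx + dy * dy + dz * dz
    Rij = R[types[i], types[j]]
    if r2 >= Rij * Rij:
        return
    r = np.sqrt(r2)
    if r < 1e-12:
        # overlapping beads: deterministic tie-break direction from the
        # pair hash (soft potential keeps the force finite at a_ij)
        gx = _pair_noise(seed, step, i, j)
        gy = _pair_noise(seed + U64(1), step, i, j)
        gz = _pair_noise(seed + U64(2), step, i, j)
        norm = np.sqrt(gx * gx + gy * gy + gz * gz) + 1e-300
        ex, ey, ez = gx / norm, gy / norm, gz / norm
        w = 1.0
    else:
        ex, ey, ez = dx / r, dy / r, dz / r
        w = 1.0 - r / Rij
    fmag = A[types[i], types[j]] * w
    if with_thermostat:
        vdote = ((vel[i, 0] - vel[j, 0]) * ex + (vel[i, 1] - vel[j, 1]) * ey
                 + (vel[i, 2] - vel[j, 2]) * ez)
        fmag += -gamma * w * w * vdote + sigma_sqdt * w * _pair_noise(seed, step, i, j)
    f[i, 0] += fmag * ex
    f[i, 1] += fmag * ey
    f[i, 2] += fmag * ez
    f[j, 0] -= fmag * ex
    f[j, 1] -= fmag * ey
    f[j, 2] -= fmag * ez


@njit(cache=True, fastmath=True)
def _nb_into(f, pos, vel, types, A, R, L, gamma, sigma_sqdt, seed, step,
             use_cells, head, nxt):
    """Accumulate nonbonded forces into ``f`` (not zeroed here)."""
    n = pos.shape[0]
    with_thermo = gamma != 0.0 or sigma_sqdt != 0.0
    ncell = int(round(head.shape[0] ** (1.0 / 3.0)))
    if (not use_cells) or ncell < 3:
        for i in range(n):
            for j in range(i + 1, n):
                _pair_force(f, pos, vel, types, A, R, L, gamma, sigma_sqdt,
                            seed, step, i, j, with_thermo)
        return
    cell_sz = L / ncell
    head[:] = -1
    for i in range(n):
        cx = int(pos[i, 0] / cell_sz) % ncell
        cy = int(pos[i, 1] / cell_sz) % ncell
        cz = int(pos[i, 2] / cell_sz) % ncell
        c = (cx * ncell + cy) * ncell + cz
        nxt[i] = head[c]
        head[c] = i
    for cx in range(ncell):
        for cy in range(ncell):
            for cz in range(ncell):
                c = (cx * ncell + cy) * ncell + cz
                for k in range(14):
                    bx = cx + _OFFS[k, 0]
                    by = cy + _OFFS[k, 1]
                    bz = cz + _OFFS[k, 2]
                    if bx >= ncell:
                        bx -= ncell
                    if by >= ncell:
                        by -= ncell
                    if by < 0:
                        by += ncell
                    if bz >= ncell:
                        bz -= ncell
                    if bz < 0:
                        bz += ncell
                    b = (bx * ncell + by) * ncell + bz
                    i = head[c]
                    while i >= 0:
                        if b == c:
                            j = nxt[i]
                        else:
                            j = head[b]
                        while j >= 0:
                            _pair_force(f, pos, vel, types, A, R, L, gamma,
                                        sigma_sqdt, seed, step, i, j, with_thermo)
                            j = nxt[j]
                        i = nxt[i]


def _ncell_for(L, R, use_cells):
    ncell = int(L / np.max(R))
    return ncell if (use_cells and ncell >= 3) else 1


@njit(cache=True, fastmath=True)
def nonbonded_forces(pos, vel, types, A, R, L, gamma, sigma_sqdt, seed, step,
                     use_cells):
    """Nonbonded forces (fresh array).

    ``sigma_sqdt`` is sigma/sqrt(dt); pass gamma = sigma_sqdt = 0 for the
    conservative part only.  ``use_cells`` selects the linked-cell path,
    which visits exactly the same pair set as the brute-force path.
    """
    n = pos.shape[0]
    f = np.zeros((n, 3))
    ncell = int(L / np.max(R))
    if not use_cells or ncell < 3:
        ncell = 1
    head = np.full(ncell * ncell * ncell, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    _nb_into(f, pos, vel, types, A, R, L, gamma, sigma_sqdt, seed, step,
             use_cells, head, nxt)
    return f


@njit(cache=True)
def nonbonded_energy(pos, types, A, R, L):
    """Total soft-repulsion energy, U = sum (a_ij R_ij / 2)(1 - r/R_ij)^2."""
    n = pos.shape[0]
    e = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            dx = _min_image(pos[i, 0] - pos[j, 0], L)
            dy = _min_image(pos[i, 1] - pos[j, 1], L)
            dz = _min_image(pos[i, 2] - pos[j, 2], L)
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            Rij = R[types[i], types[j]]
            if r < Rij:
                w = 1.0 - r / Rij
                e += 0.5 * A[types[i], types[j]] * Rij * w * w
    return e


@njit(cache=True, fastmath=True)
def _bonded_into(f, pos, L, bond_i, bond_j, bond_r0, bond_k,
                 ang_i, ang_j, ang_k, ang_th0, ang_ks):
    for b in range(bond_i.shape[0]):
        i = bond_i[b]
        j = bond_j[b]
        dx = _min_image(pos[i, 0] - pos[j, 0], L)
        dy = _min_image(pos[i, 1] - pos[j, 1], L)
        dz = _min_image(pos[i, 2] - pos[j, 2], L)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        fmag = -bond_k[b] * (r - bond_r0[b]) / r
        f[i, 0] += fmag * dx
        f[i, 1] += fmag * dy
        f[i, 2] += fmag * dz
        f[j, 0] -= fmag * dx
        f[j, 1] -= fmag * dy
        f[j, 2] -= fmag * dz
    for t in range(ang_i.shape[0]):
        i = ang_i[t]
        j = ang_j[t]
        k = ang_k[t]
        ux = _min_image(pos[i, 0] - pos[j, 0], L)
        uy = _min_image(pos[i, 1] - pos[j, 1], L)
        uz = _min_image(pos[i, 2] - pos[j, 2], L)
        wx = _min_image(pos[k, 0] - pos[j, 0], L)
        wy = _min_image(pos[k, 1] - pos[j, 1], L)
        wz = _min_image(pos[k, 2] - pos[j, 2], L)
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nw = np.sqrt(wx * wx + wy * wy + wz * wz)
        if nu < 1e-12 or nw < 1e-12:
            continue
        ax, ay, az = ux / nu, uy / nu, uz / nu
        bx, by, bz = wx / nw, wy / nw, wz / nw
        cos_t = ax * bx + ay * by + az * bz
        if cos_t > 1.0:
            cos_t = 1.0
        if cos_t < -1.0:
            cos_t = -1.0
        theta = np.arccos(cos_t)
        sin_t = np.sqrt(1.0 - cos_t * cos_t)
        if sin_t < 1e-8:
            sin_t = 1e-8  # collinear limit: (theta - theta0) -> 0 for straight chains
        coef = ang_ks[t] * (theta - ang_th0[t]) / sin_t
        fi_x = coef * (bx - cos_t * ax) / nu
        fi_y = coef * (by - cos_t * ay) / nu
        fi_z = coef * (bz - cos_t * az) / nu
        fk_x = coef * (ax - cos_t * bx) / nw
        fk_y = coef * (ay - cos_t * by) / nw
        fk_z = coef * (az - cos_t * bz) / nw
        f[i, 0] += fi_x
        f[i, 1] += fi_y
        f[i, 2] += fi_z
        f[k, 0] += fk_x
        f[k, 1] += fk_y
        f[k, 2] += fk_z
        f[j, 0] -= fi_x + fk_x
        f[j, 1] -= fi_y + fk_y
        f[j, 2] -= fi_z + fk_z


@njit(cache=True, fastmath=True)
def bonded_forces(pos, L, bond_i, bond_j, bond_r0, bond_k,
                  ang_i, ang_j, ang_k, ang_th0, ang_ks):
    """Harmonic bond and 1-3 harmonic angle forces (fresh array)."""
    f = np.zeros((pos.shape[0], 3))
    _bonded_into(f, pos, L, bond_i, bond_j, bond_r0, bond_k,
                 ang_i, ang_j, ang_k, ang_th0, ang_ks)
    return f


@njit(cache=True)
def bonded_energy(pos, L, bond_i, bond_j, bond_r0, bond_k,
                  ang_i, ang_j, ang_k, ang_th0, ang_ks):
    e = 0.0
    for b in range(bond_i.shape[0]):
        i = bond_i[b]
        j = bond_j[b]
        dx = _min_image(pos[i, 0] - pos[j, 0], L)
        dy = _min_image(pos[i, 1] - pos[j, 1], L)
        dz = _min_image(pos[i, 2] - pos[j, 2], L)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        e += 0.5 * bond_k[b] * (r - bond_r0[b]) ** 2
    for t in range(ang_i.shape[0]):
        i = ang_i[t]
        j = ang_j[t]
        k = ang_k[t]
        ux = _min_image(pos[i, 0] - pos[j, 0], L)
        uy = _min_image(pos[i, 1] - pos[j, 1], L)
        uz = _min_image(pos[i, 2] - pos[j, 2], L)
        wx = _min_image(pos[k, 0] - pos[j, 0], L)
        wy = _min_image(pos[k, 1] - pos[j, 1], L)
        wz = _min_image(pos[k, 2] - pos[j, 2], L)
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nw = np.sqrt(wx * wx + wy * wy + wz * wz)
        cos_t = (ux * wx + uy * wy + uz * wz) / (nu * nw)
        if cos_t > 1.0:
            cos_t = 1.0
        if cos_t < -1.0:
            cos_t = -1.0
        theta = np.arccos(cos_t)
        e += 0.5 * ang_ks[t] * (theta - ang_th0[t]) ** 2
    return e


@njit(cache=True, fastmath=True)
def run_steps(pos, vel, types, A, R, L, dt, gamma, sigma, seed, step0, nsteps,
              bond_i, bond_j, bond_r0, bond_k, ang_i, ang_j, ang_k, ang_th0,
              ang_ks, stride, frames, temps, frame0):
    """Velocity-Verlet main loop (lambda = 1/2); fills ``frames``/``temps``
    every ``stride`` steps.  Returns the frame count written, or -1 on a
    detected instability (displacement > L/2 in one step)."""
    n = pos.shape[0]
    sigma_sqdt = sigma / np.sqrt(dt)
    nframes = frame0
    ncell = int(L / np.max(R))
    if ncell < 3:
        ncell = 1
    head = np.full(ncell * ncell * ncell, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    have_bonded = bond_i.shape[0] > 0 or ang_i.shape[0] > 0
    f = np.zeros((n, 3))
    vpred = np.empty((n, 3))
    _nb_into(f, pos, vel, types, A, R, L, gamma, sigma_sqdt, seed, step0, True,
             head, nxt)
    if have_bonded:
        _bonded_into(f, pos, L, bond_i, bond_j, bond_r0, bond_k,
                     ang_i, ang_j, ang_k, ang_th0, ang_ks)
    half_L = 0.5 * L
    for s in range(nsteps):
        step = step0 + s
        for i in range(n):
            for d in range(3):
                vpred[i, d] = vel[i, d] + 0.5 * dt * f[i, d]
                dx = dt * vel[i, d] + 0.5 * dt * dt * f[i, d]
                if np.abs(dx) > half_L:
                    return -1
                x = pos[i, d] + dx
                x -= L * np.floor(x / L)
                pos[i, d] = x
                vel[i, d] += 0.5 * dt * f[i, d]
                f[i, d] = 0.0
        _nb_into(f, pos, vpred, types, A, R, L, gamma, sigma_sqdt, seed,
                 step + 1, True, head, nxt)
        if have_bonded:
            _bonded_into(f, pos, L, bond_i, bond_j, bond_r0, bond_k,
                         ang_i, ang_j, ang_k, ang_th0, ang_ks)
        for i in range(n):
            vel[i, 0] += 0.5 * dt * f[i, 0]
            vel[i, 1] += 0.5 * dt * f[i, 1]
            vel[i, 2] += 0.5 * dt * f[i, 2]
        if (s + 1) % stride == 0 and nframes < frames.shape[0]:
            ke = 0.0
            for i in range(n):
                frames[nframes, i, 0] = pos[i, 0]
                frames[nframes, i, 1] = pos[i, 1]
                frames[nframes, i, 2] = pos[i, 2]
                ke += vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
            temps[nframes] = ke / (3.0 * n - 3.0)
            nframes += 1
    return nframes
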
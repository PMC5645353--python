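"""Numba-compiled force, neighbor-list, and Langevin-integrator kernels.

Reduced units throughout: bead mass m = 1, energy epsilon = 1, length
sigma = 1, time sigma (m/epsilon)^(1/2).  The integrator is BAOAB Langevin
splitting; with friction gamma = 0 the O-step is the identity and the
scheme reduces exactly to velocity Verlet (used by the energy-conservation
checks).

Force-field encoding shared by all kernels (ff array, float64):
  [0] k_fene  [1] r0  [2] k_bend  [3] z^2  [4] coulomb cutoff
  [5] pair style (0 = WCA, 1 = truncated+shifted LJ)  [6] lj cutoff
  [7] epsilon
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_WCA_RC2 = 2.0 ** (1.0 / 3.0)


@njit(cache=True)
def pack_ff(k_fene, r0, k_bend, z, coul_rc, pair_style, lj_rc, eps):
    out = np.empty(8)
    out[0] = k_fene
    out[1] = r0
    out[2] = k_bend
    out[3] = z * z
    out[4] = coul_rc
    out[5] = pair_style
    out[6] = lj_rc
    out[7] = eps
    return out


@njit(cache=True)
def build_pairs(pos, rlist):
    """All-pairs neighbor search (N <= ~300, so O(N^2) is fine)."""
    n = pos.shape[0]
    rl2 = rlist * rlist
    cnt = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            if dx * dx + dy * dy + dz * dz < rl2:
                cnt += 1
    pairs = np.empty((cnt, 2), np.int64)
    k = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            if dx * dx + dy * dy + dz * dz < rl2:
                pairs[k, 0] = i
                pairs[k, 1] = j
                k += 1
    return pairs


@njit(cache=True)
def forces(pos, closed, ff, pairs, f_out, soft_fene=False):
    """Fill f_out with forces; return potential energy, or NaN when a FENE
    bond reaches R0 (topology-threatening overstretch).

    With ``soft_fene`` the FENE spring is continued quadratically beyond
    0.99 R0 (matched in value and slope) instead of diverging; used only by
    the minimizer, whose line searches need finite trial energies."""
    n = pos.shape[0]
    k_fene, r0, k_bend = ff[0], ff[1], ff[2]
    z2, coul_rc = ff[3], ff[4]
    style = int(ff[5] + 0.5)
    lj_rc2 = ff[6] * ff[6]
    eps = ff[7]
    coul_rc2 = coul_rc * coul_rc
    src6 = (1.0 / ff[6]) ** 6
    lj_shift = 4.0 * eps * (src6 * src6 - src6)
    r02 = r0 * r0
    energy = 0.0
    for i in range(n):
        f_out[i, 0] = 0.0
        f_out[i, 1] = 0.0
        f_out[i, 2] = 0.0
    # FENE bonds
    cap = 0.99 * r0
    cap2 = cap * cap
    n_bond = n if closed else n - 1
    for i in range(n_bond):
        j = (i + 1) % n
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if soft_fene and r2 > cap2:
            r = math.sqrt(r2)
            w = 1.0 - cap2 / r02
            u_cap = -0.5 * k_fene * r02 * math.log(w)
            s_cap = k_fene * cap / w          # dU/dr at the cap
            energy += u_cap + s_cap * (r - cap) + 50.0 * k_fene * (r - cap) ** 2
            fr = -(s_cap + 100.0 * k_fene * (r - cap)) / r
        elif r2 >= r02:
            return math.nan
        else:
            w = 1.0 - r2 / r02
            energy += -0.5 * k_fene * r02 * math.log(w)
            fr = -k_fene / w  # dU/dr / r, with sign folded in below
        if style == 2 and r2 < _WCA_RC2:
            # phantom chains keep the WCA core on bonded pairs only, so the
            # bond sits in the usual Kremer-Grest minimum near 0.97 sigma
            inv2 = 1.0 / r2
            sr6 = inv2 * inv2 * inv2
            energy += 4.0 * eps * (sr6 * sr6 - sr6) + eps
            fr += 24.0 * eps * (2.0 * sr6 * sr6 - sr6) * inv2
        f_out[i, 0] -= fr * dx
        f_out[i, 1] -= fr * dy
        f_out[i, 2] -= fr * dz
        f_out[j, 0] += fr * dx
        f_out[j, 1] += fr * dy
        f_out[j, 2] += fr * dz
    # bending
    if k_bend > 0.0:
        i0 = 0 if closed else 1
        i1 = n if closed else n - 1
        for i in range(i0, i1):
            im = (i - 1) % n
            ip = (i + 1) % n
            ax = pos[i, 0] - pos[im, 0]
            ay = pos[i, 1] - pos[im, 1]
            az = pos[i, 2] - pos[im, 2]
            bx = pos[ip, 0] - pos[i, 0]
            by = pos[ip, 1] - pos[i, 1]
            bz = pos[ip, 2] - pos[i, 2]
            la = math.sqrt(ax * ax + ay * ay + az * az)
            lb = math.sqrt(bx * bx + by * by + bz * bz)
            inv = 1.0 / (la * lb)
            c = (ax * bx + ay * by + az * bz) * inv
            if c > 1.0:
                c = 1.0
            elif c < -1.0:
                c = -1.0
            energy += k_bend * (1.0 - c)
            # dc/d(b1) = (e2 - c e1)/la ; dc/d(b2) = (e1 - c e2)/lb
            e1x, e1y, e1z = ax / la, ay / la, az / la
            e2x, e2y, e2z = bx / lb, by / lb, bz / lb
            g1x = (e2x - c * e1x) / la
            g1y = (e2y - c * e1y) / la
            g1z = (e2z - c * e1z) / la
            g2x = (e1x - c * e2x) / lb
            g2y = (e1y - c * e2y) / lb
            g2z = (e1z - c * e2z) / lb
            # U = k(1-c): F = k * dc/dr
            f_out[im, 0] -= k_bend * g1x
            f_out[im, 1] -= k_bend * g1y
            f_out[im, 2] -= k_bend * g1z
            f_out[i, 0] += k_bend * (g1x - g2x)
            f_out[i, 1] += k_bend * (g1y - g2y)
            f_out[i, 2] += k_bend * (g1z - g2z)
            f_out[ip, 0] += k_bend * g2x
            f_out[ip, 1] += k_bend * g2y
            f_out[ip, 2] += k_bend * g2z
    # non-bonded pairs
    for k in range(pairs.shape[0]):
        i = pairs[k, 0]
        j = pairs[k, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        fr = 0.0
        if style == 1:
            if r2 < lj_rc2:
                inv2 = 1.0 / r2
                sr6 = inv2 * inv2 * inv2
                energy += 4.0 * eps * (sr6 * sr6 - sr6) - lj_shift
                fr += 24.0 * eps * (2.0 * sr6 * sr6 - sr6) * inv2
        elif style == 0:
            if r2 < _WCA_RC2:
                inv2 = 1.0 / r2
                sr6 = inv2 * inv2 * inv2
                energy += 4.0 * eps * (sr6 * sr6 - sr6) + eps
                fr += 24.0 * eps * (2.0 * sr6 * sr6 - sr6) * inv2
        if z2 > 0.0 and r2 < coul_rc2:
            r = math.sqrt(r2)
            energy += z2 / r
            fr += z2 / (r2 * r)
        if fr != 0.0:
            f_out[i, 0] -= fr * dx
            f_out[i, 1] -= fr * dy
            f_out[i, 2] -= fr * dz
            f_out[j, 0] += fr * dx
            f_out[j, 1] += fr * dy
            f_out[j, 2] += fr * dz
    return energy


@njit(cache=True)
def total_energy(pos, closed, ff):
    f = np.empty_like(pos)
    pairs = build_pairs(pos, max(ff[4], ff[6], 1.2) + 1.0)
    return forces(pos, closed, ff, pairs, f)


@njit(cache=True)
def run_langevin(pos, vel, closed, ff, dt, gamma, temp, n_steps, stride,
                 seed, skin, traj, ke_out, pe_out):
    """BAOAB Langevin dynamics.  Samples are written every ``stride`` steps
    into ``traj`` (n_samples, N, 3) with kinetic/potential energies in
    ``ke_out``/``pe_out``.  Returns the step index at which a FENE bond
    overstretched, or -1 on success."""
    np.random.seed(seed)
    n = pos.shape[0]
    rc = ff[6] if ff[5] > 0.5 else 1.122462048309373
    if ff[3] > 0.0 and ff[4] > rc:
        rc = ff[4]
    rlist = rc + skin
    pairs = build_pairs(pos, rlist)
    ref = pos.copy()
    f = np.empty_like(pos)
    pe = forces(pos, closed, ff, pairs, f)
    if math.isnan(pe):
        return 0
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt((1.0 - c1 * c1) * temp)
    half = 0.5 * dt
    n_sample = 0
    for step in range(n_steps):
        for i in range(n):
            vel[i, 0] += half * f[i, 0]
            vel[i, 1] += half * f[i, 1]
            vel[i, 2] += half * f[i, 2]
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            pos[i, 2] += half * vel[i, 2]
        if gamma > 0.0:
            for i in range(n):
                vel[i, 0] = c1 * vel[i, 0] + c2 * np.random.standard_normal()
                vel[i, 1] = c1 * vel[i, 1] + c2 * np.random.standard_normal()
                vel[i, 2] = c1 * vel[i, 2] + c2 * np.random.standard_normal()
        for i in range(n):
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            pos[i, 2] += half * vel[i, 2]
        # neighbor-list refresh on displacement criterion
        dmax2 = 0.0
        for i in range(n):
            dx = pos[i, 0] - ref[i, 0]
            dy = pos[i, 1] - ref[i, 1]
            dz = pos[i, 2] - ref[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > dmax2:
                dmax2 = d2
        if dmax2 > 0.25 * skin * skin:
            pairs = build_pairs(pos, rlist)
            ref[:] = pos
        pe = forces(pos, closed, ff, pairs, f)
        if math.isnan(pe):
            return step
        for i in range(n):
            vel[i, 0] += half * f[i, 0]
            vel[i, 1] += half * f[i, 1]
            vel[i, 2] += half * f[i, 2]
        if (step + 1) % stride == 0 and n_sample < traj.shape[0]:
            ke = 0.0
            for i in range(n):
                traj[n_sample, i, 0] = pos[i, 0]
                traj[n_sample, i, 1] = pos[i, 1]
                traj[n_sample, i, 2] = pos[i, 2]
                ke += 0.5 * (vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
            ke_out[n_sample] = ke
            pe_out[n_sample] = pe
            n_sample += 1
    return -1


@njit(cache=True)
def energy_and_grad(x, n, closed, ff):
    """Objective for canonical-knot minimization (soft-core FENE)."""
    pos = np.ascontiguousarray(x).reshape(n, 3)
    f = np.empty((n, 3))
    pairs = build_pairs(pos, max(ff[4], ff[6], 1.2))
    e = forces(pos, closed, ff, pairs, f, soft_fene=True)
    return e, (-f).ravel()


@njit(cache=True)
def wos_capacity(centers, r_bead, r_circ, r_launch, n_walks, seed, eps,
                 grid_origin, grid_dims, cell_size, cell_start, cell_items,
                 use_grid, max_steps):
    """Walk-on-spheres hit counting for the union-of-spheres conductor.

    ``centers`` must be pre-translated so their centroid is at the origin;
    ``r_circ`` is the circumscribing radius (body fits inside it).  Walkers
    start uniformly on the launch sphere of radius ``r_launch``; a walker
    that strays outside it either escapes to infinity (probability
    1 - r_launch/rho) or re-enters on the launch sphere with the exact
    harmonic-measure (Poisson kernel) distribution.  The capacity estimate
    is r_launch * hits / n_walks.

    The distance query returns the exact distance near the body and a safe
    lower bound far from it (grid block / far-field bound), which leaves
    the walk's hitting law unchanged.
    """
    np.random.seed(seed)
    n = centers.shape[0]
    hits = 0
    for _ in range(n_walks):
        # uniform point on launch sphere
        while True:
            gx = np.random.standard_normal()
            gy = np.random.standard_normal()
            gz = np.random.standard_normal()
            g = math.sqrt(gx * gx + gy * gy + gz * gz)
            if g > 1e-12:
                break
        x = r_launch * gx / g
        y = r_launch * gy / g
        z = r_launch * gz / g
        alive = True
        for _ in range(max_steps):
            # distance to the union (exact near the body, lower bound far)
            rho = math.sqrt(x * x + y * y + z * z)
            d = rho - r_circ
            if use_grid:
                a = cell_size
                ix = int((x - grid_origin[0]) / a)
                iy = int((y - grid_origin[1]) / a)
                iz = int((z - grid_origin[2]) / a)
                m = 1e300
                if (-1 <= ix <= grid_dims[0] and -1 <= iy <= grid_dims[1]
                        and -1 <= iz <= grid_dims[2]):
                    for cx in range(max(ix - 1, 0), min(ix + 2, grid_dims[0])):
                        for cy in range(max(iy - 1, 0), min(iy + 2, grid_dims[1])):
                            for cz in range(max(iz - 1, 0), min(iz + 2, grid_dims[2])):
                                cid = (cx * grid_dims[1] + cy) * grid_dims[2] + cz
                                for kk in range(cell_start[cid], cell_start[cid + 1]):
                                    c = cell_items[kk]
                                    dx = x - centers[c, 0]
                                    dy = y - centers[c, 1]
                                    dz = z - centers[c, 2]
                                    r2 = dx * dx + dy * dy + dz * dz
                                    if r2 < m:
                                        m = r2
                dg = a - r_bead
                if m < 1e299:
                    dm = math.sqrt(m) - r_bead
                    if dm < dg:
                        dg = dm
                if dg > d:
                    d = dg
            else:
                m = 1e300
                for c in range(n):
                    dx = x - centers[c, 0]
                    dy = y - centers[c, 1]
                    dz = z - centers[c, 2]
                    r2 = dx * dx + dy * dy + dz * dz
                    if r2 < m:
                        m = r2
                d = math.sqrt(m) - r_bead
            if d < eps:
                hits += 1
                alive = False
                break
            # jump to a random point on the sphere of radius d
            while True:
                gx = np.random.standard_normal()
                gy = np.random.standard_normal()
                gz = np.random.standard_normal()
                g = math.sqrt(gx * gx + gy * gy + gz * gz)
                if g > 1e-12:
                    break
            x += d * gx / g
            y += d * gy / g
            z += d * gz / g
            rho = math.sqrt(x * x + y * y + z * z)
            if rho > r_launch:
                if np.random.random() > r_launch / rho:
                    alive = False   # escaped to infinity
                    break
                # re-enter on the launch sphere: Poisson-kernel sampling
                u = np.random.random()
                w = 1.0 / (2.0 * rho * u / (rho * rho - r_launch * r_launch)
                           + 1.0 / (rho + r_launch))
                t = (rho * rho + r_launch * r_launch - w * w) / (2.0 * rho * r_launch)
                if t > 1.0:
                    t = 1.0
                elif t < -1.0:
                    t = -1.0
                phi = 2.0 * math.pi * np.random.random()
                st = math.sqrt(1.0 - t * t)
                # frame with e3 along x (the walker direction)
                e3x, e3y, e3z = x / rho, y / rho, z / rho
                if abs(e3x) < 0.9:
                    ax, ay, az = 1.0, 0.0, 0.0
                else:
                    ax, ay, az = 0.0, 1.0, 0.0
                e1x = e3y * az - e3z * ay
                e1y = e3z * ax - e3x * az
                e1z = e3x * ay - e3y * ax
                e1n = math.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
                e1x, e1y, e1z = e1x / e1n, e1y / e1n, e1z / e1n
                e2x = e3y * e1z - e3z * e1y
                e2y = e3z * e1x - e3x * e1z
                e2z = e3x * e1y - e3y * e1x
                x = r_launch * (st * math.cos(phi) * e1x
                                + st * math.sin(phi) * e2x + t * e3x)
                y = r_launch * (st * math.cos(phi) * e1y
                                + st * math.sin(phi) * e2y + t * e3y)
                z = r_launch * (st * math.cos(phi) * e1z
                                + st * math.sin(phi) * e2z + t * e3z)
        # walkers exceeding max_steps are counted as misses (negligible)
    return hits
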
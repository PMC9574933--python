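"""Compiled kernels for DPD force evaluation.

All randomness is counter-based: the thermostat noise for a pair (i, j)
at a given step is a pure hash of (seed, step, min(i,j), max(i,j)), so
zeta_ij == zeta_ji exactly, brute-force and cell-list evaluations agree
per pair, and restarts reproduce the identical continuation.

The unsheared cell sweep gathers beads into cell-sorted arrays and
precomputes the periodic image shift per neighbour-cell pair, so the
hot pair loop is free of minimum-image branches.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

U64 = np.uint64
_MIX1 = U64(0x9E3779B97F4A7C15)
_MIX2 = U64(0xBF58476D1CE4E5B9)
_MIX3 = U64(0x94D049BB133111EB)


@njit(cache=True, inline="always")
def _splitmix(z):
    z = (z + _MIX1) & U64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> U64(30))) * _MIX2) & U64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> U64(27))) * _MIX3) & U64(0xFFFFFFFFFFFFFFFF)
    return z ^ (z >> U64(31))


@njit(cache=True, inline="always")
def _pair_hash(seed, step, i, j):
    a = U64(min(i, j))
    b = U64(max(i, j))
    h = _splitmix(U64(seed))
    h = _splitmix(h ^ (U64(step) * U64(0xD6E8FEB86659FD93)))
    h = _splitmix(h ^ (a * U64(0xA24BAED4963EE407)))
    h = _splitmix(h ^ (b * U64(0x9FB21C651E98DF25)))
    return h


@njit(cache=True, inline="always")
def _hash_normal(h):
    # Box-Muller on two 53-bit uniforms derived from the hash chain
    u1 = (float(h >> U64(11)) + 1.0) * (2.0 ** -53)
    h2 = _splitmix(h)
    u2 = float(h2 >> U64(11)) * (2.0 ** -53)
    return math.sqrt(-2.0 * math.log(u1)) * math.cos(2.0 * math.pi * u2)


@njit(cache=True, inline="always")
def pair_normal(seed, step, i, j):
    """Symmetric unit normal for the random force of pair (i, j)."""
    return _hash_normal(_pair_hash(seed, step, i, j))


@njit(cache=True, inline="always")
def _overlap_force(oi, oj, a, seed, step):
    """Maximum repulsion along a seeded random direction (r == 0)."""
    h = _pair_hash(seed, step, oi, oj)
    ux = _hash_normal(h)
    uy = _hash_normal(_splitmix(h ^ U64(0x1)))
    uz = _hash_normal(_splitmix(h ^ U64(0x2)))
    un = math.sqrt(ux * ux + uy * uy + uz * uz)
    if un < 1e-300:
        un = 1.0
    s = a / un
    if oi > oj:
        s = -s
    return s * ux, s * uy, s * uz


@njit(cache=True, inline="always")
def _pair_force(oi, oj, dx, dy, dz, dvx, dvy, dvz, ti, tj, aij, rcij,
                sigma, gamma, inv_sqrt_dt, seed, step, use_thermostat):
    """DPD pair force on bead i given the image-resolved displacement."""
    rc = rcij[ti, tj]
    r2 = dx * dx + dy * dy + dz * dz
    if r2 >= rc * rc:
        return 0.0, 0.0, 0.0
    a = aij[ti, tj]
    if r2 < 1e-24:
        return _overlap_force(oi, oj, a, seed, step)
    r = math.sqrt(r2)
    w = 1.0 - r / rc
    coef = a * w
    if use_thermostat:
        rv = (dx * dvx + dy * dvy + dz * dvz) / r
        zeta = pair_normal(seed, step, oi, oj)
        coef += -gamma * w * w * rv + sigma * w * zeta * inv_sqrt_dt
    s = coef / r
    return s * dx, s * dy, s * dz


@njit(cache=True, inline="always")
def _pair_min_image(i, j, pos, vel, types, aij, rcij, L, offset, shear_rate,
                    sigma, gamma, inv_sqrt_dt, seed, step, use_thermostat):
    """Pair force with on-the-fly Lees-Edwards minimum image."""
    dx = pos[i, 0] - pos[j, 0]
    dy = pos[i, 1] - pos[j, 1]
    dz = pos[i, 2] - pos[j, 2]
    ny = round(dy / L)
    dy -= ny * L
    dx -= ny * offset
    dx -= L * round(dx / L)
    dz -= L * round(dz / L)
    dvx = vel[i, 0] - vel[j, 0] - ny * shear_rate * L
    dvy = vel[i, 1] - vel[j, 1]
    dvz = vel[i, 2] - vel[j, 2]
    return _pair_force(i, j, dx, dy, dz, dvx, dvy, dvz,
                       types[i], types[j], aij, rcij, sigma, gamma,
                       inv_sqrt_dt, seed, step, use_thermostat)


@njit(cache=True)
def nonbonded_forces_brute(pos, vel, types, aij, rcij, L, offset, shear_rate,
                           sigma, gamma, dt, seed, step, use_thermostat, f):
    n = pos.shape[0]
    inv_sqrt_dt = 1.0 / math.sqrt(dt)
    for i in range(n):
        for j in range(i + 1, n):
            fx, fy, fz = _pair_min_image(
                i, j, pos, vel, types, aij, rcij, L, offset, shear_rate,
                sigma, gamma, inv_sqrt_dt, seed, step, use_thermostat)
            f[i, 0] += fx
            f[i, 1] += fy
            f[i, 2] += fz
            f[j, 0] -= fx
            f[j, 1] -= fy
            f[j, 2] -= fz


@njit(cache=True)
def _build_cells(pos, L, ncell):
    n = pos.shape[0]
    ntot = ncell * ncell * ncell
    cell_of = np.empty(n, dtype=np.int64)
    counts = np.zeros(ntot + 1, dtype=np.int64)
    inv = ncell / L
    for i in range(n):
        cx = int(pos[i, 0] * inv)
        cy = int(pos[i, 1] * inv)
        cz = int(pos[i, 2] * inv)
        if cx >= ncell:
            cx = ncell - 1
        if cy >= ncell:
            cy = ncell - 1
        if cz >= ncell:
            cz = ncell - 1
        c = (cx * ncell + cy) * ncell + cz
        cell_of[i] = c
        counts[c + 1] += 1
    for c in range(ntot):
        counts[c + 1] += counts[c]
    order = np.empty(n, dtype=np.int64)
    cursor = counts[:-1].copy()
    for i in range(n):
        c = cell_of[i]
        order[cursor[c]] = i
        cursor[c] += 1
    return counts, order


# half-shell neighbour offsets (dx, dy, dz)
_HALF_SHELL = np.array([
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, -1, 1), (1, 1, -1), (1, -1, -1)], dtype=np.int64)


@njit(cache=True)
def nonbonded_forces_cells(pos, vel, types, aij, rcij, L, offset, shear_rate,
                           sigma, gamma, dt, seed, step, use_thermostat,
                           max_cutoff, f):
    """Cell-list evaluation; falls back to brute force for tiny boxes.

    Without shear the half-shell sweep applies a precomputed image
    shift per neighbour cell, so the pair loop needs no minimum-image
    logic.  With an active Lees-Edwards offset the cell columns across
    the y boundary are misaligned; that path uses a full-shell sweep in
    which rows wrapping in y scan every x column, with per-pair minimum
    images.
    """
    ncell = int(L / max_cutoff)
    if ncell < 3:
        nonbonded_forces_brute(pos, vel, types, aij, rcij, L, offset,
                               shear_rate, sigma, gamma, dt, seed, step,
                               use_thermostat, f)
        return
    counts, order = _build_cells(pos, L, ncell)
    inv_sqrt_dt = 1.0 / math.sqrt(dt)
    sheared = (offset != 0.0) or (shear_rate != 0.0)
    n = pos.shape[0]
    if not sheared:
        # gather into cell-sorted arrays
        ps = np.empty((n, 3))
        vs = np.empty((n, 3))
        ts = np.empty(n, dtype=types.dtype)
        for k in range(n):
            i = order[k]
            ps[k, 0] = pos[i, 0]
            ps[k, 1] = pos[i, 1]
            ps[k, 2] = pos[i, 2]
            vs[k, 0] = vel[i, 0]
            vs[k, 1] = vel[i, 1]
            vs[k, 2] = vel[i, 2]
            ts[k] = types[i]
        fs = np.zeros((n, 3))
        nsh = _HALF_SHELL.shape[0]
        for cx in range(ncell):
            for cy in range(ncell):
                for cz in range(ncell):
                    c = (cx * ncell + cy) * ncell + cz
                    i0, i1 = counts[c], counts[c + 1]
                    # same-cell pairs: no image shift
                    for ii in range(i0, i1):
                        oi = order[ii]
                        xi = ps[ii, 0]
                        yi = ps[ii, 1]
                        zi = ps[ii, 2]
                        ti = ts[ii]
                        for jj in range(ii + 1, i1):
                            fx, fy, fz = _pair_force(
                                oi, order[jj],
                                xi - ps[jj, 0], yi - ps[jj, 1],
                                zi - ps[jj, 2],
                                vs[ii, 0] - vs[jj, 0],
                                vs[ii, 1] - vs[jj, 1],
                                vs[ii, 2] - vs[jj, 2],
                                ti, ts[jj], aij, rcij, sigma, gamma,
                                inv_sqrt_dt, seed, step, use_thermostat)
                            fs[ii, 0] += fx
                            fs[ii, 1] += fy
                            fs[ii, 2] += fz
                            fs[jj, 0] -= fx
                            fs[jj, 1] -= fy
                            fs[jj, 2] -= fz
                    for kk in range(nsh):
                        xraw = cx + _HALF_SHELL[kk, 0]
                        yraw = cy + _HALF_SHELL[kk, 1]
                        zraw = cz + _HALF_SHELL[kk, 2]
                        # periodic image shift of the neighbour cell
                        sx = 0.0
                        sy = 0.0
                        sz = 0.0
                        nx = xraw
                        if xraw >= ncell:
                            nx = xraw - ncell
                            sx = L
                        elif xraw < 0:
                            nx = xraw + ncell
                            sx = -L
                        nyc = yraw
                        if yraw >= ncell:
                            nyc = yraw - ncell
                            sy = L
                        elif yraw < 0:
                            nyc = yraw + ncell
                            sy = -L
                        nz = zraw
                        if zraw >= ncell:
                            nz = zraw - ncell
                            sz = L
                        elif zraw < 0:
                            nz = zraw + ncell
                            sz = -L
                        d = (nx * ncell + nyc) * ncell + nz
                        j0, j1 = counts[d], counts[d + 1]
                        for ii in range(i0, i1):
                            oi = order[ii]
                            # i viewed from the neighbour cell's image
                            xi = ps[ii, 0] - sx
                            yi = ps[ii, 1] - sy
                            zi = ps[ii, 2] - sz
                            ti = ts[ii]
                            for jj in range(j0, j1):
                                fx, fy, fz = _pair_force(
                                    oi, order[jj],
                                    xi - ps[jj, 0], yi - ps[jj, 1],
                                    zi - ps[jj, 2],
                                    vs[ii, 0] - vs[jj, 0],
                                    vs[ii, 1] - vs[jj, 1],
                                    vs[ii, 2] - vs[jj, 2],
                                    ti, ts[jj], aij, rcij, sigma, gamma,
                                    inv_sqrt_dt, seed, step, use_thermostat)
                                fs[ii, 0] += fx
                                fs[ii, 1] += fy
                                fs[ii, 2] += fz
                                fs[jj, 0] -= fx
                                fs[jj, 1] -= fy
                                fs[jj, 2] -= fz
        for k in range(n):
            i = order[k]
            f[i, 0] += fs[k, 0]
            f[i, 1] += fs[k, 1]
            f[i, 2] += fs[k, 2]
        return
    # sheared path: full shell, one-sided accumulation onto i
    for cx in range(ncell):
        for cy in range(ncell):
            for cz in range(ncell):
                c = (cx * ncell + cy) * ncell + cz
                i0, i1 = counts[c], counts[c + 1]
                for dy in range(-1, 2):
                    ywrap = (cy + dy < 0) or (cy + dy >= ncell)
                    nyc = (cy + dy) % ncell
                    for dz in range(-1, 2):
                        nz = (cz + dz) % ncell
                        if ywrap:
                            xlo, xhi = 0, ncell
                        else:
                            xlo, xhi = cx - 1, cx + 2
                        for x in range(xlo, xhi):
                            nx = x % ncell
                            d = (nx * ncell + nyc) * ncell + nz
                            j0, j1 = counts[d], counts[d + 1]
                            for ii in range(i0, i1):
                                i = order[ii]
                                for jj in range(j0, j1):
                                    j = order[jj]
                                    if j == i:
                                        continue
                                    fx, fy, fz = _pair_min_image(
                                        i, j, pos, vel, types, aij, rcij,
                                        L, offset, shear_rate, sigma,
                                        gamma, inv_sqrt_dt, seed, step,
                                        use_thermostat)
                                    f[i, 0] += fx
                                    f[i, 1] += fy
                                    f[i, 2] += fz


@njit(cache=True)
def bonded_forces(pos, bond_i, bond_j, bond_l0, bond_c,
                  ang_i, ang_j, ang_k, theta0, dconst,
                  L, offset, f):
    """Harmonic bond and angle forces (minimum-image displacements)."""
    for b in range(bond_i.shape[0]):
        i = bond_i[b]
        j = bond_j[b]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        ny = round(dy / L)
        dy -= ny * L
        dx -= ny * offset
        dx -= L * round(dx / L)
        dz -= L * round(dz / L)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        s = -bond_c[b] * (r - bond_l0[b]) / r
        f[i, 0] += s * dx
        f[i, 1] += s * dy
        f[i, 2] += s * dz
        f[j, 0] -= s * dx
        f[j, 1] -= s * dy
        f[j, 2] -= s * dz
    for a in range(ang_i.shape[0]):
        i = ang_i[a]
        j = ang_j[a]
        k = ang_k[a]
        b1x = pos[i, 0] - pos[j, 0]
        b1y = pos[i, 1] - pos[j, 1]
        b1z = pos[i, 2] - pos[j, 2]
        ny = round(b1y / L)
        b1y -= ny * L
        b1x -= ny * offset
        b1x -= L * round(b1x / L)
        b1z -= L * round(b1z / L)
        b2x = pos[k, 0] - pos[j, 0]
        b2y = pos[k, 1] - pos[j, 1]
        b2z = pos[k, 2] - pos[j, 2]
        ny = round(b2y / L)
        b2y -= ny * L
        b2x -= ny * offset
        b2x -= L * round(b2x / L)
        b2z -= L * round(b2z / L)
        r1 = math.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
        r2 = math.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        if r1 < 1e-12 or r2 < 1e-12:
            continue
        u1x, u1y, u1z = b1x / r1, b1y / r1, b1z / r1
        u2x, u2y, u2z = b2x / r2, b2y / r2, b2z / r2
        cost = u1x * u2x + u1y * u2y + u1z * u2z
        if cost > 1.0:
            cost = 1.0
        elif cost < -1.0:
            cost = -1.0
        theta = math.acos(cost)
        sint = math.sqrt(max(1.0 - cost * cost, 1e-16))
        coef = dconst[a] * (theta - theta0[a]) / sint
        fix = (coef / r1) * (u2x - cost * u1x)
        fiy = (coef / r1) * (u2y - cost * u1y)
        fiz = (coef / r1) * (u2z - cost * u1z)
        fkx = (coef / r2) * (u1x - cost * u2x)
        fky = (coef / r2) * (u1y - cost * u2y)
        fkz = (coef / r2) * (u1z - cost * u2z)
        f[i, 0] += fix
        f[i, 1] += fiy
        f[i, 2] += fiz
        f[k, 0] += fkx
        f[k, 1] += fky
        f[k, 2] += fkz
        f[j, 0] -= fix + fkx
        f[j, 1] -= fiy + fky
        f[j, 2] -= fiz + fkz


@njit(cache=True, inline="always")
def _short_range_pair(r2, qq, beta, alpha, rcut):
    """(energy, f/r) of the erfc and smearing terms at one image."""
    r = math.sqrt(r2)
    e = 0.0
    fr = 0.0
    if r < rcut:
        er = math.erfc(alpha * r)
        e += qq * er / r
        fr += qq * (er / r2
                    + 2.0 * alpha / math.sqrt(math.pi)
                    * math.exp(-alpha * alpha * r2) / r)
    # Slater smearing correction: u = -qq (1/r + beta) exp(-2 beta r)
    ex = math.exp(-2.0 * beta * r)
    e -= qq * (1.0 / r + beta) * ex
    fr -= qq * ex * (1.0 / r2 + 2.0 * beta / r + 2.0 * beta * beta)
    return e, fr / r


@njit(cache=True)
def ewald_real_and_correction(pos, q, idx, ke, beta, alpha, rcut, rsm,
                              L, offset, f):
    """Short-range electrostatics: erfc Ewald part + smearing correction.

    Both terms are summed over every periodic image within their
    cutoffs (``rcut`` for the erfc part, ``rsm >= rcut`` for the
    exponential smearing correction), so boxes smaller than twice the
    correction range remain accurate.  Image shifts across the y
    boundary honour the Lees-Edwards x offset.  Returns the real-space
    energy, including charge self-image interactions.
    """
    e = 0.0
    nq = idx.shape[0]
    rsm2 = rsm * rsm
    for a in range(nq):
        i = idx[a]
        for b in range(a, nq):
            j = idx[b]
            qq = ke * q[i] * q[j]
            dx0 = pos[i, 0] - pos[j, 0]
            dy0 = pos[i, 1] - pos[j, 1]
            dz0 = pos[i, 2] - pos[j, 2]
            by = -round(dy0 / L)
            for ty in range(-1, 2):
                sy = by + ty
                dy = dy0 + sy * L
                if dy * dy > rsm2:
                    continue
                dxe = dx0 + sy * offset
                bx = -round(dxe / L)
                for tx in range(-1, 2):
                    dx = dxe + (bx + tx) * L
                    d2xy = dx * dx + dy * dy
                    if d2xy > rsm2:
                        continue
                    bz = -round(dz0 / L)
                    for tz in range(-1, 2):
                        dz = dz0 + (bz + tz) * L
                        r2 = d2xy + dz * dz
                        if r2 > rsm2 or r2 < 1e-24:
                            continue
                        pe, s = _short_range_pair(r2, qq, beta, alpha, rcut)
                        if i == j:
                            e += 0.5 * pe  # self images; forces cancel
                        else:
                            e += pe
                            f[i, 0] += s * dx
                            f[i, 1] += s * dy
                            f[i, 2] += s * dz
                            f[j, 0] -= s * dx
                            f[j, 1] -= s * dy
                            f[j, 2] -= s * dz
    return e


@njit(cache=True)
def ewald_kspace(pos, q, idx, ke, alpha, L, offset, nmax, f):
    """Reciprocal-space Ewald sum for the (possibly sheared) cell.

    The Lees-Edwards cell is triclinic with tilt ``offset`` in xy; the
    reciprocal basis is built from its inverse.  Returns the k-space
    energy (self-energy excluded; add ``-ke*alpha/sqrt(pi)*sum q^2``).
    """
    nq = idx.shape[0]
    V = L * L * L
    # cell H = [[L, offset, 0], [0, L, 0], [0, 0, L]] (columns a1,a2,a3)
    # reciprocal rows b_m = 2*pi*(H^-1)[m, :]
    twopi = 2.0 * math.pi
    b1x, b1y, b1z = twopi / L, 0.0, 0.0
    b2x, b2y, b2z = -twopi * offset / (L * L), twopi / L, 0.0
    b3x, b3y, b3z = 0.0, 0.0, twopi / L

    nt = 2 * nmax + 1
    # phase tables per reciprocal direction
    c1 = np.empty((nq, nt))
    s1 = np.empty((nq, nt))
    c2 = np.empty((nq, nt))
    s2 = np.empty((nq, nt))
    c3 = np.empty((nq, nt))
    s3 = np.empty((nq, nt))
    for a in range(nq):
        i = idx[a]
        p1 = b1x * pos[i, 0] + b1y * pos[i, 1] + b1z * pos[i, 2]
        p2 = b2x * pos[i, 0] + b2y * pos[i, 1] + b2z * pos[i, 2]
        p3 = b3x * pos[i, 0] + b3y * pos[i, 1] + b3z * pos[i, 2]
        for n in range(-nmax, nmax + 1):
            c1[a, n + nmax] = math.cos(n * p1)
            s1[a, n + nmax] = math.sin(n * p1)
            c2[a, n + nmax] = math.cos(n * p2)
            s2[a, n + nmax] = math.sin(n * p2)
            c3[a, n + nmax] = math.cos(n * p3)
            s3[a, n + nmax] = math.sin(n * p3)

    kcut2 = (2.0 * alpha * 3.1) ** 2 * 1.0000001
    energy = 0.0
    cr = np.empty(nq)
    ci = np.empty(nq)
    for n1 in range(-nmax, nmax + 1):
        for n2 in range(-nmax, nmax + 1):
            for n3 in range(0, nmax + 1):
                if n3 == 0:
                    if n1 < 0 or (n1 == 0 and n2 <= 0):
                        continue  # half space; k and -k combined below
                kx = n1 * b1x + n2 * b2x + n3 * b3x
                ky = n1 * b1y + n2 * b2y + n3 * b3y
                kz = n1 * b1z + n2 * b2z + n3 * b3z
                k2 = kx * kx + ky * ky + kz * kz
                if k2 > kcut2 or k2 < 1e-14:
                    continue
                sr = 0.0
                si = 0.0
                for a in range(nq):
                    # e^{i k.r} by multiplying per-direction phases
                    re12 = (c1[a, n1 + nmax] * c2[a, n2 + nmax]
                            - s1[a, n1 + nmax] * s2[a, n2 + nmax])
                    im12 = (c1[a, n1 + nmax] * s2[a, n2 + nmax]
                            + s1[a, n1 + nmax] * c2[a, n2 + nmax])
                    re = re12 * c3[a, n3 + nmax] - im12 * s3[a, n3 + nmax]
                    im = re12 * s3[a, n3 + nmax] + im12 * c3[a, n3 + nmax]
                    cr[a] = re
                    ci[a] = im
                    qi = q[idx[a]]
                    sr += qi * re
                    si += qi * im
                ak = math.exp(-k2 / (4.0 * alpha * alpha)) / k2
                # factor 2: half-space sum counts k and -k together
                energy += 2.0 * ke * twopi / V * ak * (sr * sr + si * si)
                fpref = 4.0 * ke * twopi / V * ak
                for a in range(nq):
                    i = idx[a]
                    g = fpref * q[i] * (ci[a] * sr - cr[a] * si)
                    f[i, 0] += g * kx
                    f[i, 1] += g * ky
                    f[i, 2] += g * kz
    return energy
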
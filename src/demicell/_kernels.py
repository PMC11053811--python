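"""Numba inner loops for pair/bond force evaluation.

Cubic periodic box, minimum-image convention.  Pair interactions use the
cut-and-shifted Lennard-Jones form with per-type-pair (eps, rc); bonds use
FENE optionally composed with a WCA core.  Kept free of Python objects so
the per-step cost stays in compiled code.
"""

import numba
import numpy as np

WCA_CUTOFF2 = 2.0 ** (1.0 / 3.0)


@numba.njit(cache=True, fastmath=True)
def pair_forces(pos, pairs, types, eps_mat, rc2_mat, shift_mat, L, fcap, forces):
    """Accumulate LJ pair forces into ``forces``; returns potential energy.

    ``fcap`` limits the pair force magnitude (push-off stage relaxes the
    random initial overlaps without numerical blow-up); pass inf for the
    untouched potential.
    """
    energy = 0.0
    half = 0.5 * L
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if dx > half:
            dx -= L
        elif dx < -half:
            dx += L
        if dy > half:
            dy -= L
        elif dy < -half:
            dy += L
        if dz > half:
            dz -= L
        elif dz < -half:
            dz += L
        r2 = dx * dx + dy * dy + dz * dz
        ti = types[i]
        tj = types[j]
        rc2 = rc2_mat[ti, tj]
        if r2 < rc2 and r2 > 1e-12:
            eps = eps_mat[ti, tj]
            inv2 = 1.0 / r2
            inv6 = inv2 * inv2 * inv2
            inv12 = inv6 * inv6
            energy += 4.0 * eps * (inv12 - inv6) + shift_mat[ti, tj]
            fmag = 24.0 * eps * (2.0 * inv12 - inv6) * inv2
            r = np.sqrt(r2)
            if fmag * r > fcap:
                fmag = fcap / r
            fx = fmag * dx
            fy = fmag * dy
            fz = fmag * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
    return energy


@numba.njit(cache=True, fastmath=True)
def bond_forces(pos, bonds, active, L, k, r0, bonded_wca, forces):
    """FENE (+ optional WCA) forces for active bonds.

    Returns (energy, overstretched_bond_index); the index is -1 when every
    bond is shorter than R0, otherwise the energy is meaningless and the
    caller must abort.
    """
    energy = 0.0
    r02 = r0 * r0
    half = 0.5 * L
    for b in range(bonds.shape[0]):
        if not active[b]:
            continue
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if dx > half:
            dx -= L
        elif dx < -half:
            dx += L
        if dy > half:
            dy -= L
        elif dy < -half:
            dy += L
        if dz > half:
            dz -= L
        elif dz < -half:
            dz += L
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= r02:
            return 0.0, b
        energy += -0.5 * k * r02 * np.log(1.0 - r2 / r02)
        fmag = -k / (1.0 - r2 / r02)
        if bonded_wca and r2 < WCA_CUTOFF2 and r2 > 1e-12:
            inv2 = 1.0 / r2
            inv6 = inv2 * inv2 * inv2
            inv12 = inv6 * inv6
            energy += 4.0 * (inv12 - inv6) + 1.0
            fmag += 24.0 * (2.0 * inv12 - inv6) * inv2
        fx = fmag * dx
        fy = fmag * dy
        fz = fmag * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
    return energy, -1


@numba.njit(cache=True, fastmath=True)
def max_sq_displacement(pos, ref, L):
    best = 0.0
    for i in range(pos.shape[0]):
        dx = pos[i, 0] - ref[i, 0]
        dy = pos[i, 1] - ref[i, 1]
        dz = pos[i, 2] - ref[i, 2]
        dx -= L * np.rint(dx / L)
        dy -= L * np.rint(dy / L)
        dz -= L * np.rint(dz / L)
        d2 = dx * dx + dy * dy + dz * dz
        if d2 > best:
            best = d2
    return best


@numba.njit(cache=True, fastmath=True)
def nearest_in_range(pos, sources, targets, L, rcut2):
    """Per source bead: local index of the nearest target bead within
    sqrt(rcut2) under minimum image, or -1.  Brute force; both lists are
    small (end-caps x triggers)."""
    out = np.full(sources.shape[0], -1, dtype=np.int64)
    half = 0.5 * L
    for a in range(sources.shape[0]):
        i = sources[a]
        best = rcut2
        for b in range(targets.shape[0]):
            j = targets[b]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            if dx > half:
                dx -= L
            elif dx < -half:
                dx += L
            if dy > half:
                dy -= L
            elif dy < -half:
                dy += L
            if dz > half:
                dz -= L
            elif dz < -half:
                dz += L
            r2 = dx * dx + dy * dy + dz * dz
            if r2 <= best:
                best = r2
                out[a] = b
    return out


@numba.njit(cache=True)
def _is_bonded(i, j, bond_codes, n):
    if i > j:
        i, j = j, i
    code = i * n + j
    lo = np.searchsorted(bond_codes, code)
    return lo < bond_codes.shape[0] and bond_codes[lo] == code


@numba.njit(cache=True, fastmath=True)
def build_pair_list(pos, L, rlist, bond_codes, cap):
    """Cell-list enumeration of non-bonded pairs within ``rlist``
    (minimum image); bonded pairs (sorted i*n+j codes) are skipped inline.

    Returns (pairs, count); when count > cap the caller must retry with a
    larger capacity.  Falls back to the O(n^2) loop when the box holds
    fewer than three cells per edge.
    """
    n = pos.shape[0]
    pairs = np.empty((cap, 2), dtype=np.int64)
    count = 0
    r2max = rlist * rlist
    ncell = int(L / rlist)
    if ncell < 3:
        for i in range(n):
            for j in range(i + 1, n):
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                dx -= L * np.rint(dx / L)
                dy -= L * np.rint(dy / L)
                dz -= L * np.rint(dz / L)
                if dx * dx + dy * dy + dz * dz < r2max:
                    if not _is_bonded(i, j, bond_codes, n):
                        if count < cap:
                            pairs[count, 0] = i
                            pairs[count, 1] = j
                        count += 1
        return pairs, count

    cell = L / ncell
    ncell3 = ncell * ncell * ncell
    cid = np.empty(n, dtype=np.int64)
    for i in range(n):
        cx = int(pos[i, 0] / cell) % ncell
        cy = int(pos[i, 1] / cell) % ncell
        cz = int(pos[i, 2] / cell) % ncell
        cid[i] = (cx * ncell + cy) * ncell + cz
    # counting sort of bead indices by cell
    head = np.zeros(ncell3 + 1, dtype=np.int64)
    for i in range(n):
        head[cid[i] + 1] += 1
    for c in range(ncell3):
        head[c + 1] += head[c]
    slot = head.copy()
    order = np.empty(n, dtype=np.int64)
    for i in range(n):
        order[slot[cid[i]]] = i
        slot[cid[i]] += 1

    half = 0.5 * L
    # 13 forward neighbour offsets + the cell itself
    for cx in range(ncell):
        for cy in range(ncell):
            for cz in range(ncell):
                c0 = (cx * ncell + cy) * ncell + cz
                for off in range(14):
                    ox = OFFSETS[off, 0]
                    oy = OFFSETS[off, 1]
                    oz = OFFSETS[off, 2]
                    c1 = (((cx + ox) % ncell) * ncell + (cy + oy) % ncell) * ncell \
                        + (cz + oz) % ncell
                    same = c1 == c0
                    for a in range(head[c0], head[c0 + 1]):
                        i = order[a]
                        b0 = a + 1 if same else head[c1]
                        for b in range(b0, head[c1 + 1]):
                            j = order[b]
                            dx = pos[i, 0] - pos[j, 0]
                            dy = pos[i, 1] - pos[j, 1]
                            dz = pos[i, 2] - pos[j, 2]
                            if dx > half:
                                dx -= L
                            elif dx < -half:
                                dx += L
                            if dy > half:
                                dy -= L
                            elif dy < -half:
                                dy += L
                            if dz > half:
                                dz -= L
                            elif dz < -half:
                                dz += L
                            if dx * dx + dy * dy + dz * dz < r2max:
                                if not _is_bonded(i, j, bond_codes, n):
                                    if count < cap:
                                        pairs[count, 0] = i
                                        pairs[count, 1] = j
                                    count += 1
    return pairs, count


OFFSETS = np.array([
    [0, 0, 0],
    [1, 0, 0], [1, 1, 0], [1, -1, 0], [0, 1, 0],
    [1, 0, 1], [1, 1, 1], [1, -1, 1], [0, 1, 1],
    [1, 0, -1], [1, 1, -1], [1, -1, -1], [0, 1, -1],
    [0, 0, 1],
], dtype=np.int64)


@numba.njit(cache=True, fastmath=True)
def baoab_pre(pos, vel, images, forces, noise, half_dt, c1, c2, L):
    """Fused B(dt/2) A(dt/2) O A(dt/2) sweep with in-place wrapping.

    The trailing B(dt/2) kick happens after the force recomputation, in
    ``final_kick``.
    """
    n = pos.shape[0]
    for i in range(n):
        for d in range(3):
            v = vel[i, d] + half_dt * forces[i, d]
            x = pos[i, d] + half_dt * v
            v = c1 * v + c2 * noise[i, d]
            x += half_dt * v
            if x < 0.0 or x >= L:
                s = np.floor(x / L)
                images[i, d] += np.int64(s)
                x -= s * L
                if x >= L:          # guard against floating-point edge
                    x -= L
                    images[i, d] += 1
            vel[i, d] = v
            pos[i, d] = x


@numba.njit(cache=True, fastmath=True)
def final_kick(vel, forces, half_dt):
    n = vel.shape[0]
    for i in range(n):
        for d in range(3):
            vel[i, d] += half_dt * forces[i, d]
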
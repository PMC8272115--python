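"""Numba kernels for the DPD force loop and integrator.

All kernels work on flat arrays in reduced units with a cubic periodic box,
coordinates wrapped into [0, L).  The pair search uses a linked-cell
decomposition (cells at least one cutoff wide, half-shell neighbor
enumeration) with an all-pairs fallback for boxes smaller than three
cutoffs.

Numerical layout: master positions/velocities/forces are float64; the
per-step cell-sorted working copies used in the pair loop are float32 (pair
distances and weights need ~1e-7 relative accuracy at most, far below the
thermal noise), while each pair's force value is widened to float64 before
being added to bead i and subtracted from bead j, so pairwise antisymmetry
— and with it momentum conservation — is exact to float64 rounding.

Random-force noise is Gaussian, one deviate per interacting pair per step,
drawn from a Marsaglia-Tsang ziggurat sampler driven by an explicit
xorshift128+ generator state, which makes runs bitwise reproducible for a
given seed and keeps the per-draw cost negligible next to the force
arithmetic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: half-shell of neighbor cell offsets (13 cells; same cell handled separately)
_OFFSETS = np.array(
    [
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
        (0, 1, 1), (0, 1, -1),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    ],
    dtype=np.int64,
)


# ---------------------------------------------------------------------------
# random numbers
# ---------------------------------------------------------------------------

def rng_state(seed: int) -> np.ndarray:
    """Initialize an xorshift128+ state (two nonzero 64-bit words) from a
    seed via the splitmix64 expander."""
    mask = 0xFFFFFFFFFFFFFFFF
    state = np.empty(2, dtype=np.uint64)
    z = seed & mask
    for i in range(2):
        z = (z + 0x9E3779B97F4A7C15) & mask
        t = z
        t = ((t ^ (t >> 30)) * 0xBF58476D1CE4E5B9) & mask
        t = ((t ^ (t >> 27)) * 0x94D049BB133111EB) & mask
        state[i] = np.uint64(t ^ (t >> 31))
    if state[0] == 0 and state[1] == 0:  # all-zero state is absorbing
        state[0] = np.uint64(1)
    return state


@njit(inline='always')
def _xsr_next(st):
    """One xorshift128+ step; returns a uint64 and advances ``st`` in place."""
    s1 = st[0]
    s0 = st[1]
    st[0] = s0
    s1 ^= s1 << np.uint64(23)
    s1 ^= s1 >> np.uint64(17)
    s1 ^= s0 ^ (s0 >> np.uint64(26))
    st[1] = s1
    return s0 + s1


@njit(inline='always')
def _uniform(st):
    """Uniform double in (0, 1]."""
    return 1.0 - (_xsr_next(st) >> np.uint64(11)) * 1.1102230246251565e-16


def _build_ziggurat():
    """Tables for the Marsaglia-Tsang ziggurat normal sampler (128 layers)."""
    r = 3.442619855899
    v = 9.91256303526217e-3
    m = 2147483648.0  # 2^31, magnitude range of a signed 32-bit draw
    kn = np.zeros(128, dtype=np.int64)
    wn = np.zeros(128)
    fn = np.zeros(128)
    dn = r
    tn = r
    q = v / np.exp(-0.5 * dn * dn)
    kn[0] = int((dn / q) * m)
    kn[1] = 0
    wn[0] = q / m
    wn[127] = dn / m
    fn[0] = 1.0
    fn[127] = np.exp(-0.5 * dn * dn)
    for i in range(126, 0, -1):
        dn = np.sqrt(-2.0 * np.log(v / dn + np.exp(-0.5 * dn * dn)))
        kn[i + 1] = int((dn / tn) * m)
        tn = dn
        fn[i] = np.exp(-0.5 * dn * dn)
        wn[i] = dn / m
    return kn, wn, fn


_ZIG_KN, _ZIG_WN, _ZIG_FN = _build_ziggurat()
_ZIG_R = 3.442619855899


@njit(cache=True, fastmath=True, error_model='numpy')
def gauss(st):
    """Standard normal deviate via the ziggurat method (exact N(0, 1))."""
    while True:
        hz = np.int64(_xsr_next(st) >> np.uint64(32)) - 2147483648
        iz = hz & 127
        if hz < 0:
            ahz = -hz
        else:
            ahz = hz
        if ahz < _ZIG_KN[iz]:
            return hz * _ZIG_WN[iz]
        if iz == 0:
            # tail beyond +-r
            while True:
                x = -np.log(_uniform(st)) / _ZIG_R
                y = -np.log(_uniform(st))
                if y + y > x * x:
                    if hz > 0:
                        return _ZIG_R + x
                    return -_ZIG_R - x
        else:
            x = hz * _ZIG_WN[iz]
            if (_ZIG_FN[iz] + _uniform(st) * (_ZIG_FN[iz - 1] - _ZIG_FN[iz])
                    < np.exp(-0.5 * x * x)):
                return x


@njit(cache=True)
def gauss_fill(out, st):
    """Fill an array with standard normal deviates (for distribution tests)."""
    for i in range(out.shape[0]):
        out[i] = gauss(st)


# ---------------------------------------------------------------------------
# cell bookkeeping
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True, error_model='numpy')
def _cell_sort(pos, box, ncell, cid, cstart, order):
    """Counting sort of bead indices by cell; fills cstart (M+1) and order."""
    n = pos.shape[0]
    inv = ncell / box
    m = ncell * ncell * ncell
    for i in range(n):
        cx = int(pos[i, 0] * inv)
        cy = int(pos[i, 1] * inv)
        cz = int(pos[i, 2] * inv)
        if cx < 0:
            cx = 0
        elif cx >= ncell:
            cx = ncell - 1
        if cy < 0:
            cy = 0
        elif cy >= ncell:
            cy = ncell - 1
        if cz < 0:
            cz = 0
        elif cz >= ncell:
            cz = ncell - 1
        cid[i] = (cx * ncell + cy) * ncell + cz
    for c in range(m + 1):
        cstart[c] = 0
    for i in range(n):
        cstart[cid[i] + 1] += 1
    for c in range(m):
        cstart[c + 1] += cstart[c]
    ptr = cstart[:m].copy()
    for i in range(n):
        c = cid[i]
        order[ptr[c]] = i
        ptr[c] += 1


@njit(cache=True, fastmath=True, error_model='numpy')
def _neighbor_tables(ncell, box):
    """Static per-cell half-shell neighbor indices and periodic shifts."""
    m = ncell * ncell * ncell
    nbr = np.empty((m, 13), np.int64)
    shift = np.empty((m, 13, 3), np.float32)
    for cx in range(ncell):
        for cy in range(ncell):
            for cz in range(ncell):
                c = (cx * ncell + cy) * ncell + cz
                for o in range(13):
                    nx = cx + _OFFSETS[o, 0]
                    sx = 0.0
                    if nx >= ncell:
                        nx -= ncell
                        sx = box
                    elif nx < 0:
                        nx += ncell
                        sx = -box
                    ny = cy + _OFFSETS[o, 1]
                    sy = 0.0
                    if ny >= ncell:
                        ny -= ncell
                        sy = box
                    elif ny < 0:
                        ny += ncell
                        sy = -box
                    nz = cz + _OFFSETS[o, 2]
                    sz = 0.0
                    if nz >= ncell:
                        nz -= ncell
                        sz = box
                    elif nz < 0:
                        nz += ncell
                        sz = -box
                    nbr[c, o] = (nx * ncell + ny) * ncell + nz
                    shift[c, o, 0] = sx
                    shift[c, o, 1] = sy
                    shift[c, o, 2] = sz
    return nbr, shift


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True, error_model='numpy')
def _nb_forces_cells(pos, vel, types, a32, gamma32, sigdt32, box, rcut, ncell,
                     nbr, shift, st, cid, cstart, order, pk, fx, fy, fz, fout):
    """Nonbonded DPD forces (conservative + dissipative + random) via cells.

    ``vel`` is the velocity used in the dissipative term (the predicted
    velocity inside the modified velocity-Verlet step).  ``sigdt32`` is
    sigma / sqrt(dt); pass 0.0 to disable noise.  ``pk`` is the (N, 8)
    float32 cell-sorted working array (x, y, z, vx, vy, vz, type, unused);
    one bead per 32-byte row.  Fills ``fout`` (float64).
    """
    n = pos.shape[0]
    _cell_sort(pos, box, ncell, cid, cstart, order)
    for k in range(n):
        i = order[k]
        pk[k, 0] = pos[i, 0]
        pk[k, 1] = pos[i, 1]
        pk[k, 2] = pos[i, 2]
        pk[k, 3] = vel[i, 0]
        pk[k, 4] = vel[i, 1]
        pk[k, 5] = vel[i, 2]
        pk[k, 6] = types[i]
        fx[k] = 0.0
        fy[k] = 0.0
        fz[k] = 0.0
    one = np.float32(1.0)
    zero = np.float32(0.0)
    rcut2 = np.float32(rcut * rcut)
    inv_rcut = np.float32(1.0 / rcut)
    noise = sigdt32 != zero
    m = ncell * ncell * ncell
    for c in range(m):
        c0 = cstart[c]
        c1 = cstart[c + 1]
        # pairs within the cell
        for k1 in range(c0, c1):
            x1 = pk[k1, 0]
            y1 = pk[k1, 1]
            z1 = pk[k1, 2]
            vx1 = pk[k1, 3]
            vy1 = pk[k1, 4]
            vz1 = pk[k1, 5]
            t1 = int(pk[k1, 6])
            f1x = 0.0
            f1y = 0.0
            f1z = 0.0
            for k2 in range(k1 + 1, c1):
                dx = x1 - pk[k2, 0]
                dy = y1 - pk[k2, 1]
                dz = z1 - pk[k2, 2]
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < rcut2 and r2 > zero:
                    invr = one / np.sqrt(r2)
                    w = one - r2 * invr * inv_rcut
                    ex = dx * invr
                    ey = dy * invr
                    ez = dz * invr
                    vde = ((vx1 - pk[k2, 3]) * ex
                           + (vy1 - pk[k2, 4]) * ey
                           + (vz1 - pk[k2, 5]) * ez)
                    fmag = w * (a32[t1, int(pk[k2, 6])] - gamma32 * w * vde)
                    if noise:
                        fmag += sigdt32 * w * np.float32(gauss(st))
                    gx = np.float64(fmag * ex)
                    gy = np.float64(fmag * ey)
                    gz = np.float64(fmag * ez)
                    f1x += gx
                    f1y += gy
                    f1z += gz
                    fx[k2] -= gx
                    fy[k2] -= gy
                    fz[k2] -= gz
            fx[k1] += f1x
            fy[k1] += f1y
            fz[k1] += f1z
        # pairs with the 13 half-shell neighbor cells
        for o in range(13):
            nc = nbr[c, o]
            sx = shift[c, o, 0]
            sy = shift[c, o, 1]
            sz = shift[c, o, 2]
            n0 = cstart[nc]
            n1 = cstart[nc + 1]
            for k1 in range(c0, c1):
                x1 = pk[k1, 0] - sx
                y1 = pk[k1, 1] - sy
                z1 = pk[k1, 2] - sz
                vx1 = pk[k1, 3]
                vy1 = pk[k1, 4]
                vz1 = pk[k1, 5]
                t1 = int(pk[k1, 6])
                f1x = 0.0
                f1y = 0.0
                f1z = 0.0
                for k2 in range(n0, n1):
                    dx = x1 - pk[k2, 0]
                    dy = y1 - pk[k2, 1]
                    dz = z1 - pk[k2, 2]
                    r2 = dx * dx + dy * dy + dz * dz
                    if r2 < rcut2 and r2 > zero:
                        invr = one / np.sqrt(r2)
                        w = one - r2 * invr * inv_rcut
                        ex = dx * invr
                        ey = dy * invr
                        ez = dz * invr
                        vde = ((vx1 - pk[k2, 3]) * ex
                               + (vy1 - pk[k2, 4]) * ey
                               + (vz1 - pk[k2, 5]) * ez)
                        fmag = w * (a32[t1, int(pk[k2, 6])] - gamma32 * w * vde)
                        if noise:
                            fmag += sigdt32 * w * np.float32(gauss(st))
                        gx = np.float64(fmag * ex)
                        gy = np.float64(fmag * ey)
                        gz = np.float64(fmag * ez)
                        f1x += gx
                        f1y += gy
                        f1z += gz
                        fx[k2] -= gx
                        fy[k2] -= gy
                        fz[k2] -= gz
                fx[k1] += f1x
                fy[k1] += f1y
                fz[k1] += f1z
    for k in range(n):
        i = order[k]
        fout[i, 0] = fx[k]
        fout[i, 1] = fy[k]
        fout[i, 2] = fz[k]


@njit(cache=True, fastmath=True, error_model='numpy')
def _nb_forces_brute(pos, vel, types, a, gamma, sig_dt, box, rcut, st, fout):
    """All-pairs fallback (minimum image, float64) for boxes < 3 cutoffs."""
    n = pos.shape[0]
    fout[:] = 0.0
    rcut2 = rcut * rcut
    inv_rcut = 1.0 / rcut
    half = 0.5 * box
    noise = sig_dt != 0.0
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            if dx > half:
                dx -= box
            elif dx < -half:
                dx += box
            if dy > half:
                dy -= box
            elif dy < -half:
                dy += box
            if dz > half:
                dz -= box
            elif dz < -half:
                dz += box
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rcut2 and r2 > 0.0:
                r = np.sqrt(r2)
                w = 1.0 - r * inv_rcut
                invr = 1.0 / r
                ex = dx * invr
                ey = dy * invr
                ez = dz * invr
                vde = ((vel[i, 0] - vel[j, 0]) * ex
                       + (vel[i, 1] - vel[j, 1]) * ey
                       + (vel[i, 2] - vel[j, 2]) * ez)
                fmag = w * (a[types[i], types[j]] - gamma * w * vde)
                if noise:
                    fmag += sig_dt * w * gauss(st)
                fout[i, 0] += fmag * ex
                fout[i, 1] += fmag * ey
                fout[i, 2] += fmag * ez
                fout[j, 0] -= fmag * ex
                fout[j, 1] -= fmag * ey
                fout[j, 2] -= fmag * ez


@njit(cache=True, fastmath=True, error_model='numpy')
def _spring_forces(pos, bonds, spring_c, box, fout):
    """Harmonic bond forces F = -C r_ij (minimum image), added to ``fout``.

    Returns the index of the first bond whose minimum-image length exceeds
    box/2 (minimum-image ambiguity), or -1 if all bonds are sound.
    """
    half = 0.5 * box
    lim2 = half * half
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if dx > half:
            dx -= box
        elif dx < -half:
            dx += box
        if dy > half:
            dy -= box
        elif dy < -half:
            dy += box
        if dz > half:
            dz -= box
        elif dz < -half:
            dz += box
        if dx * dx + dy * dy + dz * dz > lim2:
            return b
        fx = spring_c * dx
        fy = spring_c * dy
        fz = spring_c * dz
        fout[i, 0] -= fx
        fout[i, 1] -= fy
        fout[i, 2] -= fz
        fout[j, 0] += fx
        fout[j, 1] += fy
        fout[j, 2] += fz
    return -1


# ---------------------------------------------------------------------------
# integrator
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True, error_model='numpy')
def run_chunk(pos, vel, frc, types, a, gamma, sig_dt, bonds, spring_c,
              box, rcut, dt, lam, nsteps, st):
    """Advance ``nsteps`` modified velocity-Verlet steps in place.

    The scheme (Groot-Warren lambda form, one force evaluation per step):

        r <- r + dt v + dt^2/2 f
        v~ <- v + lam dt f
        f' <- F(r, v~)          (dissipative term uses the predicted v~)
        v <- v + dt/2 (f + f')

    ``frc`` must hold forces consistent with (pos, vel) on entry and holds
    the final forces on exit; ``st`` is the RNG state, advanced in place.
    Returns -1 on success, or the offending bond index if a bond exceeded
    half the box (integration blown up).
    """
    n = pos.shape[0]
    ncell = int(box / rcut)
    use_cells = ncell >= 3
    m = ncell * ncell * ncell if use_cells else 1
    cid = np.empty(n, np.int64)
    cstart = np.empty(m + 1, np.int64)
    order = np.empty(n, np.int64)
    pk = np.empty((n, 8), np.float32)
    fx = np.empty(n)
    fy = np.empty(n)
    fz = np.empty(n)
    vtil = np.empty((n, 3))
    fnew = np.empty((n, 3))
    if use_cells:
        nbr, shift = _neighbor_tables(ncell, box)
    else:
        nbr = np.empty((1, 13), np.int64)
        shift = np.empty((1, 13, 3), np.float32)
    a32 = a.astype(np.float32)
    gamma32 = np.float32(gamma)
    sigdt32 = np.float32(sig_dt)
    half_dt2 = 0.5 * dt * dt
    half_dt = 0.5 * dt
    lam_dt = lam * dt
    if nsteps <= 0:
        return -1
    # first position half-step; thereafter the velocity finalization of step
    # k is fused with the position advance of step k+1
    for i in range(n):
        for d in range(3):
            x = pos[i, d] + dt * vel[i, d] + half_dt2 * frc[i, d]
            if x >= box:
                x -= box
            elif x < 0.0:
                x += box
            pos[i, d] = x
            vtil[i, d] = vel[i, d] + lam_dt * frc[i, d]
    fa = frc
    fb = fnew
    in_caller = True
    for step in range(nsteps):
        if use_cells:
            _nb_forces_cells(pos, vtil, types, a32, gamma32, sigdt32, box,
                             rcut, ncell, nbr, shift, st, cid, cstart, order,
                             pk, fx, fy, fz, fb)
        else:
            _nb_forces_brute(pos, vtil, types, a, gamma, sig_dt, box, rcut,
                             st, fb)
        bad = _spring_forces(pos, bonds, spring_c, box, fb)
        if bad >= 0:
            return bad
        if step == nsteps - 1:
            for i in range(n):
                for d in range(3):
                    vel[i, d] += half_dt * (fa[i, d] + fb[i, d])
        else:
            for i in range(n):
                for d in range(3):
                    v = vel[i, d] + half_dt * (fa[i, d] + fb[i, d])
                    vel[i, d] = v
                    x = pos[i, d] + dt * v + half_dt2 * fb[i, d]
                    if x >= box:
                        x -= box
                    elif x < 0.0:
                        x += box
                    pos[i, d] = x
                    vtil[i, d] = v + lam_dt * fb[i, d]
        tmp = fa
        fa = fb
        fb = tmp
        in_caller = not in_caller
    if not in_caller:
        # final forces ended in the scratch buffer; restore caller's array
        for i in range(n):
            for d in range(3):
                frc[i, d] = fa[i, d]
    return -1


@njit(cache=True, fastmath=True, error_model='numpy')
def compute_forces(pos, vel, types, a, gamma, sig_dt, bonds, spring_c,
                   box, rcut, st, fout):
    """One full force evaluation (nonbonded + springs) into ``fout``.

    Returns -1, or the index of a bond violating the minimum-image limit.
    """
    n = pos.shape[0]
    ncell = int(box / rcut)
    if ncell >= 3:
        m = ncell * ncell * ncell
        cid = np.empty(n, np.int64)
        cstart = np.empty(m + 1, np.int64)
        order = np.empty(n, np.int64)
        pk = np.empty((n, 8), np.float32)
        fx = np.empty(n)
        fy = np.empty(n)
        fz = np.empty(n)
        nbr, shift = _neighbor_tables(ncell, box)
        _nb_forces_cells(pos, vel, types, a.astype(np.float32),
                         np.float32(gamma), np.float32(sig_dt), box, rcut,
                         ncell, nbr, shift, st, cid, cstart, order,
                         pk, fx, fy, fz, fout)
    else:
        _nb_forces_brute(pos, vel, types, a, gamma, sig_dt, box, rcut, st,
                         fout)
    return _spring_forces(pos, bonds, spring_c, box, fout)


# ---------------------------------------------------------------------------
# neighbor-pair enumeration (analysis/API use; exact float64 distances)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True, error_model='numpy')
def _collect_pairs_cells(pos, box, rcut, ncell, out_i, out_j, fill):
    """Enumerate pairs with minimum-image distance < rcut via cells.

    Returns the pair count; stores pairs when ``fill`` is True.
    """
    n = pos.shape[0]
    m = ncell * ncell * ncell
    cid = np.empty(n, np.int64)
    cstart = np.empty(m + 1, np.int64)
    order = np.empty(n, np.int64)
    _cell_sort(pos, box, ncell, cid, cstart, order)
    rcut2 = rcut * rcut
    count = 0
    for cx in range(ncell):
        for cy in range(ncell):
            for cz in range(ncell):
                c = (cx * ncell + cy) * ncell + cz
                c0 = cstart[c]
                c1 = cstart[c + 1]
                for k1 in range(c0, c1):
                    i = order[k1]
                    for k2 in range(k1 + 1, c1):
                        j = order[k2]
                        dx = pos[i, 0] - pos[j, 0]
                        dy = pos[i, 1] - pos[j, 1]
                        dz = pos[i, 2] - pos[j, 2]
                        if dx * dx + dy * dy + dz * dz < rcut2:
                            if fill:
                                out_i[count] = i
                                out_j[count] = j
                            count += 1
                for o in range(13):
                    nx = cx + _OFFSETS[o, 0]
                    sx = 0.0
                    if nx >= ncell:
                        nx -= ncell
                        sx = box
                    elif nx < 0:
                        nx += ncell
                        sx = -box
                    ny = cy + _OFFSETS[o, 1]
                    sy = 0.0
                    if ny >= ncell:
                        ny -= ncell
                        sy = box
                    elif ny < 0:
                        ny += ncell
                        sy = -box
                    nz = cz + _OFFSETS[o, 2]
                    sz = 0.0
                    if nz >= ncell:
                        nz -= ncell
                        sz = box
                    elif nz < 0:
                        nz += ncell
                        sz = -box
                    nc = (nx * ncell + ny) * ncell + nz
                    for k1 in range(c0, c1):
                        i = order[k1]
                        for k2 in range(cstart[nc], cstart[nc + 1]):
                            j = order[k2]
                            dx = pos[i, 0] - (pos[j, 0] + sx)
                            dy = pos[i, 1] - (pos[j, 1] + sy)
                            dz = pos[i, 2] - (pos[j, 2] + sz)
                            if dx * dx + dy * dy + dz * dz < rcut2:
                                if fill:
                                    out_i[count] = i
                                    out_j[count] = j
                                count += 1
    return count


@njit(cache=True, fastmath=True, error_model='numpy')
def _collect_pairs_brute(pos, box, rcut, out_i, out_j, fill):
    """All-pairs minimum-image pair enumeration (small-box fallback)."""
    n = pos.shape[0]
    half = 0.5 * box
    rcut2 = rcut * rcut
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            if dx > half:
                dx -= box
            elif dx < -half:
                dx += box
            if dy > half:
                dy -= box
            elif dy < -half:
                dy += box
            if dz > half:
                dz -= box
            elif dz < -half:
                dz += box
            if dx * dx + dy * dy + dz * dz < rcut2:
                if fill:
                    out_i[count] = i
                    out_j[count] = j
                count += 1
    return count
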
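"""Numba inner loops: Rosenbluth growth fused with on-the-fly accumulation.

Conformations are never stored: each sample is grown, its contact energy
evaluated against the fixed fields, and its Boltzmann-weighted contribution
``w * exp(-H)`` added to per-batch accumulators (free-energy layer sums,
per-monomer concentration histograms), all inside one jitted loop.

The RNG is the same counter-based splitmix64 scheme as
:mod:`copolyscan._rng`; sample ``k`` of a sequence draws from the substream
``mix64(seq_base + k * STRIDE)``, so results are independent of the order in
which sequences or samples are processed.
"""

import numpy as np
from numba import int64, njit, uint64

U_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
U_STRIDE = np.uint64(0xD1342543DE82EF95)
_C1 = np.uint64(0xBF58476D1CE4E5B9)
_C2 = np.uint64(0x94D049BB133111EB)


@njit(cache=True)
def _mix64(z):
    z = (z ^ (z >> np.uint64(30))) * _C1
    z = (z ^ (z >> np.uint64(27))) * _C2
    return z ^ (z >> np.uint64(31))


@njit(cache=True)
def _grow_chain(s0, n, Lx, Ly, Lz, bonds, pos, occ, free, x0=-1, y0=-1, z0=-1):
    """Grow one linear Rosenbluth chain into ``pos``/``occ``.

    The first monomer is uniform over the box, or pinned at (x0, y0, z0)
    when x0 >= 0.  Returns (weight, n_placed); weight is 0.0 on a dead end.
    The caller owns clearing ``occ`` afterwards.
    """
    state = s0
    if x0 >= 0:
        x = x0
        y = y0
        z = z0
    else:
        state = state + U_GOLDEN
        x = int64(_mix64(state) % uint64(Lx))
        state = state + U_GOLDEN
        y = int64(_mix64(state) % uint64(Ly))
        state = state + U_GOLDEN
        z = int64(_mix64(state) % uint64(Lz))
    pos[0, 0] = x
    pos[0, 1] = y
    pos[0, 2] = z
    occ[x, y, z] = 1
    w = 1.0
    for k in range(1, n):
        px = pos[k - 1, 0]
        py = pos[k - 1, 1]
        pz = pos[k - 1, 2]
        nf = 0
        for b in range(26):
            nz = pz + bonds[b, 2]
            if nz < 0 or nz >= Lz:
                continue
            nx = (px + bonds[b, 0]) % Lx
            ny = (py + bonds[b, 1]) % Ly
            if occ[nx, ny, nz] == 0:
                free[nf] = b
                nf += 1
        if nf == 0:
            return 0.0, k
        state = state + U_GOLDEN
        j = int64(_mix64(state) % uint64(nf))
        bb = free[j]
        nx = (px + bonds[bb, 0]) % Lx
        ny = (py + bonds[bb, 1]) % Ly
        nz = pz + bonds[bb, 2]
        pos[k, 0] = nx
        pos[k, 1] = ny
        pos[k, 2] = nz
        occ[nx, ny, nz] = 1
        w *= nf / 26.0
    return w, n


@njit(cache=True)
def planar_scan(types, eps, phi, Lx, Ly, Lz, bonds, n_samples, seq_base, n_batches):
    """Sample one sequence in a planar (z-layered) field stack.

    Accumulates, per batch, sum(w e^-H) binned by the chain's center-of-mass
    layer (ties at half-integers go to the lower bin) and the per-monomer
    layer concentration numerators.  Returns
    (acc[n_batches, Lz], conc[n_batches, n, Lz], counts[Lz], n_dead).
    """
    n = types.shape[0]
    occ = np.zeros((Lx, Ly, Lz), np.uint8)
    pos = np.empty((n, 3), np.int64)
    free = np.empty(26, np.int64)
    acc = np.zeros((n_batches, Lz))
    conc = np.zeros((n_batches, n, Lz))
    counts = np.zeros(Lz, np.int64)
    dead = 0
    for k in range(n_samples):
        s0 = _mix64(seq_base + uint64(k) * U_STRIDE)
        w, placed = _grow_chain(s0, n, Lx, Ly, Lz, bonds, pos, occ, free)
        batch = k * n_batches // n_samples
        if w > 0.0:
            h = 0.0
            zsum = 0
            for i in range(n):
                t = types[i]
                xi = pos[i, 0]
                yi = pos[i, 1]
                zi = pos[i, 2]
                zsum += zi
                for b in range(26):
                    nz = zi + bonds[b, 2]
                    if nz < 0 or nz >= Lz:
                        continue
                    nx = (xi + bonds[b, 0]) % Lx
                    ny = (yi + bonds[b, 1]) % Ly
                    if occ[nx, ny, nz] == 0:
                        h += (
                            eps[t, 0] * phi[0, nz]
                            + eps[t, 1] * phi[1, nz]
                            + eps[t, 2] * phi[2, nz]
                        )
            zbar = zsum / n
            bidx = int64(np.ceil(zbar - 0.5))
            boltz = w * np.exp(-h)
            acc[batch, bidx] += boltz
            counts[bidx] += 1
            for i in range(n):
                conc[batch, i, pos[i, 2]] += boltz
        else:
            dead += 1
        for i in range(placed):
            occ[pos[i, 0], pos[i, 1], pos[i, 2]] = 0
    return acc, conc, counts, dead


@njit(cache=True)
def radial_scan(
    types, eps, phi3, shells, n_shells, Lx, Ly, Lz, bonds, n_samples, seq_base, n_batches
):
    """Sample one sequence in a spherical field stack.

    Returns (zacc[n_batches], conc[n_batches, n, n_shells], n_dead) where
    zacc is the per-batch partition sum and conc the per-monomer, per-shell
    Boltzmann-weighted occupancy numerators.
    """
    n = types.shape[0]
    occ = np.zeros((Lx, Ly, Lz), np.uint8)
    pos = np.empty((n, 3), np.int64)
    free = np.empty(26, np.int64)
    zacc = np.zeros(n_batches)
    conc = np.zeros((n_batches, n, n_shells))
    dead = 0
    for k in range(n_samples):
        s0 = _mix64(seq_base + uint64(k) * U_STRIDE)
        w, placed = _grow_chain(s0, n, Lx, Ly, Lz, bonds, pos, occ, free)
        batch = k * n_batches // n_samples
        if w > 0.0:
            h = 0.0
            for i in range(n):
                t = types[i]
                xi = pos[i, 0]
                yi = pos[i, 1]
                zi = pos[i, 2]
                for b in range(26):
                    nz = zi + bonds[b, 2]
                    if nz < 0 or nz >= Lz:
                        continue
                    nx = (xi + bonds[b, 0]) % Lx
                    ny = (yi + bonds[b, 1]) % Ly
                    if occ[nx, ny, nz] == 0:
                        h += (
                            eps[t, 0] * phi3[0, nx, ny, nz]
                            + eps[t, 1] * phi3[1, nx, ny, nz]
                            + eps[t, 2] * phi3[2, nx, ny, nz]
                        )
            boltz = w * np.exp(-h)
            zacc[batch] += boltz
            for i in range(n):
                conc[batch, i, shells[pos[i, 0], pos[i, 1], pos[i, 2]]] += boltz
        else:
            dead += 1
        for i in range(placed):
            occ[pos[i, 0], pos[i, 1], pos[i, 2]] = 0
    return zacc, conc, dead


@njit(cache=True)
def radial_contact_samples(
    n, Lx, Ly, Lz, bonds, phi_p, shells, n_samples, seq_base, x0=-1, y0=-1, z0=-1
):
    """Grow chains and record, per sample and per monomer, the fractional
    contact counts against a radial density field and its solvent complement,
    plus each monomer's shell index.

    The first monomer is pinned at (x0, y0, z0) when x0 >= 0, else uniform.
    Returns (w[K], cp[K, n], cs[K, n], sh[K, n]); dead-end samples keep
    w = 0 and sh = -1.
    """
    occ = np.zeros((Lx, Ly, Lz), np.uint8)
    pos = np.empty((n, 3), np.int64)
    free = np.empty(26, np.int64)
    w_out = np.zeros(n_samples)
    cp = np.zeros((n_samples, n))
    cs = np.zeros((n_samples, n))
    sh = np.full((n_samples, n), -1, np.int64)
    for k in range(n_samples):
        s0 = _mix64(seq_base + uint64(k) * U_STRIDE)
        w, placed = _grow_chain(s0, n, Lx, Ly, Lz, bonds, pos, occ, free, x0, y0, z0)
        if w > 0.0:
            w_out[k] = w
            for i in range(n):
                xi = pos[i, 0]
                yi = pos[i, 1]
                zi = pos[i, 2]
                sh[k, i] = shells[xi, yi, zi]
                for b in range(26):
                    nz = zi + bonds[b, 2]
                    if nz < 0 or nz >= Lz:
                        continue
                    nx = (xi + bonds[b, 0]) % Lx
                    ny = (yi + bonds[b, 1]) % Ly
                    if occ[nx, ny, nz] == 0:
                        p = phi_p[nx, ny, nz]
                        cp[k, i] += p
                        cs[k, i] += 1.0 - p
        for i in range(placed):
            occ[pos[i, 0], pos[i, 1], pos[i, 2]] = 0
    return w_out, cp, cs, sh
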
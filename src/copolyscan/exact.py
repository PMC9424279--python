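"""Exhaustive enumeration of tiny self-avoiding chains (exact oracle).

For chain lengths of a few monomers in a small box every self-avoiding
placement can be enumerated outright.  Under Rosenbluth growth each
self-avoiding walk G is generated with probability (1/V) prod_k 1/n_free(k)
and carries weight w = prod_k n_free(k)/26, so w * P(G) = 1 / (V * 26^(N-1))
is the same for every walk: the sampled accumulator sum w e^-H estimates the
plain enumeration sum  (n_samples / (V 26^(N-1))) * sum_G e^-H.  That makes
the enumeration below an independent ground truth for the free-energy
profile, the concentration profile and the escape time, up to the known
additive constant returned by :func:`log_sampling_norm`.
"""

from __future__ import annotations

import math

import numpy as np

from .energy import InteractionMap
from .fields import FieldStack
from .lattice_model import BOND_VECTORS, Sequence, SimulationBox
from .observables import escape_time_from_free_energies

__all__ = [
    "enumerate_saw_coords",
    "exact_boltzmann",
    "exact_free_energy",
    "exact_concentration",
    "exact_escape_time",
    "log_sampling_norm",
]


def enumerate_saw_coords(n: int, box: SimulationBox) -> np.ndarray:
    """All self-avoiding n-site chains in the box, shape (M, n, 3).

    Coordinates are site indices (z-index in [0, Lz)); x, y are periodic,
    z is bounded.  Intended for n <= 4 in small boxes."""
    xs, ys, zs = np.meshgrid(
        np.arange(box.Lx), np.arange(box.Ly), np.arange(box.Lz), indexing="ij"
    )
    confs = np.stack([xs.ravel(), ys.ravel(), zs.ravel()], axis=1)[:, None, :]
    for _ in range(1, n):
        last = confs[:, -1, :]  # (M, 3)
        cand = last[:, None, :] + BOND_VECTORS[None, :, :]  # (M, 26, 3)
        ok = (cand[:, :, 2] >= 0) & (cand[:, :, 2] < box.Lz)
        cand[:, :, 0] %= box.Lx
        cand[:, :, 1] %= box.Ly
        for j in range(confs.shape[1]):
            ok &= ~np.all(cand == confs[:, j, :][:, None, :], axis=2)
        conf_idx, bond_idx = np.nonzero(ok)
        confs = np.concatenate(
            [confs[conf_idx], cand[conf_idx, bond_idx][:, None, :]], axis=1
        )
    return confs


def _neighbor_field_sums(grids: np.ndarray, box: SimulationBox) -> np.ndarray:
    """G[f, x, y, z] = sum over the 26 neighbors of (x,y,z) of phi_f there
    (neighbors outside the z-range contribute nothing)."""
    out = np.zeros_like(grids)
    for dx, dy, dz in BOND_VECTORS:
        shifted = np.roll(np.roll(grids, int(dx), axis=1), int(dy), axis=2)
        if dz == 0:
            out += shifted
        elif dz == 1:
            out[:, :, :, 1:] += shifted[:, :, :, :-1]
        else:
            out[:, :, :, :-1] += shifted[:, :, :, 1:]
    return out


def exact_boltzmann(
    seq: Sequence,
    stack: FieldStack,
    imap: InteractionMap | None = None,
    box: SimulationBox | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Enumerate all placements of ``seq`` and return (coords, e^-H).

    coords has shape (M, n, 3) in site indices; energies follow the contact
    Hamiltonian with self-occupied neighbor sites excluded."""
    box = box or stack.box
    imap = imap or InteractionMap.membrane_default()
    n = seq.n
    confs = enumerate_saw_coords(n, box)
    grids = stack.as_grids()
    gsum = _neighbor_field_sums(grids, box)
    types = seq.type_indices(imap.monomer_types)
    eps = imap.eps  # (n_types, 3)

    m = confs.shape[0]
    h = np.zeros(m)
    for i in range(n):
        xi, yi, zi = confs[:, i, 0], confs[:, i, 1], confs[:, i, 2]
        contact = gsum[:, xi, yi, zi]  # (3, M)
        for j in range(n):
            if j == i:
                continue
            dx = (confs[:, j, 0] - xi + box.Lx // 2) % box.Lx - box.Lx // 2
            dy = (confs[:, j, 1] - yi + box.Ly // 2) % box.Ly - box.Ly // 2
            dz = confs[:, j, 2] - zi
            adj = (
                (np.abs(dx) <= 1)
                & (np.abs(dy) <= 1)
                & (np.abs(dz) <= 1)
            )
            phi_j = grids[:, confs[:, j, 0], confs[:, j, 1], confs[:, j, 2]]
            contact = contact - np.where(adj[None, :], phi_j, 0.0)
        h += eps[types[i]] @ contact
    return confs, np.exp(-h)


def exact_free_energy(
    seq: Sequence,
    stack: FieldStack,
    imap: InteractionMap | None = None,
    box: SimulationBox | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact layer free energy (z relative to the mid-plane, F = -ln sum
    e^-H over chains whose center of mass falls in each layer bin)."""
    box = box or stack.box
    confs, boltz = exact_boltzmann(seq, stack, imap, box)
    zbar = confs[:, :, 2].mean(axis=1)
    bins = np.ceil(zbar - 0.5).astype(np.int64)
    sums = np.bincount(bins, weights=boltz, minlength=box.Lz)
    z = np.arange(box.z_min, box.z_min + box.Lz) - (
        stack.mid_plane if stack.mid_plane is not None else 0.0
    )
    with np.errstate(divide="ignore"):
        return z, -np.log(sums)


def exact_concentration(
    seq: Sequence,
    stack: FieldStack,
    imap: InteractionMap | None = None,
    box: SimulationBox | None = None,
) -> np.ndarray:
    """Exact per-monomer z-layer concentrations, shape (n, Lz); rows sum
    to 1."""
    box = box or stack.box
    confs, boltz = exact_boltzmann(seq, stack, imap, box)
    z_norm = boltz.sum()
    cbar = np.zeros((seq.n, box.Lz))
    for i in range(seq.n):
        cbar[i] = np.bincount(confs[:, i, 2], weights=boltz, minlength=box.Lz)
    return cbar / z_norm


def exact_escape_time(
    seq: Sequence,
    stack: FieldStack,
    imap: InteractionMap | None = None,
    box: SimulationBox | None = None,
) -> float:
    """Escape time from the exact free-energy profile (shift-invariant, so
    directly comparable with the sampled estimate)."""
    _, f = exact_free_energy(seq, stack, imap, box)
    return escape_time_from_free_energies(f)


def log_sampling_norm(n: int, box: SimulationBox, n_samples: int) -> float:
    """ln of the factor relating the sampled accumulator to the enumeration
    sum: F_exact = F_sampled + ln(n_samples / (V * 26^(n-1)))."""
    return math.log(n_samples) - math.log(box.n_sites) - (n - 1) * math.log(26.0)
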
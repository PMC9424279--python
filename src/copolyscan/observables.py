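"""Estimators over weighted conformation streams.

All observables are Boltzmann averages over Rosenbluth-weighted samples,

    <X> = sum_G w_G e^{-H(G)} X(G) / sum_G w_G e^{-H(G)},

accumulated streamingly (no conformation storage).  The module provides:

* the layer free-energy profile F(z) = -ln sum_bin w e^-H (in kBT), binned by
  the chain center of mass relative to the membrane mid-plane;
* the Kramers-type mean first escape time over F(z), a double sum with
  dz = 1 in units of lattice^2 / self-diffusion constant;
* per-monomer mean concentration profiles and the localization score
  theta_MD used to rank sequences against a spherical target region;
* a two-state hydrogen-bond annealing search (all block assignments of fixed
  composition, Boltzmann-weighted against a radial density field);
* radial branch-point distributions of branched ensembles.

Statistical errors come from batch means over >= 20 batches throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, groupby
from typing import Iterable, Sequence as TypingSequence

import numpy as np

from . import _kernels
from ._rng import stream_seed
from .energy import InteractionMap
from .fields import DensityProfile, FieldStack
from .lattice_model import BOND_VECTORS, Conformation, SimulationBox

__all__ = [
    "FreeEnergyProfile",
    "free_energy_profile",
    "EscapeTimeResult",
    "mean_escape_time",
    "escape_time_from_free_energies",
    "BarrierResult",
    "barrier_height",
    "effective_coordination",
    "ConcentrationProfile",
    "monomer_concentration",
    "LocalizationCriterion",
    "localization_score",
    "HBondProfile",
    "hbond_anneal",
    "BranchProfile",
    "branch_point_profile",
]


def com_bin(zbar: float) -> int:
    """Integer layer bin with |zbar - z| < 1/2; ties at exactly 1/2 go to
    the lower bin."""
    return int(math.ceil(zbar - 0.5))


@dataclass
class FreeEnergyProfile:
    """Layer free energy F(z) = -ln sum_bin w e^-H, in kBT.

    ``z`` holds the bin centers relative to the membrane mid-plane; ``sums``
    the accumulated Boltzmann sums per bin, ``batch_sums`` their split over
    batches (for standard errors), ``counts`` the raw samples per bin.
    ``empty_bin`` controls bins with zero accumulated weight: "error" (the
    default) raises naming the bin, "inf" reports F = +inf there.
    """

    z: np.ndarray
    sums: np.ndarray
    counts: np.ndarray
    batch_sums: np.ndarray | None = None
    empty_bin: str = "error"

    @property
    def f(self) -> np.ndarray:
        out = np.full_like(self.sums, np.inf)
        pos = self.sums > 0
        if not pos.all():
            if self.empty_bin == "error":
                bad = self.z[~pos]
                raise ValueError(f"empty free-energy bin(s) at z = {bad.tolist()}")
        out[pos] = -np.log(self.sums[pos])
        return out

    @property
    def f_stderr(self) -> np.ndarray:
        """Per-bin standard error of F from batch means (delta method)."""
        if self.batch_sums is None:
            return np.full_like(self.sums, np.nan)
        b = self.batch_sums.shape[0]
        mean = self.batch_sums.mean(axis=0)
        sd = self.batch_sums.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(mean > 0, sd / mean / math.sqrt(b), np.nan)

    @classmethod
    def from_accumulators(
        cls,
        batch_acc: np.ndarray,
        counts: np.ndarray,
        box: SimulationBox,
        mid_plane: float,
        empty_bin: str = "error",
    ) -> "FreeEnergyProfile":
        z = np.arange(box.z_min, box.z_min + box.Lz) - mid_plane
        return cls(
            z=z,
            sums=batch_acc.sum(axis=0),
            counts=np.asarray(counts),
            batch_sums=np.asarray(batch_acc, dtype=float),
            empty_bin=empty_bin,
        )

    def shifted(self, const: float) -> "FreeEnergyProfile":
        """The profile with F -> F + const (H -> H + const on every sample)."""
        factor = math.exp(-const)
        return FreeEnergyProfile(
            z=self.z,
            sums=self.sums * factor,
            counts=self.counts,
            batch_sums=None if self.batch_sums is None else self.batch_sums * factor,
            empty_bin=self.empty_bin,
        )


def free_energy_profile(
    stream: Iterable[tuple[Conformation, float, float]],
    box: SimulationBox,
    mid_plane: float = 0.0,
    n_batches: int = 20,
    empty_bin: str = "error",
) -> FreeEnergyProfile:
    """Accumulate F(z) from a stream of (conformation, weight, energy).

    Each conformation joins the unique bin with |zbar - z| < 1/2, zbar being
    the mean monomer z-coordinate; zero-weight (dead-end) entries are counted
    but contribute nothing.
    """
    acc = np.zeros((n_batches, box.Lz))
    counts = np.zeros(box.Lz, dtype=np.int64)
    k = 0
    for conf, w, h in stream:
        if w > 0:
            zbar = float(conf.coords[:, 2].mean())
            bidx = com_bin(zbar) - box.z_min
            acc[k % n_batches, bidx] += w * math.exp(-h)
            counts[bidx] += 1
        k += 1
    if k == 0:
        raise ValueError("empty conformation stream")
    return FreeEnergyProfile.from_accumulators(acc, counts, box, mid_plane, empty_bin)


@dataclass
class EscapeTimeResult:
    """Mean first escape time over a free-energy profile (units of
    lattice^2 / self-diffusion constant).  Invariant under F -> F + const."""

    tau: float
    z_minus: float
    z_plus: float
    log_tau_stderr: float = float("nan")
    sequence: str | None = None
    n_samples: int | None = None
    seed: int | None = None


def escape_time_from_free_energies(f: np.ndarray) -> float:
    """Discrete Kramers double sum: tau = sum_z e^{F(z)} sum_{z' <= z}
    e^{-F(z')}, dz = 1, computed relative to the profile midrange for
    overflow control."""
    f = np.asarray(f, dtype=float)
    if f.size == 0 or not np.all(np.isfinite(f)):
        raise ValueError("escape time needs a finite free-energy profile")
    f0 = (f.max() + f.min()) / 2.0
    up = np.exp(f - f0)
    down = np.exp(-(f - f0))
    return float(np.sum(up * np.cumsum(down)))


def mean_escape_time(profile: FreeEnergyProfile) -> EscapeTimeResult:
    """Mean first escape time between the bottom and top box layers."""
    tau = escape_time_from_free_energies(profile.f)
    se = float("nan")
    if profile.batch_sums is not None:
        taus = []
        for row in profile.batch_sums:
            if np.all(row > 0):
                taus.append(math.log(escape_time_from_free_energies(-np.log(row))))
        if len(taus) >= 2:
            se = float(np.std(taus, ddof=1) / math.sqrt(len(taus)))
    return EscapeTimeResult(
        tau=tau,
        z_minus=float(profile.z[0]),
        z_plus=float(profile.z[-1]),
        log_tau_stderr=se,
        n_samples=int(profile.counts.sum()),
    )


@dataclass
class BarrierResult:
    """Desorption barrier: solvent-plateau free energy minus the global
    minimum of F(z), in kBT."""

    barrier: float
    plateau: float
    minimum: float
    n_plateau_bins: int


def barrier_height(
    profile: FreeEnergyProfile, plateau_band: tuple[float, float] = (8.5, 12.5)
) -> BarrierResult:
    """Estimate the barrier as mean F over the solvent plateau (bins with
    |z| inside ``plateau_band``, clear of both the head groups and the box
    walls) minus the global minimum of F."""
    f = profile.f
    sel = (np.abs(profile.z) >= plateau_band[0]) & (np.abs(profile.z) <= plateau_band[1])
    if not sel.any():
        raise ValueError("plateau band selects no bins")
    plateau = float(f[sel].mean())
    fmin = float(f.min())
    return BarrierResult(plateau - fmin, plateau, fmin, int(sel.sum()))


def effective_coordination(
    barrier: float, eps_contact: float = 0.1, block_length: int = 12
) -> float:
    """Effective number of realized solvent contacts per hydrophobic monomer
    implied by a desorption barrier: z_eff = F_barrier / (eps * N_T)."""
    return barrier / (eps_contact * block_length)


@dataclass
class ConcentrationProfile:
    """Boltzmann-averaged per-monomer layer concentrations C_i(layer).

    ``layers`` are z-relative layer centers (planar) or shell indices
    (spherical); rows of ``cbar`` sum to 1 for every monomer (each
    conformation puts each monomer in exactly one layer)."""

    layers: np.ndarray
    cbar: np.ndarray  # (n_monomers, n_layers)
    z_norm: float
    batch_numerators: np.ndarray | None = None  # (B, n, n_layers)
    batch_z: np.ndarray | None = None  # (B,)
    n_dead: int | None = None

    @property
    def n_monomers(self) -> int:
        return self.cbar.shape[0]

    @classmethod
    def from_accumulators(cls, batch_conc, batch_z, layers) -> "ConcentrationProfile":
        batch_conc = np.asarray(batch_conc, dtype=float)
        batch_z = np.asarray(batch_z, dtype=float)
        z = batch_z.sum()
        if z <= 0:
            raise ValueError("zero total Boltzmann weight; no usable samples")
        return cls(
            layers=np.asarray(layers),
            cbar=batch_conc.sum(axis=0) / z,
            z_norm=float(z),
            batch_numerators=batch_conc,
            batch_z=batch_z,
        )


def _shell_index(coords: np.ndarray, box: SimulationBox) -> np.ndarray:
    cx, cy, cz = box.center()
    # coords carry absolute z; the center's z-index shifts by z_min
    d = coords - np.array([cx, cy, cz + box.z_min])
    return np.floor(np.sqrt((d * d).sum(axis=1))).astype(np.int64)


def monomer_concentration(
    stream: Iterable[tuple[Conformation, float, float]],
    box: SimulationBox,
    geometry: str = "planar-z",
    mid_plane: float = 0.0,
    n_batches: int = 20,
) -> ConcentrationProfile:
    """Accumulate C_i from a stream of (conformation, weight, energy);
    layers are z layers (planar) or radial shells floor(r) (spherical)."""
    first = None
    acc = None
    batch_z = np.zeros(n_batches)
    k = 0
    if geometry == "planar-z":
        n_layers = box.Lz
        layers = np.arange(box.z_min, box.z_min + box.Lz) - mid_plane
    elif geometry == "spherical-r":
        corner = np.array([box.Lx, box.Ly, box.Lz]) / 2
        n_layers = int(np.floor(np.sqrt((corner**2).sum()))) + 1
        layers = np.arange(n_layers)
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    for conf, w, h in stream:
        if first is None:
            first = conf.n
            acc = np.zeros((n_batches, first, n_layers))
        if w > 0:
            boltz = w * math.exp(-h)
            b = k % n_batches
            batch_z[b] += boltz
            if geometry == "planar-z":
                idx = conf.coords[:, 2] - box.z_min
            else:
                idx = _shell_index(conf.coords.astype(float), box)
            for i in range(conf.n):
                acc[b, i, idx[i]] += boltz
        k += 1
    if first is None:
        raise ValueError("empty conformation stream")
    return ConcentrationProfile.from_accumulators(acc, batch_z, layers)


@dataclass(frozen=True)
class LocalizationCriterion:
    """Target region for theta_MD: a set of monomer indices (1-based) that
    should sit in the open radial interval (r_lo, r_hi)."""

    indices: tuple[int, ...]
    r_lo: float
    r_hi: float

    def __post_init__(self):
        if len(self.indices) == 0:
            raise ValueError("the localization criterion needs at least one monomer")
        if any(i < 1 for i in self.indices):
            raise ValueError("monomer indices are 1-based")
        if not self.r_lo < self.r_hi:
            raise ValueError("the radial interval needs r_lo < r_hi")

    def shell_mask(self, n_shells: int) -> np.ndarray:
        """Shells [s, s+1) overlapping the open interval (r_lo, r_hi)."""
        s = np.arange(n_shells)
        return (s < self.r_hi) & (s + 1 > self.r_lo)


def localization_score(conc: ConcentrationProfile, crit: LocalizationCriterion) -> float:
    """theta_MD = sum_{i in M} sum_{shells in D} C_i(shell); bounded by |M|."""
    idx = np.array(crit.indices) - 1
    if idx.max() >= conc.n_monomers:
        raise ValueError("criterion indices exceed the chain length")
    mask = crit.shell_mask(conc.cbar.shape[1])
    return float(conc.cbar[np.ix_(idx, np.flatnonzero(mask))].sum())


# ---------------------------------------------------------------------------
# Two-state hydrogen bonding


@dataclass
class HBondProfile:
    """Annealed H-bond statistics of a two-state chain in a radial density
    field: per-position bond probability, per-shell bond fraction, and the
    block-size frequency f(s) = f_HB(s) / (f_HB(s) + f_noHB(s))."""

    position_prob: np.ndarray
    shells: np.ndarray
    layer_fraction: np.ndarray
    layer_fraction_se: np.ndarray
    layer_weight: np.ndarray
    block_sizes: np.ndarray
    block_freq: np.ndarray

    @property
    def mean_fraction(self) -> float:
        return float(self.position_prob.mean())


def _block_counts(states: TypingSequence[int], n: int) -> tuple[np.ndarray, np.ndarray]:
    hb = np.zeros(n, dtype=np.int64)
    no = np.zeros(n, dtype=np.int64)
    for state, run in groupby(states):
        size = sum(1 for _ in run)
        (hb if state else no)[size - 1] += 1
    return hb, no


def hbond_anneal(
    profile: DensityProfile,
    n: int = 16,
    hb_fraction: float = 0.5,
    imap: InteractionMap | None = None,
    box: SimulationBox | None = None,
    samples: int = 20000,
    seed: int = 0,
    n_batches: int = 20,
    chunk: int = 512,
    anchor: str = "center",
) -> HBondProfile:
    """Anneal the positions of the H-bonded blocks of a two-state chain.

    The composition is fixed (``hb_fraction`` of the ``n`` monomers carry a
    bond); every C(n, n_HB) assignment is enumerated exactly and weighted by
    sum_G w_G e^{-H(assignment, G)} over a shared sample of conformations in
    the radial density field ``profile``.

    The chain represents a chain *of* the globule whose own concentration it
    feels, so by default its first monomer is anchored at the field center
    and the chain radiates across the density gradient; ``anchor="uniform"``
    instead samples free chains uniformly over the box.
    """
    m = hb_fraction * n
    if abs(m - round(m)) > 1e-9:
        raise ValueError(f"hb_fraction * n = {m} must be an integer")
    m = int(round(m))
    imap = imap or InteractionMap.hbond_default()
    box = box or SimulationBox()
    e_hb_p = imap.get("HB", "P")
    e_hb_s = imap.get("HB", "S")
    e_no_p = imap.get("NOHB", "P")
    e_no_s = imap.get("NOHB", "S")

    phi = profile.to_grid(box)
    cx, cy, cz = box.center()
    x = np.arange(box.Lx)[:, None, None] - cx
    y = np.arange(box.Ly)[None, :, None] - cy
    z = np.arange(box.Lz)[None, None, :] - cz
    shells3d = np.floor(np.sqrt(x * x + y * y + z * z)).astype(np.int64)
    n_shells = int(shells3d.max()) + 1

    if anchor == "center":
        x0, y0, z0 = (box.Lx - 1) // 2, (box.Ly - 1) // 2, (box.Lz - 1) // 2
    elif anchor == "uniform":
        x0 = y0 = z0 = -1
    else:
        raise ValueError(f"anchor must be 'center' or 'uniform', got {anchor!r}")
    base = stream_seed(seed, f"hbond:{n}:{m}")
    w, cp, cs, sh = _kernels.radial_contact_samples(
        n, box.Lx, box.Ly, box.Lz, BOND_VECTORS, phi, shells3d, samples,
        np.uint64(base), x0, y0, z0,
    )

    assignments = list(combinations(range(n), m))
    a_mat = np.zeros((len(assignments), n))
    for j, pos in enumerate(assignments):
        a_mat[j, list(pos)] = 1.0
    hb_blocks = np.zeros((len(assignments), n), dtype=np.int64)
    no_blocks = np.zeros((len(assignments), n), dtype=np.int64)
    for j in range(len(assignments)):
        hb_blocks[j], no_blocks[j] = _block_counts(a_mat[j].astype(int), n)

    pos_acc = np.zeros(n)
    pa_acc = np.zeros(len(assignments))
    num_b = np.zeros((n_batches, n_shells))
    den_b = np.zeros((n_batches, n_shells))
    z_total = 0.0

    # energy per (assignment, conformation) decomposes over positions:
    # state HB contributes e_hb_p*cp + e_hb_s*cs, state NOHB the complement.
    x_hb = e_hb_p * cp + e_hb_s * cs  # (K, n)
    x_no = e_no_p * cp + e_no_s * cs
    for b in range(n_batches):
        lo = b * samples // n_batches
        hi = (b + 1) * samples // n_batches
        for g0 in range(lo, hi, chunk):
            g1 = min(g0 + chunk, hi)
            sel = slice(g0, g1)
            live = w[sel] > 0
            if not live.any():
                continue
            wg = w[sel][live]
            e = a_mat @ x_hb[sel][live].T + (1.0 - a_mat) @ x_no[sel][live].T
            wag = wg[None, :] * np.exp(-e)  # (n_assign, k)
            tg = wag.sum(axis=0)
            gg = a_mat.T @ wag  # (n, k)
            z_total += tg.sum()
            pos_acc += gg.sum(axis=1)
            pa_acc += wag.sum(axis=1)
            sh_g = sh[sel][live]
            for i in range(n):
                num_b[b] += np.bincount(sh_g[:, i], weights=gg[i], minlength=n_shells)
                den_b[b] += np.bincount(sh_g[:, i], weights=tg, minlength=n_shells)
    if z_total <= 0:
        raise ValueError("zero total Boltzmann weight; no usable samples")

    num = num_b.sum(axis=0)
    den = den_b.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(den > 0, num / den, np.nan)
        frac_batches = np.where(den_b > 0, num_b / den_b, np.nan)
    import warnings

    with warnings.catch_warnings(), np.errstate(invalid="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        n_ok = np.sum(~np.isnan(frac_batches), axis=0)
        se = np.nanstd(frac_batches, axis=0, ddof=1) / np.sqrt(np.maximum(n_ok, 1))
        se = np.where(n_ok >= 2, se, np.nan)

    p_a = pa_acc / z_total
    e_hb_size = p_a @ hb_blocks
    e_no_size = p_a @ no_blocks
    tot = e_hb_size + e_no_size
    with np.errstate(divide="ignore", invalid="ignore"):
        block_freq = np.where(tot > 0, e_hb_size / tot, np.nan)

    return HBondProfile(
        position_prob=pos_acc / z_total,
        shells=np.arange(n_shells),
        layer_fraction=frac,
        layer_fraction_se=se,
        layer_weight=den,
        block_sizes=np.arange(1, n + 1),
        block_freq=block_freq,
    )


# ---------------------------------------------------------------------------
# Branched ensembles


@dataclass
class BranchProfile:
    """Normalized radial distributions of branch points and of all monomers
    for an ensemble of branched conformations."""

    shells: np.ndarray
    branch_density: np.ndarray
    monomer_density: np.ndarray
    n_branch_points: int
    total_weight: float


def branch_point_profile(
    ensemble: Iterable[Conformation],
    box: SimulationBox,
    weights: Iterable[float] | None = None,
) -> BranchProfile:
    """Weighted radial histograms of branch-point and monomer positions.

    ``weights`` defaults to each conformation's Rosenbluth weight; pass
    ``w * exp(-H)`` values for field-coupled ensembles."""
    ensemble = list(ensemble)
    if not ensemble:
        raise ValueError("empty ensemble")
    if weights is None:
        weights = [c.weight for c in ensemble]
    weights = list(weights)
    corner = np.array([box.Lx, box.Ly, box.Lz]) / 2
    n_shells = int(np.floor(np.sqrt((corner**2).sum()))) + 1
    branch_hist = np.zeros(n_shells)
    mono_hist = np.zeros(n_shells)
    n_bp = 0
    total_w = 0.0
    for conf, wt in zip(ensemble, weights):
        if wt <= 0:
            continue
        total_w += wt
        shells = _shell_index(conf.coords.astype(float), box)
        np.add.at(mono_hist, shells, wt)
        bps = conf.topology_or_linear().branch_points()
        n_bp += len(bps)
        for i in bps:
            branch_hist[shells[i]] += wt
    if total_w <= 0:
        raise ValueError("ensemble has zero total weight")
    b_sum = branch_hist.sum()
    return BranchProfile(
        shells=np.arange(n_shells),
        branch_density=branch_hist / b_sum if b_sum > 0 else branch_hist,
        monomer_density=mono_hist / mono_hist.sum(),
        n_branch_points=n_bp,
        total_weight=total_w,
    )
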
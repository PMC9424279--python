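"""Cubic lattice, sequence space, and Rosenbluth growth of self-avoiding walks.

Chains live on a simple cubic lattice with a 26-vector bond set (all nonzero
vectors with components in {-1, 0, +1}), so bonded monomers are "touching
cubes".  The box is periodic in x and y and hard-walled in z; a growth
attempt outside the z-range counts as a blocked site.  Conformations are
generated by Rosenbluth chain growth: each monomer is placed uniformly among
the unoccupied neighbor sites of its parent and the conformation carries the
weight

    w = prod_k  n_free(k) / 26,

the product of normalized free "atmospheres", which removes the growth bias
when conformations are averaged as ``sum_G w_G X(G)``.  A dead end (no free
neighbor) yields a valid zero-weight conformation that stays in the sample
count, keeping the estimator unbiased.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterator

import numpy as np

from ._rng import SplitMix64, sample_state, stream_seed

__all__ = [
    "BOND_VECTORS",
    "bond_vectors",
    "SimulationBox",
    "Sequence",
    "Topology",
    "Conformation",
    "canonical_form",
    "enumerate_sequences",
    "count_sequences",
    "grow_linear",
    "grow_branched",
]

#: The 26 bond vectors (1,0,0)/(1,1,0)/(1,1,1) with all permutations and
#: sign changes, in a fixed deterministic order shared with the numba kernels.
BOND_VECTORS = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ],
    dtype=np.int64,
)


def bond_vectors() -> frozenset[tuple[int, int, int]]:
    """The bond set as a frozen set of (dx, dy, dz) tuples (26 entries)."""
    return frozenset(map(tuple, BOND_VECTORS.tolist()))


@dataclass(frozen=True)
class SimulationBox:
    """Lattice box: periodic in x and y, bounded in z.

    ``z_min``/``z_max`` are absolute layer coordinates (z_max is derived,
    ``z_min + Lz - 1``).  The default 32-layer height matches a free-diffusion
    escape time tau ~ |2 z|^2 ~ 1e3.
    """

    Lx: int = 32
    Ly: int = 32
    Lz: int = 32
    z_min: int = -16

    def __post_init__(self):
        if min(self.Lx, self.Ly, self.Lz) < 1:
            raise ValueError("box dimensions must be positive integers")

    @property
    def z_max(self) -> int:
        return self.z_min + self.Lz - 1

    @property
    def n_sites(self) -> int:
        return self.Lx * self.Ly * self.Lz

    def contains_z(self, z: int) -> bool:
        return self.z_min <= z <= self.z_max

    def center(self) -> tuple[float, float, float]:
        """Geometric center in site coordinates (x, y, z-index)."""
        return ((self.Lx - 1) / 2, (self.Ly - 1) / 2, (self.Lz - 1) / 2)


@dataclass(frozen=True)
class Sequence:
    """An ordered monomer pattern over the {T (hydrophobic), H (hydrophilic)}
    alphabet (extensible to other labels)."""

    labels: tuple[str, ...]

    def __post_init__(self):
        if len(self.labels) < 1:
            raise ValueError("a sequence needs at least one monomer")

    @classmethod
    def from_string(cls, s: str) -> "Sequence":
        return cls(tuple(s))

    def to_string(self) -> str:
        return "".join(self.labels)

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def n_tail(self) -> int:
        """Number of hydrophobic (T) monomers."""
        return sum(1 for c in self.labels if c == "T")

    @property
    def n_head(self) -> int:
        """Number of hydrophilic (H) monomers."""
        return sum(1 for c in self.labels if c == "H")

    def type_indices(self, alphabet: tuple[str, ...] = ("T", "H")) -> np.ndarray:
        """Map labels onto integer type codes in the order of ``alphabet``."""
        lut = {c: i for i, c in enumerate(alphabet)}
        try:
            return np.array([lut[c] for c in self.labels], dtype=np.int8)
        except KeyError as e:  # pragma: no cover - defensive
            raise ValueError(f"label {e.args[0]!r} not in alphabet {alphabet}") from e

    def reversed(self) -> "Sequence":
        return Sequence(self.labels[::-1])


def canonical_form(seq: Sequence) -> Sequence:
    """Representative of the reversal-equivalence class: the lexicographically
    smaller of the sequence and its reversal ('H' < 'T')."""
    s = seq.to_string()
    return Sequence.from_string(min(s, s[::-1]))


def count_sequences(n: int, n_tail: int, dedupe_reversal: bool = False) -> int:
    """Number of distinct patterns of composition ``n_tail``/``n``:
    n!/(n_T! n_H!), or the number of reversal classes when deduping
    (Burnside: (C + #palindromes) / 2)."""
    if not 0 <= n_tail <= n:
        raise ValueError(f"invalid composition: n_tail={n_tail} not in [0, {n}]")
    total = math.comb(n, n_tail)
    if not dedupe_reversal:
        return total
    half = n // 2
    if n % 2 == 0:
        pal = math.comb(half, n_tail // 2) if n_tail % 2 == 0 else 0
    else:
        # middle monomer absorbs the parity of the T count
        pal = math.comb(half, n_tail // 2)
    return (total + pal) // 2


def enumerate_sequences(
    n: int, n_tail: int, dedupe_reversal: bool = False
) -> tuple[Iterator[Sequence], int]:
    """Lazy stream over all patterns with ``n_tail`` T monomers out of ``n``,
    plus the total count.

    Without deduping every ordering appears exactly once (lexicographic in the
    positions of the T monomers); with ``dedupe_reversal`` one canonical
    representative per reversal class is yielded.
    """
    count = count_sequences(n, n_tail, dedupe_reversal)

    def gen() -> Iterator[Sequence]:
        for tails in combinations(range(n), n_tail):
            labels = ["H"] * n
            for i in tails:
                labels[i] = "T"
            s = "".join(labels)
            if dedupe_reversal and s > s[::-1]:
                continue
            yield Sequence.from_string(s)

    return gen(), count


@dataclass(frozen=True)
class Topology:
    """Connectivity tree: ``parents[i]`` is the parent monomer of i (root -1).

    ``functionality`` records, per branch point, the number of child branches
    its branching draw assigned (the realized child count can be smaller if
    the monomer budget ran out).
    """

    parents: tuple[int, ...]
    functionality: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.parents[0] != -1:
            raise ValueError("monomer 0 must be the root (parent -1)")
        for i, p in enumerate(self.parents[1:], start=1):
            if not 0 <= p < i:
                raise ValueError(f"parent of monomer {i} must precede it, got {p}")

    @classmethod
    def linear(cls, n: int) -> "Topology":
        return cls(tuple(range(-1, n - 1)))

    @property
    def n(self) -> int:
        return len(self.parents)

    def children(self) -> list[list[int]]:
        kids: list[list[int]] = [[] for _ in range(self.n)]
        for i, p in enumerate(self.parents):
            if p >= 0:
                kids[p].append(i)
        return kids

    @property
    def is_linear(self) -> bool:
        return all(len(c) <= 1 for c in self.children())

    def branch_points(self) -> tuple[int, ...]:
        """Monomers whose branching draw fired during growth."""
        return tuple(sorted(self.functionality))


@dataclass
class Conformation:
    """A grown chain: sites per monomer plus its Rosenbluth weight.

    ``coords[i] = (x, y, z)`` with x, y in [0, L) and z an absolute layer in
    [z_min, z_max].  ``weight == 0`` iff growth dead-ended, in which case only
    the first ``n_placed`` rows are meaningful.
    """

    sequence: Sequence
    coords: np.ndarray
    weight: float
    topology: Topology | None = None
    n_placed: int | None = None

    @property
    def n(self) -> int:
        return self.sequence.n

    def topology_or_linear(self) -> Topology:
        return self.topology if self.topology is not None else Topology.linear(self.n)

    def validate(self, box: SimulationBox) -> None:
        """Assert excluded volume and the 26-vector bond constraint
        (periodic in x, y).  Raises ``ValueError`` on violation."""
        n = self.n if self.weight > 0 else (self.n_placed or 0)
        coords = self.coords[:n]
        occupied = set(map(tuple, coords.tolist()))
        if len(occupied) != n:
            raise ValueError("excluded volume violated: duplicate site")
        for z in coords[:, 2]:
            if not box.contains_z(int(z)):
                raise ValueError(f"site outside z-range: z={z}")
        parents = self.topology_or_linear().parents
        bonds = bond_vectors()
        for i in range(1, n):
            p = parents[i]
            dx = (coords[i, 0] - coords[p, 0] + box.Lx // 2) % box.Lx - box.Lx // 2
            dy = (coords[i, 1] - coords[p, 1] + box.Ly // 2) % box.Ly - box.Ly // 2
            dz = coords[i, 2] - coords[p, 2]
            if (int(dx), int(dy), int(dz)) not in bonds:
                raise ValueError(f"bond {p}->{i} not in the 26-vector set")


class _Grower:
    """Shared Rosenbluth placement machinery for the pure-Python growers."""

    def __init__(self, box: SimulationBox, rng: SplitMix64):
        self.box = box
        self.rng = rng
        self.occupied: set[tuple[int, int, int]] = set()
        self.coords: list[tuple[int, int, int]] = []
        self.weight = 1.0
        self.dead = False

    def place_first(self, start: tuple[int, int, int] | None) -> None:
        if start is None:
            x = self.rng.below(self.box.Lx)
            y = self.rng.below(self.box.Ly)
            z = self.rng.below(self.box.Lz)
        else:
            x, y, z = start[0], start[1], start[2] - self.box.z_min
        site = (x, y, z)
        self.occupied.add(site)
        self.coords.append(site)

    def place_child(self, parent_index: int) -> int | None:
        """Place one monomer adjacent to ``parent_index``; returns its index
        or None on a dead end (weight becomes 0)."""
        px, py, pz = self.coords[parent_index]
        free = []
        for b in range(26):
            dx, dy, dz = BOND_VECTORS[b]
            nz = pz + int(dz)
            if not 0 <= nz < self.box.Lz:
                continue
            site = ((px + int(dx)) % self.box.Lx, (py + int(dy)) % self.box.Ly, nz)
            if site not in self.occupied:
                free.append(site)
        if not free:
            self.weight = 0.0
            self.dead = True
            return None
        site = free[self.rng.below(len(free))]
        self.weight *= len(free) / 26.0
        self.occupied.add(site)
        self.coords.append(site)
        return len(self.coords) - 1

    def finish(self, sequence: Sequence, topology: Topology | None) -> Conformation:
        n = sequence.n
        coords = np.zeros((n, 3), dtype=np.int64)
        for i, (x, y, z) in enumerate(self.coords):
            coords[i] = (x, y, z + self.box.z_min)
        return Conformation(
            sequence=sequence,
            coords=coords,
            weight=self.weight,
            topology=topology,
            n_placed=len(self.coords),
        )


def grow_linear(
    sequence: Sequence,
    box: SimulationBox = SimulationBox(),
    seed: int = 0,
    sample_index: int = 0,
    start: tuple[int, int, int] | None = None,
) -> Conformation:
    """Grow one linear Rosenbluth conformation.

    The first monomer is uniform over the box (or pinned at ``start``, given
    in absolute coordinates, for tests); each next monomer is uniform over
    the unoccupied 26-neighborhood of its predecessor.  ``(seed,
    sample_index)`` selects the deterministic substream; the stream is
    identical to the one consumed by the scan kernels.
    """
    rng = SplitMix64(sample_state(stream_seed(seed, sequence.to_string()), sample_index))
    g = _Grower(box, rng)
    g.place_first(start)
    for _ in range(1, sequence.n):
        if g.place_child(len(g.coords) - 1) is None:
            break
    return g.finish(sequence, None)


def grow_branched(
    n: int,
    theta: float,
    f: int = 2,
    box: SimulationBox = SimulationBox(),
    seed: int = 0,
    sample_index: int = 0,
    sequence: Sequence | None = None,
    start: tuple[int, int, int] | None = None,
) -> Conformation:
    """Grow one (possibly) branched Rosenbluth conformation.

    From the third placed monomer on, each newly placed monomer becomes a
    branch point with probability ``theta`` and is assigned ``f`` child
    branches.  A branch point's children are placed consecutively (later
    siblings see earlier siblings' sites as occupied), then each child's
    subtree is grown depth-first, first child first, until ``n`` monomers are
    placed.  Draw order per monomer: site choice, then the branching draw.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must be in [0, 1]")
    if f < 2:
        raise ValueError("branch functionality f must be >= 2")
    if n < 1:
        raise ValueError("n must be >= 1")
    if sequence is None:
        sequence = Sequence.from_string("T" * n)
    if sequence.n != n:
        raise ValueError("sequence length must equal n")

    rng = SplitMix64(sample_state(stream_seed(seed, f"branched:{sequence.to_string()}"), sample_index))
    g = _Grower(box, rng)
    g.place_first(start)
    parents = [-1]
    functionality: dict[int, int] = {}

    def n_children(index_placed: int, monomer: int) -> int:
        if index_placed < 3:
            return 1
        if rng.uniform() < theta:
            functionality[monomer] = f
            return f
        return 1

    # stack of monomers whose subtree still needs expanding (LIFO)
    quota = {0: 1}
    stack = [0]
    while stack and len(g.coords) < n and not g.dead:
        m = stack.pop()
        kids = []
        for _ in range(quota[m]):
            if len(g.coords) == n or g.dead:
                break
            k = g.place_child(m)
            if k is None:
                break
            parents.append(m)
            quota[k] = n_children(len(g.coords), k)
            kids.append(k)
        stack.extend(reversed(kids))

    # pad parents for unplaced monomers of a dead-ended growth (linear tail)
    if len(parents) < n:
        parents = parents + [i - 1 for i in range(len(parents), n)]
    return g.finish(sequence, Topology(tuple(parents), functionality))
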
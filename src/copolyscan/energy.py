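"""Contact counting and the lattice contact Hamiltonian.

A monomer interacts with whatever fields fill the unoccupied sites of its
26-neighborhood:

    H(G) = sum_monomers sum_fields  eps[type, field] * U[type, field],

with U the (possibly fractional) number of field contacts.  Sites occupied by
the same chain contribute nothing (incompressibility: a site holds either a
monomer or field/solvent), and neighbor sites outside the z-range contribute
nothing either, consistent with blocked-site growth.  Intra-chain energy
beyond excluded volume is zero, and all energies are in units of kBT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fields import FIELD_NAMES, FieldStack
from .lattice_model import BOND_VECTORS, Conformation, SimulationBox

__all__ = ["InteractionMap", "ContactTally", "contact_counts", "hamiltonian"]


@dataclass(frozen=True)
class InteractionMap:
    """Contact energies eps[monomer type, field type] in kBT per contact."""

    monomer_types: tuple[str, ...]
    field_types: tuple[str, ...]
    eps: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.eps, dtype=float)
        if e.shape != (len(self.monomer_types), len(self.field_types)):
            raise ValueError("eps matrix shape must be (n_monomer_types, n_field_types)")
        if not np.all(np.isfinite(e)):
            raise ValueError("contact energies must be finite")
        object.__setattr__(self, "eps", e)

    @classmethod
    def membrane_default(cls) -> "InteractionMap":
        """The amphiphile/membrane map: eps_{T-H} = eps_{H-T} = eps_{T-S} =
        0.1 kBT, all other contacts athermal."""
        eps = np.zeros((2, 3))
        eps[0, 1] = 0.1  # hydrophobic monomer in head field
        eps[0, 2] = 0.1  # hydrophobic monomer in solvent
        eps[1, 0] = 0.1  # hydrophilic monomer in tail field
        return cls(("T", "H"), FIELD_NAMES, eps)

    @classmethod
    def hbond_default(cls) -> "InteractionMap":
        """Two-state model vs. (polymer density, solvent) fields: an H-bonded
        monomer pays 0.1 kBT per polymer contact, a free monomer 0.1 kBT per
        solvent contact (mirror of the membrane scheme's magnitude)."""
        eps = np.array([[0.1, 0.0], [0.0, 0.1]])
        return cls(("HB", "NOHB"), ("P", "S"), eps)

    @classmethod
    def zeros(cls, monomer_types=("T", "H"), field_types=FIELD_NAMES) -> "InteractionMap":
        return cls(tuple(monomer_types), tuple(field_types),
                   np.zeros((len(monomer_types), len(field_types))))

    def scaled(self, factor: float) -> "InteractionMap":
        return InteractionMap(self.monomer_types, self.field_types, self.eps * factor)

    def get(self, monomer: str, field_name: str) -> float:
        return float(self.eps[self.monomer_types.index(monomer),
                              self.field_types.index(field_name)])


@dataclass
class ContactTally:
    """Per-monomer, per-field effective contact numbers (fractional fields
    give fractional counts; each monomer totals at most 26)."""

    counts: np.ndarray  # (n_monomers, n_fields)
    field_types: tuple[str, ...] = FIELD_NAMES

    def total(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def contact_counts(
    conf: Conformation, stack: FieldStack, box: SimulationBox | None = None
) -> ContactTally:
    """Count field contacts over each monomer's 26 neighbor sites, skipping
    sites occupied by the same conformation and sites outside the z-range."""
    box = box or stack.box
    n = conf.n if conf.weight > 0 else (conf.n_placed or 0)
    coords = conf.coords[:n]
    for z in coords[:, 2]:
        if not box.contains_z(int(z)):
            raise ValueError(f"monomer at z={z} lies outside the box")
    occupied = set(map(tuple, coords.tolist()))
    counts = np.zeros((conf.n, 3))
    for i in range(n):
        x, y, z = (int(v) for v in coords[i])
        for dx, dy, dz in BOND_VECTORS:
            nz = z + int(dz)
            if not box.contains_z(nz):
                continue
            site = ((x + int(dx)) % box.Lx, (y + int(dy)) % box.Ly, nz)
            if site in occupied:
                continue
            counts[i] += stack.fractions_at(*site)
    return ContactTally(counts)


def hamiltonian(
    conf: Conformation,
    stack: FieldStack,
    imap: InteractionMap | None = None,
    box: SimulationBox | None = None,
) -> float:
    """Contact Hamiltonian of a conformation in a field stack, in kBT."""
    imap = imap or InteractionMap.membrane_default()
    tally = contact_counts(conf, stack, box)
    types = conf.sequence.type_indices(imap.monomer_types)
    return float(np.einsum("if,if->", imap.eps[types], tally.counts))
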
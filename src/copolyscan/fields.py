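"""Fixed external field stacks: membrane slabs, core-shell micelles, globules.

The box is partitioned into three volume-fraction fields — hydrophobic
(lipid-tail-like) Phi_T, hydrophilic (head-group-like) Phi_H and solvent
Phi_S — that sum to one at every site.  Fields are frozen (quasi-instantaneous
mean-field approximation): chains feel the fields, the fields never respond.

Planar stacks vary along z only and are described per layer; spherical stacks
vary with the Euclidean distance r from the box center and are held as full
3D grids (a site belongs to shell floor(r) for profile reporting).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lattice_model import SimulationBox

__all__ = [
    "FIELD_T",
    "FIELD_H",
    "FIELD_S",
    "FIELD_NAMES",
    "FieldStack",
    "DensityProfile",
    "planar_membrane",
    "spherical_micelle",
    "sigmoid_globule",
    "globule_stack",
    "write_profile_tsv",
    "read_profile_tsv",
]

FIELD_T, FIELD_H, FIELD_S = 0, 1, 2
FIELD_NAMES = ("T", "H", "S")


@dataclass
class FieldStack:
    """Per-site volume fractions (Phi_T, Phi_H, Phi_S) in a box.

    geometry "planar-z": ``layer_fractions`` has shape (3, Lz) and
    ``mid_plane`` is the membrane mid-plane in absolute z units (half-integer
    when the tail slab is even).  geometry "spherical-r": ``grids`` has shape
    (3, Lx, Ly, Lz) and ``shells`` the per-site shell index floor(r).
    """

    geometry: str
    box: SimulationBox
    layer_fractions: np.ndarray | None = None
    mid_plane: float | None = None
    grids: np.ndarray | None = None
    shells: np.ndarray | None = None

    def __post_init__(self):
        if self.geometry not in ("planar-z", "spherical-r"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        frac = self.layer_fractions if self.geometry == "planar-z" else self.grids
        if frac is None:
            raise ValueError("field stack is missing its fraction data")
        if np.any(frac < 0) or np.any(frac > 1):
            raise ValueError("volume fractions must lie in [0, 1]")
        if not np.allclose(frac.sum(axis=0), 1.0):
            raise ValueError("volume fractions must sum to 1 at every site")

    def fractions_at(self, x: int, y: int, z: int) -> np.ndarray:
        """(Phi_T, Phi_H, Phi_S) at an absolute site (x, y, z)."""
        zi = z - self.box.z_min
        if self.geometry == "planar-z":
            return self.layer_fractions[:, zi]
        return self.grids[:, x % self.box.Lx, y % self.box.Ly, zi]

    def as_grids(self) -> np.ndarray:
        """Full (3, Lx, Ly, Lz) grids regardless of geometry."""
        if self.geometry == "spherical-r":
            return self.grids
        g = np.broadcast_to(
            self.layer_fractions[:, None, None, :],
            (3, self.box.Lx, self.box.Ly, self.box.Lz),
        )
        return np.ascontiguousarray(g)

    def n_shells(self) -> int:
        if self.geometry != "spherical-r":
            raise ValueError("shells are defined for spherical stacks only")
        return int(self.shells.max()) + 1

    def layer_profile(self) -> pd.DataFrame:
        """Per-layer (planar) or per-shell (spherical) mean fractions."""
        if self.geometry == "planar-z":
            z = np.arange(self.box.z_min, self.box.z_min + self.box.Lz)
            data = {"layer": z - self.mid_plane}
            for k, name in enumerate(FIELD_NAMES):
                data[f"phi_{name}"] = self.layer_fractions[k]
            return pd.DataFrame(data)
        ns = self.n_shells()
        flat = self.shells.ravel()
        counts = np.bincount(flat, minlength=ns)
        data = {"layer": np.arange(ns)}
        for k, name in enumerate(FIELD_NAMES):
            sums = np.bincount(flat, weights=self.grids[k].ravel(), minlength=ns)
            data[f"phi_{name}"] = sums / np.maximum(counts, 1)
        return pd.DataFrame(data)


def planar_membrane(
    box: SimulationBox = SimulationBox(),
    tail_thickness: int = 6,
    head_thickness: int = 2,
) -> FieldStack:
    """A flat bilayer: a contiguous hydrophobic tail slab (default 6 layers)
    centered in the box, flanked by hydrophilic head slabs (default 2 layers
    per side), solvent elsewhere.  Layer fractions are pure 0/1."""
    if tail_thickness < 1 or head_thickness < 0:
        raise ValueError("slab thicknesses must be positive")
    if tail_thickness + 2 * head_thickness > box.Lz:
        raise ValueError(
            f"membrane ({tail_thickness} + 2*{head_thickness} layers) does not "
            f"fit in a box of Lz={box.Lz}"
        )
    frac = np.zeros((3, box.Lz))
    t0 = (box.Lz - tail_thickness) // 2
    frac[FIELD_S, :] = 1.0
    for zi in range(t0 - head_thickness, t0):
        frac[:, zi] = (0.0, 1.0, 0.0)
    for zi in range(t0, t0 + tail_thickness):
        frac[:, zi] = (1.0, 0.0, 0.0)
    for zi in range(t0 + tail_thickness, t0 + tail_thickness + head_thickness):
        frac[:, zi] = (0.0, 1.0, 0.0)
    mid_plane = box.z_min + t0 + (tail_thickness - 1) / 2
    return FieldStack(
        geometry="planar-z", box=box, layer_fractions=frac, mid_plane=mid_plane
    )


def _radial_grid(box: SimulationBox) -> np.ndarray:
    cx, cy, cz = box.center()
    x = np.arange(box.Lx)[:, None, None] - cx
    y = np.arange(box.Ly)[None, :, None] - cy
    z = np.arange(box.Lz)[None, None, :] - cz
    return np.sqrt(x * x + y * y + z * z)


def spherical_micelle(
    box: SimulationBox = SimulationBox(),
    core_radius: float = 13.0,
    shell_thickness: float = 3.0,
) -> FieldStack:
    """A core-shell micelle: hydrophobic core of radius 13 lattice units,
    hydrophilic shell of thickness 3, solvent beyond; r from the box center."""
    if core_radius <= 0 or shell_thickness < 0:
        raise ValueError("micelle radii must be positive")
    half = min(box.Lx, box.Ly, box.Lz) / 2
    if core_radius + shell_thickness > half:
        raise ValueError(
            f"micelle (radius {core_radius} + shell {shell_thickness}) exceeds "
            f"the box half-extent {half}"
        )
    r = _radial_grid(box)
    grids = np.zeros((3, box.Lx, box.Ly, box.Lz))
    grids[FIELD_T] = r < core_radius
    grids[FIELD_H] = (r >= core_radius) & (r < core_radius + shell_thickness)
    grids[FIELD_S] = r >= core_radius + shell_thickness
    return FieldStack(
        geometry="spherical-r",
        box=box,
        grids=grids,
        shells=np.floor(r).astype(np.int64),
    )


@dataclass(frozen=True)
class DensityProfile:
    """Radial polymer volume fraction phi_p(r) = A - A / (1 + exp(-r + r0)).

    A = 1 is a dense globule, A = 0.5 a sparse one; the complementary
    solvent fraction is 1 - phi_p(r)."""

    amplitude: float = 1.0
    midpoint: float = 9.0

    def __post_init__(self):
        if not 0.0 < self.amplitude <= 1.0:
            raise ValueError("amplitude must be in (0, 1]")

    def phi(self, r):
        r = np.asarray(r, dtype=float)
        out = self.amplitude - self.amplitude / (1.0 + np.exp(-r + self.midpoint))
        return out if out.ndim else float(out)

    def to_grid(self, box: SimulationBox) -> np.ndarray:
        """phi_p evaluated at every site's Euclidean r (shape Lx, Ly, Lz)."""
        return self.phi(_radial_grid(box))


def sigmoid_globule(amplitude: float = 1.0, midpoint: float = 9.0) -> DensityProfile:
    """Sigmoid globule density profile (see :class:`DensityProfile`)."""
    return DensityProfile(amplitude=amplitude, midpoint=midpoint)


def globule_stack(box: SimulationBox, profile: DensityProfile) -> FieldStack:
    """A spherical FieldStack with Phi_T = phi_p (the polymer's own density
    acting as the hydrophobic-like field), Phi_H = 0, Phi_S = 1 - phi_p."""
    phi = profile.to_grid(box)
    grids = np.stack([phi, np.zeros_like(phi), 1.0 - phi])
    r = _radial_grid(box)
    return FieldStack(
        geometry="spherical-r",
        box=box,
        grids=grids,
        shells=np.floor(r).astype(np.int64),
    )


def write_profile_tsv(stack: FieldStack, path) -> None:
    """Dump the per-layer profile as TSV (layer coordinate, phi per field)."""
    stack.layer_profile().to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_profile_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
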
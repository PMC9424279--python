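"""Enumeration-selection orchestration.

A scan iterates a sequence space (one composition class or a full
composition sweep), draws an independent Rosenbluth sample stream per
sequence in the fixed fields, accumulates the design observable streamingly,
and emits a complete ranking.  Per-sequence work is side-effect free: every
sequence's substream is keyed by (master seed, sequence string), so scoring
any subset of sequences, in any order or concurrently, reproduces identical
numbers.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from . import _kernels
from ._rng import stream_seed
from .energy import InteractionMap
from .fields import FieldStack, planar_membrane, spherical_micelle
from .lattice_model import BOND_VECTORS, Sequence, SimulationBox, enumerate_sequences
from .observables import (
    ConcentrationProfile,
    FreeEnergyProfile,
    LocalizationCriterion,
    localization_score,
    mean_escape_time,
)

__all__ = ["ScanConfig", "ScanResult", "run_scan", "rank",
           "sample_free_energy_profile", "sample_concentration_profile",
           "config_fingerprint"]


@dataclass(frozen=True)
class ScanConfig:
    """Everything a scan needs; validated before launch."""

    geometry: str = "planar"  # "planar" (membrane) or "spherical" (micelle)
    box: SimulationBox = field(default_factory=SimulationBox)
    n: int = 12
    n_tail: int | None = 6  # None sweeps every composition 0..n
    samples: int = 100_000
    seed: int = 0
    criterion: str = "escape_time"  # or "localization"
    localization: LocalizationCriterion | None = None
    dedupe: bool = False
    n_batches: int = 20
    tail_thickness: int = 6
    head_thickness: int = 2
    core_radius: float = 13.0
    shell_thickness: float = 3.0
    imap: InteractionMap = field(default_factory=InteractionMap.membrane_default)
    keep_profiles: tuple[str, ...] = ()

    def validate(self) -> None:
        if self.geometry not in ("planar", "spherical"):
            raise ValueError(f"geometry must be 'planar' or 'spherical', got {self.geometry!r}")
        if self.criterion not in ("escape_time", "localization"):
            raise ValueError(f"criterion must be 'escape_time' or 'localization', got {self.criterion!r}")
        if self.criterion == "escape_time" and self.geometry != "planar":
            raise ValueError("the escape-time criterion needs the planar geometry")
        if self.criterion == "localization":
            if self.geometry != "spherical":
                raise ValueError("the localization criterion needs the spherical geometry")
            if self.localization is None:
                raise ValueError("the localization criterion needs a LocalizationCriterion")
            if max(self.localization.indices) > self.n:
                raise ValueError("localization indices exceed the chain length n")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.n_tail is not None and not 0 <= self.n_tail <= self.n:
            raise ValueError(f"invalid composition: n_tail={self.n_tail} not in [0, {self.n}]")
        if self.n_batches < 2:
            raise ValueError("need at least 2 batches for standard errors")
        if self.samples < 20 * self.n_batches:
            raise ValueError(
                f"samples ({self.samples}) must be >= 20 * n_batches ({20 * self.n_batches})"
            )

    def build_fields(self) -> FieldStack:
        if self.geometry == "planar":
            return planar_membrane(self.box, self.tail_thickness, self.head_thickness)
        return spherical_micelle(self.box, self.core_radius, self.shell_thickness)

    def sequences(self) -> tuple[Iterator[Sequence], int]:
        if self.n_tail is not None:
            return enumerate_sequences(self.n, self.n_tail, self.dedupe)
        streams = [enumerate_sequences(self.n, nt, self.dedupe) for nt in range(self.n + 1)]
        total = sum(c for _, c in streams)

        def gen():
            for it, _ in streams:
                yield from it

        return gen(), total


@dataclass
class ScanResult:
    """Ranking table plus optional per-sequence profiles and provenance."""

    table: pd.DataFrame
    profiles: dict
    provenance: dict


def config_fingerprint(config: ScanConfig) -> str:
    """Stable hash of the scan configuration (for logs and provenance)."""
    payload = repr(replace(config, imap=None)).encode() + config.imap.eps.tobytes()
    return hashlib.sha256(payload).hexdigest()[:16]


def rank(scores: pd.DataFrame, direction: str = "asc") -> pd.DataFrame:
    """Stable ranking: by score (ascending or descending), ties broken by
    the sequence string; flagged (failed) sequences always come last."""
    df = scores.copy()
    df["_flagged"] = df["flag"].astype(str) != ""
    df["_key"] = df["score"] if direction == "asc" else -df["score"]
    df = df.sort_values(["_flagged", "_key", "sequence"], kind="stable")
    df = df.drop(columns=["_flagged", "_key"]).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def sample_free_energy_profile(
    sequence: Sequence,
    stack: FieldStack | None = None,
    box: SimulationBox | None = None,
    imap: InteractionMap | None = None,
    samples: int = 100_000,
    seed: int = 0,
    n_batches: int = 20,
    empty_bin: str = "error",
) -> FreeEnergyProfile:
    """Sample one sequence in a planar stack and return its F(z) profile."""
    box = box or SimulationBox()
    stack = stack if stack is not None else planar_membrane(box)
    if stack.geometry != "planar-z":
        raise ValueError("free-energy profiles need a planar field stack")
    imap = imap or InteractionMap.membrane_default()
    base = np.uint64(stream_seed(seed, sequence.to_string()))
    types = sequence.type_indices(imap.monomer_types)
    acc, _conc, counts, _dead = _kernels.planar_scan(
        types, imap.eps, stack.layer_fractions,
        stack.box.Lx, stack.box.Ly, stack.box.Lz,
        BOND_VECTORS, samples, base, n_batches,
    )
    return FreeEnergyProfile.from_accumulators(
        acc, counts, stack.box, stack.mid_plane, empty_bin=empty_bin
    )


def sample_concentration_profile(
    sequence: Sequence,
    stack: FieldStack,
    imap: InteractionMap | None = None,
    samples: int = 100_000,
    seed: int = 0,
    n_batches: int = 20,
) -> ConcentrationProfile:
    """Sample one sequence in a spherical stack and return its per-monomer
    radial concentration profile."""
    if stack.geometry != "spherical-r":
        raise ValueError("radial concentration profiles need a spherical field stack")
    imap = imap or InteractionMap.membrane_default()
    base = np.uint64(stream_seed(seed, sequence.to_string()))
    types = sequence.type_indices(imap.monomer_types)
    n_shells = stack.n_shells()
    zacc, conc, dead = _kernels.radial_scan(
        types, imap.eps, stack.grids, stack.shells, n_shells,
        stack.box.Lx, stack.box.Ly, stack.box.Lz,
        BOND_VECTORS, samples, base, n_batches,
    )
    out = ConcentrationProfile.from_accumulators(conc, zacc, np.arange(n_shells))
    out.n_dead = int(dead)
    return out


def _theta_with_stderr(
    conc: ConcentrationProfile, crit: LocalizationCriterion
) -> tuple[float, float]:
    theta = localization_score(conc, crit)
    idx = np.array(crit.indices) - 1
    mask = np.flatnonzero(crit.shell_mask(conc.cbar.shape[1]))
    thetas = []
    for b in range(conc.batch_numerators.shape[0]):
        if conc.batch_z[b] > 0:
            cb = conc.batch_numerators[b] / conc.batch_z[b]
            thetas.append(cb[np.ix_(idx, mask)].sum())
    se = float(np.std(thetas, ddof=1) / np.sqrt(len(thetas))) if len(thetas) >= 2 else float("nan")
    return theta, se


def run_scan(config: ScanConfig) -> ScanResult:
    """Score every sequence of the configured space and rank them.

    Escape-time scans rank ascending (fastest translocation first);
    localization scans rank descending (best spatial fit first).  A failing
    sequence (e.g. an empty free-energy bin at low sampling) is flagged and
    listed last; it never aborts the scan.
    """
    config.validate()
    stack = config.build_fields()
    seqs, total = config.sequences()
    rows = []
    profiles: dict[str, object] = {}
    dead_total = 0
    for seq in seqs:
        label = seq.to_string()
        flag = ""
        score = float("nan")
        se = float("nan")
        try:
            if config.criterion == "escape_time":
                prof = sample_free_energy_profile(
                    seq, stack=stack, imap=config.imap,
                    samples=config.samples, seed=config.seed,
                    n_batches=config.n_batches,
                )
                res = mean_escape_time(prof)
                score = res.tau
                se = res.tau * res.log_tau_stderr
                dead_total += config.samples - int(prof.counts.sum())
                if label in config.keep_profiles:
                    profiles[label] = prof
            else:
                conc = sample_concentration_profile(
                    seq, stack, imap=config.imap,
                    samples=config.samples, seed=config.seed,
                    n_batches=config.n_batches,
                )
                score, se = _theta_with_stderr(conc, config.localization)
                dead_total += conc.n_dead or 0
                if label in config.keep_profiles:
                    profiles[label] = conc
        except ValueError as e:
            flag = str(e)
        rows.append(
            {"sequence": label, "score": score, "stderr": se,
             "n_samples": config.samples, "flag": flag}
        )
    if len(rows) != total:
        raise AssertionError("sequence enumeration count mismatch")
    direction = "asc" if config.criterion == "escape_time" else "desc"
    table = rank(pd.DataFrame(rows), direction)
    provenance = {
        "seed": config.seed,
        "samples_per_sequence": config.samples,
        "n_sequences": total,
        "criterion": config.criterion,
        "geometry": config.geometry,
        "dedupe": config.dedupe,
        "config_hash": config_fingerprint(config),
        "version": _pkg_version,
        "n_flagged": int((table["flag"].astype(str) != "").sum()),
        "dead_end_fraction": dead_total / (config.samples * total),
    }
    return ScanResult(table=table, profiles=profiles, provenance=provenance)
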
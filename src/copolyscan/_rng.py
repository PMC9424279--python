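"""Counter-based pseudo-random substreams (splitmix64).

Every conformation sample in a scan is drawn from its own deterministic
substream keyed by ``(master seed, sequence label, sample index)``.  This
makes per-sequence work order-insensitive and embarrassingly parallel:
scoring a subset of sequences, or the same sequences in a different order,
reproduces bit-identical results.

The same integer recurrence is implemented twice — here in pure Python (used
by the single-conformation growers in :mod:`copolyscan.lattice_model`) and in
the numba kernels of :mod:`copolyscan._kernels`.  A unit test pins the two
paths to identical streams.
"""

from __future__ import annotations

MASK64 = (1 << 64) - 1
#: splitmix64 increment ("golden gamma").
GOLDEN = 0x9E3779B97F4A7C15
#: stride separating per-sample substreams within one sequence.
STRIDE = 0xD1342543DE82EF95


def mix64(z: int) -> int:
    """splitmix64 finalizer: a 64-bit avalanche permutation."""
    z &= MASK64
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & MASK64
    return z ^ (z >> 31)


def fold_bytes(h: int, data: bytes) -> int:
    """Fold a byte string into a 64-bit state, one avalanche per byte."""
    h &= MASK64
    for b in data:
        h = mix64(h ^ b)
    return h


def stream_seed(master_seed: int, label: str) -> int:
    """Base state of the substream family belonging to one sequence."""
    return fold_bytes(mix64(master_seed), label.encode())


def sample_state(base: int, index: int) -> int:
    """Initial state of the substream for sample ``index`` of a sequence."""
    return mix64((base + index * STRIDE) & MASK64)


class SplitMix64:
    """Minimal splitmix64 generator over an explicit integer state."""

    __slots__ = ("state",)

    def __init__(self, state: int):
        self.state = state & MASK64

    def u64(self) -> int:
        self.state = (self.state + GOLDEN) & MASK64
        return mix64(self.state)

    def below(self, n: int) -> int:
        """Uniform integer in [0, n) (modulo draw; bias < 2**-57 for n <= 64)."""
        return self.u64() % n

    def uniform(self) -> float:
        """Uniform double in [0, 1) with 53 random bits."""
        return (self.u64() >> 11) * 2.0**-53
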
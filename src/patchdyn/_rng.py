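"""Deterministic 64-bit PRNG shared by the python and numba engines.

Both simulation engines draw from the same SplitMix64 stream so that a
run is bit-reproducible regardless of which engine executes it.  The
python implementation here is the reference; :mod:`patchdyn._kernels`
mirrors it with uint64 arithmetic inside the jitted code.
"""

from __future__ import annotations

import numpy as np

_MASK64 = (1 << 64) - 1
_GAMMA = 0x9E3779B97F4A7C15
_MIX1 = 0xBF58476D1CE4E5B9
_MIX2 = 0x94D049BB133111EB


def splitmix64_next(state: int) -> tuple[int, int]:
    """Advance the SplitMix64 state; returns ``(new_state, output)``."""
    state = (state + _GAMMA) & _MASK64
    z = state
    z = ((z ^ (z >> 30)) * _MIX1) & _MASK64
    z = ((z ^ (z >> 27)) * _MIX2) & _MASK64
    return state, z ^ (z >> 31)


class SplitMix64:
    """Tiny convenience wrapper used by the pure-python engine."""

    def __init__(self, state: int):
        self.state = int(state) & _MASK64

    def next_u64(self) -> int:
        self.state, z = splitmix64_next(self.state)
        return z

    def randbelow(self, n: int) -> int:
        # Modulo draw; the bias is < n / 2**64 and, crucially, identical
        # between the python and numba implementations.
        return self.next_u64() % n


def derive_seeds(seed, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit integer seeds from ``seed``."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    state = ss.generate_state(n, dtype=np.uint64)
    return [int(s & 0x7FFFFFFF) for s in state]


def derive_state(seed) -> int:
    """Derive a full 64-bit SplitMix64 state from ``seed``."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return int(ss.generate_state(1, dtype=np.uint64)[0])
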
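"""Seeded Bloom filter used as the ``quer`` structure of compressed containers.

The filter records which length-l suffix prefixes were present at burst
time; later look-ups probe it before touching the exact arrays, and a new
prefix is only ever inserted into the first container whose filter already
claims it (false-positive "recycling"), so the bit array never changes
after the burst.

In *restricted* mode the hash functions read only the interior characters
(positions 2..l-1) of the probe string.  All 16 strings c1·mid·c2 sharing
a middle then probe identical positions — the property that lets graph
traversal resolve all four successor/predecessor variants of a k-mer in a
single container.

Hashing is a splitmix64 double-hashing family over the 2-bit packing of
the hashed characters: h_i = hA + i·hB (mod m), deterministic for a given
seed on every platform.
"""

from __future__ import annotations

import math

from . import dna

_MASK64 = (1 << 64) - 1


def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    z = x
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    return z ^ (z >> 31)


def default_num_hashes(m: int, c: int) -> int:
    """Heuristic hash count for a filter of m bits holding about c elements.

    max(1, round(ln2 · m/c)), capped at 4 — the optimum for c elements in
    m bits, bounded to keep probe cost flat.
    """
    return max(1, min(4, round(math.log(2) * m / max(1, c))))


class BloomFilter:
    """Fixed-size Bloom filter with no false negatives.

    Parameters
    ----------
    m : filter length in bits.
    f : number of hash functions.
    seed : hash seed; equal seeds give bit-identical filters.
    restricted : hash only positions 2..l-1 of each probe string.
    """

    __slots__ = ("m", "f", "seed", "restricted", "bits")

    def __init__(self, m: int, f: int, seed: int = 0, restricted: bool = False, bits: int = 0):
        if m < 1 or f < 1:
            raise ValueError("m and f must be positive")
        self.m = m
        self.f = f
        self.seed = seed
        self.restricted = restricted
        self.bits = bits  # int bitmask, bit j <=> position j+1

    def _key(self, e: str) -> int:
        s = e[1:-1] if self.restricted else e
        # length folded in so "aa" and "aaa" hash independently
        return (dna.encode(s) << 6) | (len(s) & 63)

    def positions(self, e: str) -> list[int]:
        """The f probed 0-based bit positions for element ``e``."""
        key = self._key(e)
        ha = _splitmix64(key ^ self.seed)
        hb = _splitmix64(key ^ ((self.seed * 0x9E3779B97F4A7C15 + 0xDA942042E4DD58B5) & _MASK64)) | 1
        return [((ha + i * hb) % self.m) for i in range(self.f)]

    def insert(self, e: str) -> None:
        """Set the f hashed positions; idempotent."""
        for p in self.positions(e):
            self.bits |= 1 << p

    def may_contain(self, e: str) -> bool:
        """Conjunction of the f probed bits; never false for an inserted e."""
        b = self.bits
        return all((b >> p) & 1 for p in self.positions(e))

    def copy(self) -> "BloomFilter":
        return BloomFilter(self.m, self.f, self.seed, self.restricted, self.bits)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BloomFilter):
            return NotImplemented
        return (self.m, self.f, self.seed, self.restricted, self.bits) == (
            other.m, other.f, other.seed, other.restricted, other.bits)

    def __repr__(self) -> str:
        return (f"BloomFilter(m={self.m}, f={self.f}, seed={self.seed}, "
                f"restricted={self.restricted}, popcount={self.bits.bit_count()})")
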